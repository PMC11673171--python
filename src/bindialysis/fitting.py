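"""Grid-sweep estimation of the binding constant KB, the membrane
conductance KfreeA at the 500 mL/min reference flow, and its flow
dependence beta_Qd.

Two goodness-of-fit criteria are supported: the sum of squared
deviations over the whole concentration trace, and the signed percent
error of the final concentration (negative when the model
under-predicts it).  The sweep simulates every grid point, records the
full error surface, and returns the arg-min; ties break toward the
smallest KB, then KfreeA, then beta, for determinism.

Measured data must share the model's output time grid — the error
functions never interpolate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import Setup, ValidationError
from .session import simulate_session

__all__ = [
    "FitCriterion",
    "FitGrid",
    "FitResult",
    "AlignmentError",
    "sum_of_squares_error",
    "final_percent_error",
    "sweep_fit",
]

logger = logging.getLogger(__name__)

# parameter bounds of the physically sensible search space
KB_BOUNDS = (0.5e7, 7.5e7)  # 1/M
KA_BOUNDS = (100.0, 2500.0)  # mL/min
BETA_BOUNDS = (0.0, 0.6)


class FitCriterion(str, Enum):
    SUM_OF_SQUARES = "sum_of_squares"
    FINAL_PERCENT_ERROR = "final_percent_error"


class AlignmentError(ValidationError):
    """Model and measured series are on different time grids."""


def _check_aligned(model: pd.Series, measured: pd.Series) -> None:
    tm = np.asarray(model.index, dtype=float)
    tt = np.asarray(measured.index, dtype=float)
    if tm.shape != tt.shape or not np.allclose(tm, tt, rtol=0, atol=1e-9):
        raise AlignmentError(
            "model and measured series must share the same time grid "
            "(no implicit interpolation)"
        )


def sum_of_squares_error(model: pd.Series, measured: pd.Series) -> float:
    """Sum over time points of (C_model - C_measured)^2 (mg/dL)^2."""
    _check_aligned(model, measured)
    return float(np.sum((model.to_numpy() - measured.to_numpy()) ** 2))


def final_percent_error(model: pd.Series, measured: pd.Series) -> float:
    """Signed percent error of the final concentration.

    Negative when the model under-predicts the measured final value.
    """
    _check_aligned(model, measured)
    true_end = float(measured.iloc[-1])
    if true_end == 0:
        raise ZeroDivisionError("measured final concentration is zero")
    return 100.0 * (float(model.iloc[-1]) - true_end) / true_end


@dataclass(frozen=True)
class FitGrid:
    """Search lattice; every axis must be non-empty, strictly
    increasing and inside the physical bounds."""

    kb_values: tuple[float, ...]
    kfreeA_values: tuple[float, ...]
    beta_values: tuple[float, ...] = (0.05544,)

    def __post_init__(self) -> None:
        for name, values, (lo, hi) in (
            ("kb_values", self.kb_values, KB_BOUNDS),
            ("kfreeA_values", self.kfreeA_values, KA_BOUNDS),
            ("beta_values", self.beta_values, BETA_BOUNDS),
        ):
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValidationError(f"{name} must be non-empty")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
            if arr.min() < lo or arr.max() > hi:
                logger.warning(
                    "%s outside the usual bounds [%g, %g]; proceeding", name, lo, hi
                )

    def points(self):
        """Grid points in deterministic (kb, kA, beta) sorted order."""
        for kb in self.kb_values:
            for ka in self.kfreeA_values:
                for beta in self.beta_values:
                    yield float(kb), float(ka), float(beta)


@dataclass(frozen=True)
class FitResult:
    best_params: tuple[float, float, float]  # (KB, KfreeA_at_500, beta_Qd)
    error_surface: pd.DataFrame  # columns kb, kfreeA, beta, error
    criterion: FitCriterion

    def to_json_dict(self) -> dict:
        kb, ka, beta = self.best_params
        return {
            "KB_per_M": kb,
            "KfreeA_at_500_mL_min": ka,
            "beta_Qd": beta,
            "criterion": self.criterion.value,
            "best_error": float(
                self.error_surface.loc[
                    (self.error_surface.kb == kb)
                    & (self.error_surface.kfreeA == ka)
                    & (self.error_surface.beta == beta),
                    "error",
                ].iloc[0]
            ),
        }


def _as_datasets(setup, measured):
    if isinstance(measured, pd.Series):
        return [(setup, measured)]
    if isinstance(setup, Setup):
        raise ValidationError(
            "multiple measured series require a matching list of setups"
        )
    if len(setup) != len(measured):
        raise ValidationError("setups and measured series must pair up")
    return list(zip(setup, measured))


def sweep_fit(
    setup: Setup | list[Setup],
    measured: pd.Series | list[pd.Series],
    grid: FitGrid,
    criterion: FitCriterion | str = FitCriterion.SUM_OF_SQUARES,
    cache: dict | None = None,
    **session_kwargs,
) -> FitResult:
    """Exhaustive deterministic sweep over the parameter grid.

    ``measured`` is a pandas Series indexed by time (min) in mg/dL, or
    a list of such series paired with a list of setups (multi-condition
    fitting, e.g. the flow-dependence parameter across flow rates);
    errors are summed over datasets (percent errors by absolute value).
    A grid point whose simulation fails records an infinite error and
    the sweep continues.  ``cache`` (optional dict) memoizes simulated
    traces across calls — replicate fits against the same model curves
    reuse them; results are independent of cache state.
    """
    criterion = FitCriterion(criterion)
    datasets = _as_datasets(setup, measured)
    if cache is None:
        cache = {}

    rows = []
    best: tuple[float, tuple[float, float, float]] | None = None
    for kb, ka, beta in grid.points():
        total = 0.0
        for idx, (stp, data) in enumerate(datasets):
            key = (idx, stp.name, kb, ka, beta, tuple(np.asarray(data.index)))
            try:
                if key in cache:
                    model = cache[key]
                else:
                    trial = stp.with_params(KB=kb, KfreeA_at_500=ka, beta_Qd=beta)
                    trace = simulate_session(
                        trial,
                        output_times=np.asarray(data.index, dtype=float),
                        **session_kwargs,
                    )
                    model = pd.Series(trace.Cb_reservoir, index=trace.t)
                    cache[key] = model
                if criterion is FitCriterion.SUM_OF_SQUARES:
                    total += sum_of_squares_error(model, data)
                else:
                    total += abs(final_percent_error(model, data))
            except Exception as exc:  # failed grid point: record, keep sweeping
                logger.warning(
                    "grid point (KB=%g, kA=%g, beta=%g) failed on dataset %d: %s",
                    kb, ka, beta, idx, exc,
                )
                total = math.inf
                break
        rows.append({"kb": kb, "kfreeA": ka, "beta": beta, "error": total})
        if math.isfinite(total) and (best is None or total < best[0]):
            best = (total, (kb, ka, beta))

    surface = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every grid point failed to simulate")
    return FitResult(
        best_params=best[1], error_surface=surface, criterion=criterion
    )
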