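"""Pseudo-experimental reservoir time series.

Emulates the statistical structure of the bench study: replicate runs
whose initial compositions scatter around the condition means (Gaussian
truncated at zero, SDs as reported for each condition), simulated with
known "true" model parameters, then corrupted with i.i.d. Gaussian
measurement noise at the sampling times.  This gives the fitting
module a ground truth to recover without any external data.

Default sampling is every 30 min, a typical bench schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Setup, ValidationError, builtin_setup
from .session import simulate_session

__all__ = [
    "NoiseModel",
    "condition_setup",
    "CONDITION_SD",
    "draw_initial_conditions",
    "generate_condition",
]

# condition number -> (fixture name, SDs of the Table of starting
# compositions: blood toxin mg/dL, blood albumin g/dL, dialysate albumin g/dL)
_CONDITIONS = {
    1: ("f6hps", (3.06, 0.37, 0.41)),
    2: ("f3_qd150", (2.84, 0.07, 0.23)),
    3: ("f3_qd20", (2.35, 0.12, 0.13)),
    4: ("f3_qd800", (0.43, 0.02, 0.04)),
    5: ("f3_qd2", (1.94, 0.22, 0.14)),
}

CONDITION_SD = {
    k: {"Cb_toxin0": v[1][0], "Cb_albumin": v[1][1], "Cd_albumin": v[1][2]}
    for k, v in _CONDITIONS.items()
}


def condition_setup(condition: int) -> Setup:
    """Mean setup of bench condition 1-5 (see the shipped fixtures)."""
    try:
        name, _ = _CONDITIONS[condition]
    except KeyError:
        raise ValidationError(f"condition must be 1..5, got {condition}") from None
    return builtin_setup(name)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and between-replicate variation.

    ``initial_condition_sd`` maps OperatingPoint field names
    (Cb_toxin0, Cb_albumin, Cd_albumin) to SDs in their clinical units;
    draws are truncated at zero by redraw.
    """

    measurement_sd: float = 0.3  # mg/dL
    initial_condition_sd: dict = field(default_factory=dict)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measurement_sd < 0:
            raise ValidationError("measurement_sd must be >= 0")
        if any(v < 0 for v in self.initial_condition_sd.values()):
            raise ValidationError("initial-condition SDs must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @classmethod
    def for_condition(cls, condition: int, **kwargs) -> "NoiseModel":
        """Noise model seeded with the condition's reported starting SDs."""
        return cls(initial_condition_sd=dict(CONDITION_SD[condition]), **kwargs)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0  # mean far below zero: degenerate but defined


def draw_initial_conditions(
    setup: Setup, noise: NoiseModel, rng: np.random.Generator
) -> dict:
    """One replicate's starting composition (clinical units)."""
    draws = {}
    for name, sd in noise.initial_condition_sd.items():
        mean = getattr(setup.operating, name)
        draws[name] = _truncated_normal(rng, mean, sd)
    return draws


def generate_condition(
    setup: Setup,
    noise: NoiseModel,
    sample_times: np.ndarray | None = None,
    true_params: dict | None = None,
    return_truth: bool = False,
    **session_kwargs,
):
    """Replicate pseudo-measured blood-reservoir series.

    Parameters
    ----------
    true_params : optional overrides {"KB": ..., "KfreeA_at_500": ...,
        "beta_Qd": ...} applied on top of the setup (the generating
        "truth" the fitting module should recover).
    sample_times : measurement times in minutes (default every 30 min).
    return_truth : also return the noiseless mean-setup trace.

    Returns a list of ``replicates`` pandas Series (mg/dL vs min);
    deterministic given ``noise.seed``.  Identical initial-condition
    draws reuse one simulation, so measurement-noise-only studies cost
    a single session.
    """
    if sample_times is None:
        sample_times = np.arange(
            0.0, setup.operating.duration * 60.0 + 1e-9, 30.0
        )
    sample_times = np.asarray(sample_times, dtype=float)
    if true_params:
        setup = setup.with_params(**true_params)

    rng = np.random.default_rng(noise.seed)
    sim_cache: dict[tuple, np.ndarray] = {}

    def simulate(overrides: dict) -> np.ndarray:
        key = tuple(sorted(overrides.items()))
        if key not in sim_cache:
            stp = setup.with_params(**overrides) if overrides else setup
            trace = simulate_session(
                stp, output_times=sample_times, **session_kwargs
            )
            sim_cache[key] = trace.Cb_reservoir
        return sim_cache[key]

    out = []
    for _ in range(noise.replicates):
        draws = draw_initial_conditions(setup, noise, rng)
        clean = simulate(draws)
        noisy = clean + rng.normal(0.0, noise.measurement_sd, size=clean.shape) \
            if noise.measurement_sd > 0 else clean.copy()
        noisy = np.maximum(noisy, 0.0)
        out.append(pd.Series(noisy, index=sample_times, name="Cb_mg_dL"))
    if return_truth:
        truth = pd.Series(simulate({}), index=sample_times, name="Cb_mg_dL")
        return out, truth
    return out
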