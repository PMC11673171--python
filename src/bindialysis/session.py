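"""Quasi-steady treatment-session simulation.

Two well-mixed reservoirs (blood analog and dialysate) recirculate
through the dialyzer.  The dialyzer pass is assumed to reach steady
state instantly relative to the reservoir dynamics, so at each time
step the reservoir concentrations set the single-pass inlet boundary
conditions and the pass removal rate xy0 drives the reservoir balance::

    Vb dCb/dt = Qb (Cb_out - Cb_in) = xy0
    Vd dCd/dt = Qd (Cd_out - Cd_in) = -xy0

(blood reservoir feeds the z=0 inlet, dialysate reservoir the z=L
inlet).  Net ultrafiltration is zero, so volumes are constant and
Vb*Cb + Vd*Cd is conserved exactly by construction; the residual
conservation defect measures temporal integration error only.

Hydraulics are solved once per session: reservoir composition does not
alter viscosity in this model, and the membrane conductance is
adjusted to the session's dialysate inlet flow rate (not the local
flow) before the time loop starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import Setup, ValidationError, clinical_to_molar, molar_to_clinical
from .hydraulics import solve_axial_hydraulics
from .membrane import kfreeA_at_flow
from .single_pass import NoSolutionError, SinglePassProblem, solve_single_pass

__all__ = ["SessionTrace", "simulate_session", "final_concentration"]


@dataclass(frozen=True)
class SessionTrace:
    """Reservoir total-toxin time series (clinical units)."""

    t: np.ndarray  # min, strictly increasing
    Cb_reservoir: np.ndarray  # mg/dL total toxin
    Cd_reservoir: np.ndarray  # mg/dL total toxin
    removal_rate: np.ndarray  # mg/min, instantaneous blood-side loss
    Vb: float  # mL
    Vd: float  # mL

    @property
    def conservation_defect(self) -> float:
        """Max relative drift of Vb*Cb + Vd*Cd over the trace."""
        total = self.Vb * self.Cb_reservoir + self.Vd * self.Cd_reservoir
        return float(np.max(np.abs(total - total[0])) / abs(total[0]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.t,
                "Cb_mg_dL": self.Cb_reservoir,
                "Cd_mg_dL": self.Cd_reservoir,
                "removal_mg_min": self.removal_rate,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        decline = 100.0 * (1.0 - self.Cb_reservoir[-1] / self.Cb_reservoir[0])
        return {
            "final_Cb_mg_dL": float(self.Cb_reservoir[-1]),
            "final_Cd_mg_dL": float(self.Cd_reservoir[-1]),
            "percent_decline": float(decline),
            "conservation_defect": self.conservation_defect,
            "duration_min": float(self.t[-1]),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def simulate_session(
    setup: Setup,
    t_end: float | None = None,
    max_dt: float = 100.0,
    output_times: np.ndarray | None = None,
    rtol: float = 1e-6,
    max_step_z: float = 1.0e-3,
    bvp_tol_rel: float = 1e-6,
    kfreeA_override: float | None = None,
) -> SessionTrace:
    """Simulate a treatment session and return the reservoir trace.

    Parameters
    ----------
    t_end : session duration in minutes (defaults to the setup's).
    max_dt : temporal max step in seconds (quasi-steady cap).
    output_times : sample times in minutes (default: every minute).
    rtol : relative tolerance of the adaptive temporal integrator.
    max_step_z : spatial max step of each single-pass solve (m).
    bvp_tol_rel : shooting residual tolerance relative to Qb*Cb(0).
    """
    op = setup.operating
    if t_end is None:
        t_end = op.duration * 60.0
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    if max_dt <= 0:
        raise ValidationError("max_dt must be positive")

    sol_sys = setup.solute
    cb0 = clinical_to_molar(op.Cb_toxin0, sol_sys.mw_toxin, "mg/dL")
    cd0 = clinical_to_molar(op.Cd_toxin0, sol_sys.mw_toxin, "mg/dL")
    catlb = clinical_to_molar(op.Cb_albumin, sol_sys.mw_binder, "g/dL")
    catld = clinical_to_molar(op.Cd_albumin, sol_sys.mw_binder, "g/dL")

    profile = solve_axial_hydraulics(
        setup.geometry, setup.fluids, op.Qb_in, op.Qd_in
    )
    kA_eff = (
        kfreeA_at_flow(setup.transport, op.Qd_in)
        if kfreeA_override is None
        else kfreeA_override
    )
    bvp_tol = bvp_tol_rel * max(op.Qb_in * cb0, 1e-30)

    last_xy0: list[float | None] = [None]

    def removal_rate(t: float, cb: float, cd: float) -> float:
        """xy0 (M mL/min) for reservoir concentrations cb, cd (M)."""
        problem = SinglePassProblem(
            profile=profile,
            Cb_in_total=max(cb, 0.0),
            Cd_in_total=max(cd, 0.0),
            Catlb_in=catlb,
            Catld_in=catld,
            solute=sol_sys,
            KfreeA_eff=kA_eff,
            sigma=setup.geometry.sigma,
        )
        try:
            sol = solve_single_pass(
                problem, tol=bvp_tol, max_step=max_step_z, hint=last_xy0[0]
            )
        except NoSolutionError as exc:
            raise NoSolutionError(
                f"{exc} (at t = {t:.2f} min of the session)", exc.trace
            ) from exc
        last_xy0[0] = sol.xy0
        return sol.xy0

    def rhs(t: float, y: np.ndarray) -> list[float]:
        xy0 = removal_rate(t, y[0], y[1])
        return [xy0 / op.Vb, -xy0 / op.Vd]

    if output_times is None:
        output_times = np.arange(0.0, t_end + 1e-9, 1.0)
    output_times = np.asarray(output_times, dtype=float)
    if output_times[0] > 0:
        output_times = np.insert(output_times, 0, 0.0)

    result = solve_ivp(
        rhs,
        (0.0, t_end),
        [cb0, cd0],
        method="RK45",
        max_step=max_dt / 60.0,  # seconds -> minutes
        rtol=rtol,
        atol=1e-12,
        t_eval=output_times,
        dense_output=False,
    )
    if not result.success:
        raise RuntimeError(f"temporal integration failed: {result.message}")

    cb = np.maximum(result.y[0], 0.0)
    cd = np.maximum(result.y[1], 0.0)
    cb_mg = np.array([molar_to_clinical(c, sol_sys.mw_toxin, "mg/dL") for c in cb])
    cd_mg = np.array([molar_to_clinical(c, sol_sys.mw_toxin, "mg/dL") for c in cd])
    # removal rate (mg/min) reconstructed from the blood-reservoir slope
    removal = -op.Vb * np.gradient(cb_mg, result.t) * 0.01  # mg/dL*mL -> mg
    return SessionTrace(
        t=result.t,
        Cb_reservoir=cb_mg,
        Cd_reservoir=cd_mg,
        removal_rate=removal,
        Vb=op.Vb,
        Vd=op.Vd,
    )


def final_concentration(trace: SessionTrace) -> float:
    """Blood-reservoir total toxin at the end of the session (mg/dL)."""
    if trace.t.size == 0:
        raise ValidationError("empty session trace")
    return float(trace.Cb_reservoir[-1])
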