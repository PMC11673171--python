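"""Local transmembrane toxin flux.

Transport of the free (unbound) toxin across the membrane combines
diffusion, scaled by the conductance KfreeA, with convection by the
local ultrafiltration flux Jv, weighted by the Peclet function
``f(Pe) = 1/Pe - 1/(exp(Pe) - 1)``.  Because Jv changes sign along the
fiber (backfiltration), the flux law is a three-branch piecewise
function: a purely diffusive middle branch for |Jv| below a critical
flux avoids the 1/Pe singularity, and the outer branches advect the
upstream side's free concentration.

Two adjustment laws complete the picture: an affine dependence of
KfreeA on the dialysate inlet flow rate (boundary-layer effect,
referenced to 500 mL/min with scale 300 mL/min), and rescaling of
KfreeA between dialyzers of the same membrane material by the ratio of
nominal membrane areas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import TransportCoefficients, ValidationError

__all__ = [
    "FluxContext",
    "peclet",
    "peclet_f",
    "jv_crit",
    "local_flux",
    "kfreeA_at_flow",
    "rescale_kfreeA_by_area",
    "beta_upper_bound",
    "KFREEA_REFERENCE_FLOW",
    "KFREEA_FLOW_SCALE",
]

logger = logging.getLogger(__name__)

KFREEA_REFERENCE_FLOW = 500.0  # mL/min
KFREEA_FLOW_SCALE = 300.0  # mL/min

_PE_SERIES_THRESHOLD = 1e-6
_PE_OVERFLOW = 700.0


def peclet(Jv: float, sigma: float, L: float, kA: float) -> float:
    """Peclet number Pe = Jv (1 - sigma) L / kA.

    Inputs must be unit-coherent: with Jv in mL min^-1 mm^-1 and kA in
    mL/min, L must be in mm (the package passes Jv per metre with L in
    metres, which is equivalent).  ``kA = 0`` means pure diffusion is
    degenerate and the caller must use the diffusive branch semantics.
    """
    if kA <= 0:
        raise ValidationError("kA must be positive (kA=0 is pure-diffusion degenerate)")
    return Jv * (1.0 - sigma) * L / kA


def peclet_f(Pe):
    """Convection weighting f(Pe) = 1/Pe - 1/(exp(Pe) - 1).

    Total function on the reals: the removable singularity at Pe = 0 is
    handled by the series 1/2 - Pe/12, and exp overflow by the
    asymptote f -> 1/Pe for large positive Pe.  Satisfies
    f(Pe) + f(-Pe) = 1 and 0 < f < 1.
    """
    pe = np.asarray(Pe, dtype=float)
    scalar = pe.ndim == 0
    pe = np.atleast_1d(pe)
    out = np.empty_like(pe)
    small = np.abs(pe) < _PE_SERIES_THRESHOLD
    big = pe > _PE_OVERFLOW
    rest = ~(small | big)
    out[small] = 0.5 - pe[small] / 12.0
    out[big] = 1.0 / pe[big]
    out[rest] = 1.0 / pe[rest] - 1.0 / np.expm1(pe[rest])
    return float(out[0]) if scalar else out


def jv_crit(Qb: float, Qd: float) -> float:
    """Critical ultrafiltration flux min(Qb, Qd) * 1e-5 per mm.

    Flows in mL/min; result in mL min^-1 mm^-1.  Below this magnitude
    the flux law switches to its purely diffusive branch.
    """
    if Qb <= 0 or Qd <= 0:
        raise ValidationError("flow rates must be positive")
    return min(Qb, Qd) * 1.0e-5


@dataclass(frozen=True)
class FluxContext:
    """Everything the local flux law needs at one axial position."""

    Jv_local: float  # mL min^-1 mm^-1
    Cs_b: float  # M, free toxin blood side
    Cs_d: float  # M, free toxin dialysate side
    KfreeA_eff: float  # mL/min (flow-adjusted)
    L: float  # m
    sigma: float
    Qb_local: float  # mL/min
    Qd_local: float  # mL/min


def local_flux(ctx: FluxContext) -> float:
    """d(Q C_total)/dz for the blood side (M mL min^-1 m^-1).

    Three-branch piecewise law selected by comparing Jv to +/- Jv_crit;
    the convective branches advect the upstream side's free
    concentration.  The branches agree to first order in Jv at the
    switch, so the law is effectively continuous.
    """
    for name in ("Jv_local", "Cs_b", "Cs_d", "KfreeA_eff", "L", "sigma",
                 "Qb_local", "Qd_local"):
        v = getattr(ctx, name)
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite FluxContext field {name!r}: {v}")
    if ctx.KfreeA_eff < 0:
        raise ValidationError("KfreeA_eff must be non-negative")

    crit = jv_crit(ctx.Qb_local, ctx.Qd_local)  # per mm
    diffusive = -(ctx.KfreeA_eff / ctx.L) * (ctx.Cs_b - ctx.Cs_d)  # per m
    if -crit < ctx.Jv_local < crit:
        return diffusive
    # Convective branches.  The signed form below, with the blood-side free
    # concentration in the last term for BOTH signs of Jv, is identical to
    # the side-swapped branch via the identity f(Pe) = 1 - f(-Pe): for
    # Jv < 0 it equals |Jv|(1-sigma) f(|Pe|) (Cs_d - Cs_b) + |Jv|(1-sigma) Cs_d
    # minus the diffusive term, i.e. it advects the upstream (dialysate)
    # side, and it is exactly antisymmetric under (side swap, Jv -> -Jv).
    jv_m = ctx.Jv_local * 1.0e3  # per metre
    one_minus_sigma = 1.0 - ctx.sigma
    if ctx.KfreeA_eff == 0.0:
        # pure convection: f -> step function of sign(Pe)
        advected = ctx.Cs_b if ctx.Jv_local > 0 else ctx.Cs_d
        return -jv_m * one_minus_sigma * advected
    pe = jv_m * one_minus_sigma * ctx.L / ctx.KfreeA_eff
    f = peclet_f(pe)
    return (
        (jv_m * one_minus_sigma * f - ctx.KfreeA_eff / ctx.L)
        * (ctx.Cs_b - ctx.Cs_d)
        - jv_m * one_minus_sigma * ctx.Cs_b
    )


def kfreeA_at_flow(tc: TransportCoefficients, Qd0: float) -> float:
    """Flow-adjusted conductance KfreeA(Qd0) in mL/min.

    Affine in the dialysate inlet/outlet flow rate Qd0:
    ``KfreeA_at_500 * (1 + beta * (Qd0 - 500)/300)``, clamped at zero
    (with a warning) in the unphysical negative region.
    """
    if Qd0 < 0:
        raise ValidationError("Qd0 must be non-negative")
    factor = 1.0 + tc.beta_Qd * (Qd0 - KFREEA_REFERENCE_FLOW) / KFREEA_FLOW_SCALE
    value = tc.KfreeA_at_500 * factor
    if value < 0:
        logger.warning(
            "flow-adjusted KfreeA negative (%.4g mL/min at Qd0=%.4g); clamping to 0",
            value,
            Qd0,
        )
        return 0.0
    return value


def rescale_kfreeA_by_area(kA_old: float, area_new: float, area_old: float) -> float:
    """Rescale a fitted conductance to a dialyzer of different nominal area."""
    if area_new <= 0 or area_old <= 0:
        raise ValidationError("areas must be positive")
    return kA_old * area_new / area_old


def beta_upper_bound(KfreeA_at_500: float = 1.0) -> float:
    """Largest physically meaningful beta_Qd.

    Solves the affine flow law for the beta at which the adjusted
    conductance reaches zero at zero dialysate flow; beyond it the law
    would predict a negative conductance.  Computed as the root of the
    (linear-in-beta) law from two evaluations, not assumed.
    """
    def g(beta: float) -> float:
        # unclamped law at Qd0 = 0 (clamping would hide the root)
        return KfreeA_at_500 * (
            1.0 + beta * (0.0 - KFREEA_REFERENCE_FLOW) / KFREEA_FLOW_SCALE
        )

    g0, g1 = g(0.0), g(1.0)
    return g0 / (g0 - g1)
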