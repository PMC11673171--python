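"""Counter-current single-pass boundary-value problem in the
amount-removed (chi) formulation, solved by a modified shooting method.

chi(z) is the cumulative amount of toxin transferred from blood to
dialysate between the blood inlet and z (negative by convention)::

    chi = Qb Cstlb - Qb_in Cstlb_in = Cstld Qd - Cstld_out Qd_in

so a single stiff ODE in chi carries the whole concentration field:
total concentrations on both sides are reconstructed from chi and the
hydraulic flow profiles, binder profiles follow flow conservation, and
free fractions come from the binding equilibrium.  Boundary conditions
are chi(0) = 0 and chi(L) = xy0 (unknown); each shot integrates the
initial-value problem from the dialysate inlet z = L down to z = 0,
which keeps the state bounded and minimizes stiffness, and reports
Delta = chi(0).

The shooting search uses equally spaced xy0 guesses, classifies the
intervals between them by the sign/stability pattern of Delta (types
1-8b), refines high-priority intervals breadth-first (at most 13 per
generation) with a coarse subdivision and low-priority ones with a
fine subdivision, and rejects candidate roots that are not
reproducible when re-integrated at half the spatial step (spurious
zeros caused by numerical instability).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .config import SoluteSystem, ValidationError
from .hydraulics import AxialProfile

__all__ = [
    "SinglePassProblem",
    "SinglePassSolution",
    "GuessEval",
    "GuessInterval",
    "IntervalType",
    "Priority",
    "NoSolutionError",
    "shoot_once",
    "classify_interval",
    "intervals_from_sweep",
    "guess_trace_to_frame",
    "solve_single_pass",
]

_MLMIN_PER_M3S = 6.0e7
_CHI_BLOWUP_FACTOR = 50.0  # |chi| beyond this multiple of the scale = unstable


# ---------------------------------------------------------------------------
# Compiled kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _free_kernel(ct: float, ca: float, kb: float) -> float:
    """Stable-root free toxin; NaN signals an unphysical state."""
    if ct < 0.0 or ca < 0.0:
        return np.nan
    q = ca + 1.0 / kb - ct
    disc = q * q + 4.0 * ct / kb
    if disc < 0.0:
        return np.nan
    root = math.sqrt(disc)
    if q > 0.0:
        cs = 2.0 * ct / (kb * (root + q))
    else:
        cs = 0.5 * (root - q)
    return cs if cs < ct else ct


@njit(cache=True)
def _rhs_kernel(z: float, chi: float, p: np.ndarray) -> float:
    """d(chi)/dz (M mL/min per m) at axial position z.

    p layout:
      0:L  1:k  2:D  3:gamma  4:Qd_in_si  5:Qb_in_mL  6:Qd_in_mL
      7:QbCb_in  8:CdoutQd  9:CatlbQb  10:CatldQd  11:KB  12:kA_eff  13:sigma
    """
    L = p[0]
    k = p[1]
    D = p[2]
    gamma = p[3]
    # transmembrane pressure and dialysate flow, closed form
    if k > 0.0:
        u = D * math.sinh(k * (L / 2.0 - z))
        qd_si = p[4] - gamma * (D / k) * (
            math.cosh(k * L / 2.0) - math.cosh(k * (L / 2.0 - z))
        )
    else:
        u = D * (L / 2.0 - z)
        qd_si = p[4]
    qd = qd_si * 6.0e7
    qb = qd + (p[5] - p[6])
    if qd <= 0.0 or qb <= 0.0:
        return np.nan
    jv_mm = gamma * u * 6.0e4  # mL/min per mm

    cstlb = (p[7] + chi) / qb
    cstld = (chi + p[8]) / qd
    # tolerate round-off-scale negatives (e.g. Jacobian perturbations at a
    # zero-concentration inlet); genuine excursions still signal instability
    floor = -1e-6 * (p[7] + p[8] + 1e-300) / (qd if qd < qb else qb)
    if cstlb < floor or cstld < floor:
        return np.nan
    if cstlb < 0.0:
        cstlb = 0.0
    if cstld < 0.0:
        cstld = 0.0
    catlb = p[9] / qb
    catld = p[10] / qd
    kb = p[11]
    csb = _free_kernel(cstlb, catlb, kb)
    csd = _free_kernel(cstld, catld, kb)
    if np.isnan(csb) or np.isnan(csd):
        return np.nan

    kA = p[12]
    sigma = p[13]
    crit = (qb if qb < qd else qd) * 1.0e-5
    if -crit < jv_mm < crit:
        return -(kA / L) * (csb - csd)
    # signed upstream-weighted convective law (antisymmetric; see membrane.py)
    jv_m = jv_mm * 1.0e3
    oms = 1.0 - sigma
    if kA == 0.0:
        adv = csb if jv_mm > 0.0 else csd
        return -jv_m * oms * adv
    pe = jv_m * oms * L / kA
    if abs(pe) < 1.0e-6:
        f = 0.5 - pe / 12.0
    elif pe > 700.0:
        f = 1.0 / pe
    else:
        f = 1.0 / pe - 1.0 / math.expm1(pe)
    return (jv_m * oms * f - kA / L) * (csb - csd) - jv_m * oms * csb


@njit(cache=True)
def _integrate_kernel(
    xy0: float,
    h: float,
    n_steps: int,
    p: np.ndarray,
    chi_bound: float,
    record: np.ndarray,
):
    """Implicit-trapezoidal integration of chi from z = L to z = 0.

    Fixed step h (A-stable, damped Newton per step, numeric Jacobian).
    Returns (chi_at_0, stable).  ``record`` (length n_steps+1 or 0)
    receives chi at the grid nodes ordered from z=0 to z=L.
    """
    L = p[0]
    chi = xy0
    if record.size:
        record[n_steps] = chi
    eps = max(abs(xy0) * 1e-7, chi_bound * 1e-10, 1e-18)
    newton_tol = chi_bound * 1e-12
    for i in range(n_steps):
        z0 = L - i * h
        z1 = L - (i + 1) * h
        f0 = _rhs_kernel(z0, chi, p)
        if np.isnan(f0):
            return np.nan, False
        x = chi - h * f0  # explicit predictor (dz = -h)
        converged = False
        for _ in range(30):
            f1 = _rhs_kernel(z1, x, p)
            if np.isnan(f1):
                return np.nan, False
            g = x - chi + 0.5 * h * (f0 + f1)
            if abs(g) < newton_tol:
                converged = True
                break
            fp = _rhs_kernel(z1, x + eps, p)
            fm = _rhs_kernel(z1, x - eps, p)
            if np.isnan(fp) or np.isnan(fm):
                return np.nan, False
            gprime = 1.0 + 0.25 * h * (fp - fm) / eps
            if gprime == 0.0:
                return np.nan, False
            dx = g / gprime
            x -= dx
            if abs(dx) < newton_tol:
                converged = True
                break
        if not converged:
            return np.nan, False
        chi = x
        if not np.isfinite(chi) or abs(chi) > chi_bound:
            return np.nan, False
        if record.size:
            record[n_steps - 1 - i] = chi
    return chi, True


_EMPTY = np.empty(0)


# ---------------------------------------------------------------------------
# Problem and solution containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SinglePassProblem:
    """One quasi-steady pass through the dialyzer.

    Concentrations in M, conductance in mL/min.  ``Catlb_in`` is the
    binder at the blood inlet (z=0), ``Catld_in`` at the dialysate
    inlet (z=L); binder profiles along z follow flow conservation.
    """

    profile: AxialProfile
    Cb_in_total: float
    Cd_in_total: float
    Catlb_in: float
    Catld_in: float
    solute: SoluteSystem
    KfreeA_eff: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Cb_in_total", "Cd_in_total", "Catlb_in", "Catld_in"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.KfreeA_eff < 0:
            raise ValidationError("KfreeA_eff must be non-negative")

    @property
    def Qb_in(self) -> float:
        """Blood inlet flow, mL/min."""
        return self.profile.field.Qb_in * _MLMIN_PER_M3S

    @property
    def Qd_in(self) -> float:
        """Dialysate inlet flow, mL/min."""
        return self.profile.field.Qd_in * _MLMIN_PER_M3S

    @property
    def chi_scale(self) -> float:
        """Natural scale of chi: the whole blood-side toxin stream."""
        return max(self.Qb_in * self.Cb_in_total, 1e-300)

    def _params(self, xy0: float) -> np.ndarray:
        fld = self.profile.field
        qb_ml = self.Qb_in
        qd_ml = self.Qd_in
        cd_out = self.Cd_in_total - xy0 / qd_ml
        return np.array(
            [
                fld.L,
                fld.k,
                fld.D,
                fld.gamma,
                fld.Qd_in,
                qb_ml,
                qd_ml,
                qb_ml * self.Cb_in_total,
                cd_out * qd_ml,
                self.Catlb_in * qb_ml,
                self.Catld_in * qd_ml,
                self.solute.KB,
                self.KfreeA_eff,
                self.sigma,
            ]
        )


@dataclass(frozen=True)
class SinglePassSolution:
    """Converged single pass: chi(z), removal xy0 and outlet totals."""

    z: np.ndarray
    chi: np.ndarray  # M mL/min, <= 0
    xy0: float
    Cb_out_total: float
    Cd_out_total: float
    residual: float  # |chi(z=0)|

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_m": self.z, "chi_M_mL_min": self.chi})


# ---------------------------------------------------------------------------
# Shooting
# ---------------------------------------------------------------------------


def shoot_once(
    p: SinglePassProblem,
    xy0_guess: float,
    max_step: float = 1.0e-3,
    method: str = "trapezoid",
) -> tuple[float, bool]:
    """Integrate one initial-value problem from z=L to z=0.

    Returns ``(delta, stable)`` with ``delta = chi(0)`` (the known
    boundary value is 0).  Integration failure or an excursion outside
    the physical range is *not* an error: it is reported as
    ``stable=False`` and consumed by the interval classifier.
    """
    if not math.isfinite(xy0_guess):
        raise ValidationError("xy0_guess must be finite")
    params = p._params(xy0_guess)
    L = p.profile.field.L
    n_steps = max(1, int(math.ceil(L / max_step - 1e-12)))
    h = L / n_steps
    bound = _CHI_BLOWUP_FACTOR * p.chi_scale
    if method == "trapezoid":
        delta, stable = _integrate_kernel(xy0_guess, h, n_steps, params, bound, _EMPTY)
        return float(delta), bool(stable)
    if method == "radau":
        try:
            sol = solve_ivp(
                lambda z, y: np.array([_rhs_kernel(z, y[0], params)]),
                (L, 0.0),
                [xy0_guess],
                method="Radau",
                max_step=max_step,
                rtol=1e-8,
                atol=1e-12 * p.chi_scale,
            )
        except (ValueError, FloatingPointError):
            return float("nan"), False  # NaN excursion: unstable shot
        ok = sol.success and np.all(np.isfinite(sol.y)) and abs(sol.y[0, -1]) <= bound
        return (float(sol.y[0, -1]) if ok else float("nan")), bool(ok)
    raise ValidationError(f"unknown integration method {method!r}")


def _chi_profile(
    p: SinglePassProblem, xy0: float, max_step: float
) -> tuple[np.ndarray, np.ndarray]:
    params = p._params(xy0)
    L = p.profile.field.L
    n_steps = max(1, int(math.ceil(L / max_step - 1e-12)))
    h = L / n_steps
    record = np.empty(n_steps + 1)
    bound = _CHI_BLOWUP_FACTOR * p.chi_scale
    _integrate_kernel(xy0, h, n_steps, params, bound, record)
    z = np.linspace(0.0, L, n_steps + 1)
    return z, record


# ---------------------------------------------------------------------------
# Interval taxonomy
# ---------------------------------------------------------------------------


class IntervalType(str, Enum):
    T1 = "1"  # negative -> positive
    T2 = "2"  # positive -> negative
    T3 = "3"  # negative -> positive, unstable in between
    T4 = "4"  # positive -> negative, unstable in between
    T5 = "5"  # negative -> unstable, no positives after
    T6 = "6"  # unstable -> positive, no negatives before
    T7 = "7"  # positive -> smaller positive
    T8A = "8a"  # positive -> smaller positive, partial instability between
    T8B = "8b"  # positive -> smaller positive, fully unstable between


class Priority(str, Enum):
    HIGH = "high"
    LOW = "low"


_HIGH_PRIORITY = {IntervalType.T1, IntervalType.T2, IntervalType.T7, IntervalType.T8A}


@dataclass(frozen=True)
class GuessEval:
    """One shot: guess, residual Delta and stability flag."""

    xy0: float
    delta: float
    stable: bool


@dataclass(frozen=True)
class GuessInterval:
    lower: float
    upper: float
    delta_lower: float
    delta_upper: float
    instability_flags: tuple[bool, ...]
    interval_type: IntervalType
    priority: Priority

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def distance_to_target(self) -> float:
        """Distance of the interval's stable bounds from Delta = 0."""
        candidates = [
            abs(d)
            for d, ok in (
                (self.delta_lower, not math.isnan(self.delta_lower)),
                (self.delta_upper, not math.isnan(self.delta_upper)),
            )
            if ok
        ]
        return min(candidates) if candidates else math.inf


def classify_interval(
    left: GuessEval,
    right: GuessEval,
    interior: tuple[GuessEval, ...] = (),
) -> GuessInterval | None:
    """Assign the taxonomy type to a pair of sweep-adjacent guesses.

    Returns ``None`` for non-intervals: patterns (stable, monotone
    non-decreasing Delta, no sign change) that cannot bracket a root.
    """
    if left.xy0 >= right.xy0:
        raise ValidationError("guesses must be ordered lower < upper")
    flags = (left.stable, *[g.stable for g in interior], right.stable)
    any_unstable = not all(flags[1:-1]) if len(flags) > 2 else False
    all_interior_unstable = len(flags) > 2 and not any(flags[1:-1])

    def make(t: IntervalType) -> GuessInterval:
        return GuessInterval(
            lower=left.xy0,
            upper=right.xy0,
            delta_lower=left.delta if left.stable else math.nan,
            delta_upper=right.delta if right.stable else math.nan,
            instability_flags=tuple(not f for f in flags),
            interval_type=t,
            priority=Priority.HIGH if t in _HIGH_PRIORITY else Priority.LOW,
        )

    if left.stable and right.stable:
        dl, dr = left.delta, right.delta
        if dl < 0.0 <= dr:
            return make(IntervalType.T3 if any_unstable else IntervalType.T1)
        if dl >= 0.0 > dr:
            return make(IntervalType.T4 if any_unstable else IntervalType.T2)
        if dl > 0.0 and 0.0 < dr < dl:
            if not any_unstable:
                return make(IntervalType.T7)
            return make(
                IntervalType.T8B if all_interior_unstable else IntervalType.T8A
            )
        return None  # monotone stable pattern: expected, no root inside
    if left.stable and not right.stable:
        if left.delta < 0.0:
            return make(IntervalType.T5)
        return None
    if right.stable and not left.stable:
        if right.delta > 0.0:
            return make(IntervalType.T6)
        return None
    return None


def intervals_from_sweep(evals: list[GuessEval]) -> list[GuessInterval]:
    """Candidate root intervals from an ordered sweep of guesses.

    Adjacent stable pairs are classified directly; maximal unstable
    runs are bridged by an interval between the nearest stable
    neighbours (types 3/4/8), and unstable runs at the sweep edges
    yield edge types 5/6.
    """
    evals = sorted(evals, key=lambda g: g.xy0)
    out: list[GuessInterval] = []
    stable_idx = [i for i, g in enumerate(evals) if g.stable]
    if not stable_idx:
        return out
    # leading/trailing unstable runs
    first, last = stable_idx[0], stable_idx[-1]
    if first > 0:
        iv = classify_interval(evals[0], evals[first], tuple(evals[1:first]))
        if iv:
            out.append(iv)
    if last < len(evals) - 1:
        iv = classify_interval(evals[last], evals[-1], tuple(evals[last + 1 : -1]))
        if iv:
            out.append(iv)
    # spans between consecutive stable anchors
    for i, j in zip(stable_idx, stable_idx[1:]):
        iv = classify_interval(evals[i], evals[j], tuple(evals[i + 1 : j]))
        if iv:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# Modified shooting search
# ---------------------------------------------------------------------------


def guess_trace_to_frame(trace: list[GuessEval]) -> pd.DataFrame:
    """Debug dump of a shooting search (guess grid, Delta, stability)
    for residual-landscape diagnostics; write with ``.to_csv``."""
    return pd.DataFrame(
        {
            "xy0_guess": [g.xy0 for g in trace],
            "delta": [g.delta for g in trace],
            "stable": [g.stable for g in trace],
        }
    )


class NoSolutionError(RuntimeError):
    """The shooting search exhausted its guesses without a verified root."""

    def __init__(self, message: str, trace: list[GuessEval]):
        super().__init__(message)
        self.trace = trace


def _sort_key(iv: GuessInterval):
    # high priority first; then nearest to target; ties -> lower |xy0|
    return (
        0 if iv.priority is Priority.HIGH else 1,
        iv.distance_to_target(),
        -iv.upper,
    )


def solve_single_pass(
    p: SinglePassProblem,
    n_guesses: int = 25,
    tol: float | None = None,
    max_step: float = 1.0e-3,
    hint: float | None = None,
    n_sub_coarse: int = 4,
    refine_ratio: int = 10,
    max_generations: int = 64,
    debug_trace: list | None = None,
) -> SinglePassSolution:
    """Solve the single-pass BVP for xy0 = chi(L).

    Guesses span ``[-Qb_in * Cb_in_total, 0]`` (a pass cannot remove
    more toxin than the blood stream carries).  ``hint`` (e.g. the
    previous time step's xy0 during a session) restricts the first
    sweep to a narrow window, falling back to the full range when the
    window contains no interval.  A candidate root is accepted only if
    it is reproducible when re-integrated at half the spatial step.
    """
    if n_guesses < 3:
        raise ValidationError("n_guesses must be >= 3")
    scale = p.chi_scale
    if tol is None:
        tol = 1e-6 * scale
    if tol <= 0:
        raise ValidationError("tol must be positive")
    lo_full, hi_full = -p.Qb_in * p.Cb_in_total, 0.0

    all_evals: list[GuessEval] = []

    def evaluate(x: float) -> GuessEval:
        d, s = shoot_once(p, x, max_step=max_step)
        g = GuessEval(x, d, s)
        all_evals.append(g)
        if debug_trace is not None:
            debug_trace.append(g)
        return g

    def verified(g: GuessEval) -> bool:
        d_half, s_half = shoot_once(p, g.xy0, max_step=max_step / 2)
        return s_half and abs(d_half) < 100 * tol

    def finish(g: GuessEval) -> SinglePassSolution:
        z, chi = _chi_profile(p, g.xy0, max_step)
        cb_out = (p.Qb_in * p.Cb_in_total + g.xy0) / p.Qb_in
        cd_out = p.Cd_in_total - g.xy0 / p.Qd_in
        return SinglePassSolution(
            z=z,
            chi=chi,
            xy0=g.xy0,
            Cb_out_total=cb_out,
            Cd_out_total=cd_out,
            residual=abs(g.delta),
        )

    def search(lo: float, hi: float, n0: int) -> SinglePassSolution | None:
        xs = np.linspace(lo, hi, n0)
        evals = [evaluate(x) for x in xs]
        for g in evals:
            if g.stable and abs(g.delta) < tol and verified(g):
                return finish(g)
        queue = sorted(intervals_from_sweep(evals), key=_sort_key)
        width_floor = max(1e-14 * (hi_full - lo_full), 1e-300)
        for _ in range(max_generations):
            if not queue:
                return None
            batch, queue = queue[:13], queue[13:]
            children: list[GuessInterval] = []
            for iv in batch:
                if iv.width <= width_floor:
                    continue
                n_sub = (
                    n_sub_coarse
                    if iv.priority is Priority.HIGH
                    else n_sub_coarse * refine_ratio
                )
                xs = np.linspace(iv.lower, iv.upper, n_sub + 1)
                sub = [evaluate(x) for x in xs[1:-1]]
                # reuse endpoint evaluations
                end_lo = GuessEval(iv.lower, iv.delta_lower, not math.isnan(iv.delta_lower))
                end_hi = GuessEval(iv.upper, iv.delta_upper, not math.isnan(iv.delta_upper))
                seq = [end_lo, *sub, end_hi]
                for g in seq:
                    if g.stable and abs(g.delta) < tol and verified(g):
                        return finish(g)
                children.extend(intervals_from_sweep(seq))
            queue = sorted(children + queue, key=_sort_key)
        return None

    # trivial fixed point (no transport, or both sides toxin-free)
    g0 = evaluate(0.0)
    if g0.stable and abs(g0.delta) < tol and verified(g0):
        return finish(g0)

    back_hi = p.Qd_in * p.Cd_in_total  # back-transport fallback upper bound
    if hint is not None:
        span = max(hi_full - lo_full, back_hi, scale)
        window = 0.01 * span
        centre = min(max(hint, lo_full), max(hi_full, back_hi))
        while window <= span:
            lo = max(centre - window, lo_full)
            hi = min(centre + window, max(hi_full, back_hi))
            if lo < hi:
                sol = search(lo, hi, max(5, n_guesses // 5))
                if sol is not None:
                    return sol
            window *= 4
    if lo_full < hi_full:
        sol = search(lo_full, hi_full, n_guesses)
        if sol is not None:
            return sol
    if back_hi > 0.0:
        # dialysate-to-blood transport (xy0 > 0): only possible root when
        # the dialysate free concentration exceeds the blood side's
        sol = search(0.0, back_hi, n_guesses)
        if sol is not None:
            return sol
    raise NoSolutionError(
        f"no verified root with |Delta| < {tol:.3e} after sweeping "
        f"[{lo_full:.3e}, {max(hi_full, back_hi):.3e}] with {len(all_evals)} shots",
        all_evals,
    )
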