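"""Independent oracles used by the test suite.

Each oracle deliberately takes a different computational route from the
implementation it checks: bisection on the mass-action relation for the
binding quadratic, dense Runge-Kutta integration plus scalar root
finding for the closed-form hydraulics, collocation (scipy.solve_bvp)
for the shooting solution of the single-pass boundary-value problem,
and a nonlinear equilibrium/mass-balance solve for the session
end state.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp
from scipy.optimize import brentq

from bindialysis.binding import free_toxin
from bindialysis.membrane import peclet_f


def bisect_free_toxin(c_total: float, c_binder: float, KB: float,
                      tol: float = 1e-14) -> float:
    """Free toxin by bisection on mass action, bracketed by [0, c_total]."""
    if c_total == 0:
        return 0.0

    def residual(cs: float) -> float:
        # KB * cs * (ca - (ct - cs)) - (ct - cs), monotone increasing in cs
        return KB * cs * (c_binder - c_total + cs) - (c_total - cs)

    lo, hi = 0.0, c_total
    while True:
        mid = 0.5 * (lo + hi)
        if not (lo < mid < hi) or hi - lo <= tol * mid:
            return mid
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid


def dense_hydraulics(geom, fluids, Qb_in_mL, Qd_in_mL, z_eval):
    """Integrate the four coupled pressure/flow ODEs numerically.

    State y = [Pb, Pd, Qb, Qd] (SI).  The unknown blood inlet pressure
    is found by a scalar root solve on the net-ultrafiltration defect
    Qb(L) - Qb(0).  Returns dict of arrays on z_eval (SI units).
    """
    import math

    from bindialysis.hydraulics import shell_resistance

    L = geom.fiber_length
    a = 8.0 * fluids.mu_blood / (geom.n_fibers * math.pi * geom.r_inner**4)
    b = shell_resistance(geom, fluids.mu_dialysate)
    gamma = 2.0 * geom.n_fibers * math.pi * geom.r_inner * geom.Lp
    qb0 = Qb_in_mL / 6e7
    qd_in = Qd_in_mL / 6e7

    def rhs(z, y):
        Pb, Pd, Qb, Qd = y
        j = gamma * (Pb - Pd)
        return [-a * Qb, b * Qd, -j, -j]

    def qd0_for(pb0):
        # Qd(0) is itself unknown; but Qd(L) - Qd(0) = Qb(L) - Qb(0), so
        # enforcing zero net UF makes Qd(0) = Qd_in.  Use that directly.
        return qd_in

    def defect(pb0):
        sol = solve_ivp(rhs, (0, L), [pb0, 0.0, qb0, qd0_for(pb0)],
                        rtol=1e-12, atol=1e-18, dense_output=True)
        return sol.y[2, -1] - qb0

    scale = max(a * qb0, b * qd_in) * L
    pb0 = brentq(defect, -10 * scale, 10 * scale, xtol=1e-12 * max(scale, 1e-30))
    sol = solve_ivp(rhs, (0, L), [pb0, 0.0, qb0, qd_in],
                    rtol=1e-12, atol=1e-18, dense_output=True)
    y = sol.sol(z_eval)
    return {"Pb": y[0], "Pd": y[1], "Qb": y[2], "Qd": y[3],
            "Jv": gamma * (y[0] - y[1])}


def collocation_xy0(problem, n_mesh: int = 2001, tol: float = 1e-8) -> float:
    """Single-pass xy0 by collocation on a dense mesh (independent of
    the shooting path).  The unknown boundary value enters as a free
    parameter with the extra condition chi(L) = xy0."""
    fld = problem.profile.field
    L = fld.L
    Qb_in, Qd_in = problem.Qb_in, problem.Qd_in
    KB = problem.solute.KB
    kA = problem.KfreeA_eff
    sig = problem.sigma

    def rhs(z, y, params):
        xy0 = params[0]
        chi = y[0]
        u = fld.u(z)
        qd = fld.Qd(z) * 6e7
        qb = qd + (Qb_in - Qd_in)
        jv_mm = fld.gamma * u * 6e4
        cd_out = problem.Cd_in_total - xy0 / Qd_in
        cstlb = np.clip((Qb_in * problem.Cb_in_total + chi) / qb, 0.0, None)
        cstld = np.clip((chi + cd_out * Qd_in) / qd, 0.0, None)
        csb = free_toxin(cstlb, problem.Catlb_in * Qb_in / qb, KB)
        csd = free_toxin(cstld, problem.Catld_in * Qd_in / qd, KB)
        diff = -(kA / L) * (csb - csd)
        jv_m = jv_mm * 1e3
        if kA > 0:
            pe = jv_m * (1 - sig) * L / kA
            f = peclet_f(pe)
            conv = (jv_m * (1 - sig) * f - kA / L) * (csb - csd) - jv_m * (
                1 - sig
            ) * csb
        else:
            conv = -jv_m * (1 - sig) * np.where(jv_mm > 0, csb, csd)
        crit = np.minimum(qb, qd) * 1e-5
        return np.where(np.abs(jv_mm) < crit, diff, conv)[None, :]

    def bc(ya, yb, params):
        return np.array([ya[0], yb[0] - params[0]])

    z = np.linspace(0.0, L, n_mesh)
    y_init = np.zeros((1, n_mesh))
    sol = solve_bvp(
        rhs, bc, z, y_init, p=[-0.01 * problem.chi_scale],
        tol=tol, max_nodes=500_000,
    )
    assert sol.status in (0, 1), sol.message
    return float(sol.p[0])


def equilibrium_final_totals(setup):
    """Long-time reservoir totals: equal free concentrations plus
    conservation of total toxin mass (clinical units, mg/dL)."""
    from bindialysis.config import clinical_to_molar, molar_to_clinical

    op = setup.operating
    mw_t, mw_b = setup.solute.mw_toxin, setup.solute.mw_binder
    KB = setup.solute.KB
    cb0 = clinical_to_molar(op.Cb_toxin0, mw_t, "mg/dL")
    cd0 = clinical_to_molar(op.Cd_toxin0, mw_t, "mg/dL")
    ab = clinical_to_molar(op.Cb_albumin, mw_b, "g/dL")
    ad = clinical_to_molar(op.Cd_albumin, mw_b, "g/dL")
    total = op.Vb * cb0 + op.Vd * cd0  # M * mL

    def gap(cb):
        cd = (total - op.Vb * cb) / op.Vd
        return free_toxin(cb, ab, KB) - free_toxin(cd, ad, KB)

    cb_eq = brentq(gap, 0.0, total / op.Vb, xtol=1e-18)
    cd_eq = (total - op.Vb * cb_eq) / op.Vd
    return (
        molar_to_clinical(cb_eq, mw_t, "mg/dL"),
        molar_to_clinical(cd_eq, mw_t, "mg/dL"),
    )
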