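import dataclasses
import math

import numpy as np
import pytest

import bindialysis as bd
from bindialysis.single_pass import (
    GuessEval,
    IntervalType,
    Priority,
    classify_interval,
    intervals_from_sweep,
    shoot_once,
    solve_single_pass,
)

from .conftest import make_problem
from .oracles import collocation_xy0


def _no_transport_problem(setup):
    geom = dataclasses.replace(setup.geometry, Lp=0.0)
    sealed = dataclasses.replace(setup, geometry=geom)
    p = make_problem(sealed)
    return dataclasses.replace(p, KfreeA_eff=0.0)


class TestShootOnce:
    def test_no_transport_fixed_point(self, f3_setup):
        p = _no_transport_problem(f3_setup)
        delta, stable = shoot_once(p, 0.0)
        assert stable
        assert delta == pytest.approx(0.0, abs=1e-15 * p.chi_scale)

    def test_zero_removal_inconsistent_with_gradient(self, f3_problem):
        delta, stable = shoot_once(f3_problem, 0.0)
        assert stable
        assert abs(delta) > 1e-3 * f3_problem.chi_scale

    def test_delta_vanishes_at_oracle_root(self, f3_problem):
        xy0_true = collocation_xy0(f3_problem)
        delta, stable = shoot_once(f3_problem, xy0_true)
        assert stable
        assert abs(delta) < 1e-4 * f3_problem.chi_scale

    def test_backends_agree_on_stable_guess(self, f3_problem):
        guess = -0.1 * f3_problem.chi_scale
        d_trap, s_trap = shoot_once(f3_problem, guess)
        d_radau, s_radau = shoot_once(f3_problem, guess, method="radau")
        assert s_trap and s_radau
        assert abs(d_trap - d_radau) < 1e-4 * f3_problem.chi_scale

    def test_delta_monotone_over_stable_guesses(self, f3_problem):
        guesses = np.linspace(-f3_problem.chi_scale, 0.0, 15)
        deltas = [shoot_once(f3_problem, g) for g in guesses]
        stable_d = [d for d, s in deltas if s]
        assert len(stable_d) >= 5
        assert np.all(np.diff(stable_d) >= 0)


def _ev(x, delta, stable=True):
    return GuessEval(x, delta if stable else math.nan, stable)


class TestIntervalTaxonomy:
    def test_sign_change_types(self):
        assert classify_interval(_ev(-2, -3), _ev(-1, 2)).interval_type is IntervalType.T1
        assert classify_interval(_ev(-2, 5), _ev(-1, -2)).interval_type is IntervalType.T2

    def test_positive_to_smaller_positive_is_suspicious(self):
        iv = classify_interval(_ev(-2, 5), _ev(-1, 2))
        assert iv.interval_type is IntervalType.T7
        assert iv.priority is Priority.HIGH

    def test_monotone_increase_is_expected_pattern(self):
        assert classify_interval(_ev(-2, 5), _ev(-1, 8)) is None
        assert classify_interval(_ev(-2, -5), _ev(-1, -2)) is None

    def test_unstable_interior_demotes_sign_changes(self):
        mid = (_ev(-1.5, 0, stable=False),)
        t3 = classify_interval(_ev(-2, -3), _ev(-1, 2), mid)
        t4 = classify_interval(_ev(-2, 3), _ev(-1, -2), mid)
        assert t3.interval_type is IntervalType.T3
        assert t4.interval_type is IntervalType.T4
        assert t3.priority is t4.priority is Priority.LOW

    def test_edge_types_and_priorities(self):
        t5 = classify_interval(_ev(-2, -3), _ev(-1, 0, stable=False))
        assert t5.interval_type is IntervalType.T5
        assert t5.priority is Priority.LOW
        t6 = classify_interval(_ev(-2, 0, stable=False), _ev(-1, 2))
        assert t6.interval_type is IntervalType.T6

    def test_partial_vs_full_instability_between_positives(self):
        partial = (
            _ev(-1.8, 0, stable=False),
            _ev(-1.5, 4.0),
            _ev(-1.2, 0, stable=False),
        )
        full = (_ev(-1.8, 0, stable=False), _ev(-1.2, 0, stable=False))
        t8a = classify_interval(_ev(-2, 5), _ev(-1, 2), partial)
        t8b = classify_interval(_ev(-2, 5), _ev(-1, 2), full)
        assert t8a.interval_type is IntervalType.T8A
        assert t8a.priority is Priority.HIGH
        assert t8b.interval_type is IntervalType.T8B
        assert t8b.priority is Priority.LOW

    def test_sweep_bridges_unstable_runs(self):
        evals = [
            _ev(-5, 0, stable=False),
            _ev(-4, -3),
            _ev(-3, 0, stable=False),
            _ev(-2, 2),
            _ev(-1, 5),
        ]
        types = {iv.interval_type for iv in intervals_from_sweep(evals)}
        assert IntervalType.T3 in types  # -3 .. +2 across the unstable run
        # leading unstable run before a negative anchor is not an interval
        assert IntervalType.T6 not in types


class TestSolveSinglePass:
    def test_no_transport_returns_identity_pass(self, f3_setup):
        p = _no_transport_problem(f3_setup)
        sol = solve_single_pass(p)
        assert sol.xy0 == pytest.approx(0.0, abs=1e-9 * p.chi_scale)
        assert sol.Cb_out_total == pytest.approx(p.Cb_in_total, rel=1e-12)
        assert sol.Cd_out_total == pytest.approx(p.Cd_in_total, abs=1e-20)

    def test_agrees_with_collocation_oracle(self, f3_problem):
        sol = solve_single_pass(f3_problem)
        xy0_oracle = collocation_xy0(f3_problem)
        assert sol.xy0 == pytest.approx(xy0_oracle, rel=1e-3)

    def test_removal_is_negative_and_bounded(self, f3_problem):
        sol = solve_single_pass(f3_problem)
        assert sol.xy0 < 0
        assert abs(sol.xy0) <= f3_problem.Qb_in * f3_problem.Cb_in_total
        assert sol.residual < 1e-6 * f3_problem.chi_scale

    def test_outlets_conserve_mass_structurally(self, f3_problem):
        sol = solve_single_pass(f3_problem)
        blood_loss = f3_problem.Qb_in * (f3_problem.Cb_in_total - sol.Cb_out_total)
        dial_gain = f3_problem.Qd_in * (sol.Cd_out_total - f3_problem.Cd_in_total)
        assert blood_loss == pytest.approx(dial_gain, rel=1e-10)
        assert blood_loss == pytest.approx(-sol.xy0, rel=1e-10)

    def test_chi_profile_boundary_values(self, f3_problem):
        sol = solve_single_pass(f3_problem)
        assert sol.chi[0] == pytest.approx(0.0, abs=1e-6 * f3_problem.chi_scale)
        assert sol.chi[-1] == pytest.approx(sol.xy0, rel=1e-12)
        assert np.all(sol.chi <= 1e-12)

    def test_hint_reproduces_cold_start(self, f3_problem):
        cold = solve_single_pass(f3_problem)
        warm = solve_single_pass(f3_problem, hint=cold.xy0 * 1.02)
        assert warm.xy0 == pytest.approx(cold.xy0, rel=1e-4)

    def test_halving_spatial_step_barely_moves_root(self, f3_problem):
        a = solve_single_pass(f3_problem, max_step=1.0e-3)
        b = solve_single_pass(f3_problem, max_step=0.5e-3)
        assert abs(a.xy0 - b.xy0) / abs(a.xy0) < 5e-4

    def test_debug_trace_records_guesses(self, f3_problem):
        trace: list = []
        solve_single_pass(f3_problem, debug_trace=trace)
        assert len(trace) >= 5
        assert all(isinstance(g, GuessEval) for g in trace)
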