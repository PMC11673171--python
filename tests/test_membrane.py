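import numpy as np
import pytest
import sympy

import bindialysis as bd
from bindialysis.config import TransportCoefficients, ValidationError
from bindialysis.membrane import (
    FluxContext,
    beta_upper_bound,
    jv_crit,
    kfreeA_at_flow,
    local_flux,
    peclet,
    peclet_f,
    rescale_kfreeA_by_area,
)


class TestPeclet:
    def test_zero_flux_gives_zero(self):
        assert peclet(0.0, 0.0, 0.2, 769.23) == 0.0

    def test_fully_rejected_solute_gives_zero(self):
        assert peclet(5.0, 1.0, 0.2, 769.23) == 0.0

    def test_constructed_identity(self):
        # Jv * L = kA and sigma = 0 -> Pe = 1
        assert peclet(10.0, 0.0, 20.0, 200.0) == pytest.approx(1.0)

    def test_degenerate_conductance_rejected(self):
        with pytest.raises(ValidationError):
            peclet(1.0, 0.0, 0.2, 0.0)


class TestPecletF:
    def test_series_limit_at_zero(self):
        assert peclet_f(0.0) == pytest.approx(0.5, abs=1e-12)
        assert peclet_f(1e-9) == pytest.approx(0.5 - 1e-9 / 12, rel=1e-9)

    def test_complementarity_identity(self):
        for pe in [0.1, 1.0, 10.0]:
            assert peclet_f(pe) + peclet_f(-pe) == pytest.approx(1.0, abs=1e-12)

    def test_complementarity_on_random_values(self):
        rng = np.random.default_rng(3)
        pe = rng.uniform(-50, 50, size=200)
        assert np.allclose(peclet_f(pe) + peclet_f(-pe), 1.0, atol=1e-12)

    def test_value_at_one_against_high_precision_evaluation(self):
        # 50-digit direct evaluation of 1/Pe - 1/(e^Pe - 1) at Pe = 1
        expected = float(
            sympy.N(1 - 1 / (sympy.exp(sympy.Integer(1)) - 1), 50)
        )
        assert peclet_f(1.0) == pytest.approx(expected, rel=1e-14)

    def test_bounded_in_unit_interval(self):
        pe = np.concatenate([np.linspace(-800, 800, 1001), [1e-8, -1e-8]])
        f = peclet_f(pe)
        assert np.all(f > 0) and np.all(f < 1)


class TestJvCrit:
    def test_direct_formula(self):
        assert jv_crit(150, 20) == pytest.approx(2e-4)

    def test_equal_flows(self):
        assert jv_crit(90, 90) == pytest.approx(90e-5)

    def test_symmetric(self):
        assert jv_crit(150, 20) == jv_crit(20, 150)


def _ctx(**overrides):
    base = dict(
        Jv_local=0.0, Cs_b=2e-4, Cs_d=1e-4, KfreeA_eff=769.23,
        L=0.20, sigma=0.0, Qb_local=150.0, Qd_local=150.0,
    )
    base.update(overrides)
    return FluxContext(**base)


class TestLocalFlux:
    def test_equilibrium_no_driving_force(self):
        assert local_flux(_ctx(Cs_b=1e-4, Cs_d=1e-4, Jv_local=0.0)) == 0.0

    def test_diffusive_branch_is_single_product(self):
        flux = local_flux(_ctx(Jv_local=1e-4))  # |Jv| < crit = 1.5e-3
        assert flux == pytest.approx(-(769.23 / 0.20) * 1e-4, rel=1e-12)

    def test_sign_follows_concentration_gradient_in_diffusive_branch(self):
        assert local_flux(_ctx(Cs_b=1e-4, Cs_d=3e-4, Jv_local=1e-4)) > 0
        assert local_flux(_ctx(Cs_b=3e-4, Cs_d=1e-4, Jv_local=-1e-4)) < 0

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_branch_continuity_at_switch(self, sign):
        crit = jv_crit(150.0, 150.0)
        below = local_flux(_ctx(Jv_local=sign * 0.99 * crit))
        above = local_flux(_ctx(Jv_local=sign * 1.01 * crit))
        bound = crit * 1.0 * max(2e-4, 1e-4) * 2 * 1e3  # per-metre units
        assert abs(above - below) < bound

    def test_antisymmetric_under_side_swap_and_flux_reversal(self):
        a = local_flux(_ctx(Jv_local=5e-3, Cs_b=3e-4, Cs_d=1e-4))
        b = local_flux(_ctx(Jv_local=-5e-3, Cs_b=1e-4, Cs_d=3e-4))
        assert a == pytest.approx(-b, rel=1e-12)

    def test_full_rejection_reduces_all_branches_to_diffusion(self):
        diff = local_flux(_ctx(Jv_local=1e-6, sigma=1.0))
        conv = local_flux(_ctx(Jv_local=5e-3, sigma=1.0))
        assert conv == pytest.approx(diff, rel=1e-12)

    def test_pure_convection_advects_upstream_side(self):
        up = local_flux(_ctx(Jv_local=5e-3, KfreeA_eff=0.0))
        assert up == pytest.approx(-5e-3 * 1e3 * 2e-4, rel=1e-12)  # -Jv*Cs_b
        down = local_flux(_ctx(Jv_local=-5e-3, KfreeA_eff=0.0))
        assert down == pytest.approx(5e-3 * 1e3 * 1e-4, rel=1e-12)  # +|Jv|*Cs_d

    def test_non_finite_field_named_in_error(self):
        with pytest.raises(FloatingPointError, match="Cs_b"):
            local_flux(_ctx(Cs_b=float("nan")))


class TestFlowAdjustment:
    TC = TransportCoefficients(KfreeA_at_500=769.23, beta_Qd=0.05544)

    def test_reference_flow_is_identity(self):
        assert kfreeA_at_flow(self.TC, 500.0) == pytest.approx(769.23, rel=1e-14)

    def test_stated_percent_change_over_300(self):
        ratio = kfreeA_at_flow(self.TC, 800.0) / kfreeA_at_flow(self.TC, 500.0)
        assert ratio == pytest.approx(1.05544, rel=1e-12)

    def test_upper_beta_zeroes_conductance_at_zero_flow(self):
        tc = TransportCoefficients(KfreeA_at_500=2500.0, beta_Qd=0.6)
        assert kfreeA_at_flow(tc, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_affine_in_flow(self):
        qd = np.array([0.0, 100.0, 500.0, 800.0, 1200.0])
        vals = np.array([kfreeA_at_flow(self.TC, q) for q in qd])
        slopes = np.diff(vals) / np.diff(qd)
        expected = 769.23 * 0.05544 / 300.0
        assert np.allclose(slopes, expected, rtol=1e-12)


class TestAreaRescaling:
    def test_f6hps_to_f3(self):
        assert rescale_kfreeA_by_area(2500.0, 0.4, 1.3) == pytest.approx(
            769.23, abs=0.005
        )

    def test_identity_and_round_trip(self):
        assert rescale_kfreeA_by_area(1234.5, 0.9, 0.9) == 1234.5
        there = rescale_kfreeA_by_area(2500.0, 0.4, 1.3)
        assert rescale_kfreeA_by_area(there, 1.3, 0.4) == pytest.approx(
            2500.0, rel=1e-12
        )


class TestBetaUpperBound:
    def test_bound_is_reference_over_scale_ratio(self):
        assert beta_upper_bound() == pytest.approx(0.6, rel=1e-12)
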