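import numpy as np
import pytest

import bindialysis as bd


@pytest.fixture(scope="session")
def f3_setup():
    return bd.builtin_setup("f3_qd150")


@pytest.fixture(scope="session")
def f6hps_setup():
    return bd.builtin_setup("f6hps")


@pytest.fixture(scope="session")
def all_setups():
    return [bd.builtin_setup(name) for name in bd.builtin_setup_names()]


def make_problem(setup, Cb_mg_dl=None, Cd_mg_dl=0.0):
    """SinglePassProblem for a setup at given reservoir concentrations."""
    op = setup.operating
    profile = bd.solve_axial_hydraulics(
        setup.geometry, setup.fluids, op.Qb_in, op.Qd_in
    )
    mw_t = setup.solute.mw_toxin
    mw_b = setup.solute.mw_binder
    cb = bd.clinical_to_molar(
        op.Cb_toxin0 if Cb_mg_dl is None else Cb_mg_dl, mw_t, "mg/dL"
    )
    cd = bd.clinical_to_molar(Cd_mg_dl, mw_t, "mg/dL")
    return bd.SinglePassProblem(
        profile=profile,
        Cb_in_total=cb,
        Cd_in_total=cd,
        Catlb_in=bd.clinical_to_molar(op.Cb_albumin, mw_b, "g/dL"),
        Catld_in=bd.clinical_to_molar(op.Cd_albumin, mw_b, "g/dL"),
        solute=setup.solute,
        KfreeA_eff=bd.kfreeA_at_flow(setup.transport, op.Qd_in),
        sigma=setup.geometry.sigma,
    )


@pytest.fixture(scope="session")
def f3_problem(f3_setup):
    return make_problem(f3_setup)
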