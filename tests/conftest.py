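import math

import numpy as np
import pytest

from vscable import (
    CableParams,
    SynthMorphSpec,
    SynthRFSpec,
    build_model,
    make_branchlet_rfs,
    make_cylinder,
    make_vs_like_tree,
)

# Passive constants used for the VS cells: Rm = 2,000 Ω·cm², Ri = 40 Ω·cm.
PARAMS = CableParams()


def r_inf_mohm(params: CableParams, diameter_um: float) -> float:
    """Input resistance of a semi-infinite cylinder (closed form), MΩ."""
    d_cm = diameter_um * 1e-4
    return (
        (2.0 / (math.pi * d_cm**1.5))
        * math.sqrt(params.rm_ohm_cm2 * params.ri_ohm_cm)
        / 1e6
    )


def sealed_cable_green(params, diameter_um, length_um, x_um, x0_um):
    """Closed-form transfer resistance (MΩ) of a finite sealed cylinder:
    R(X, X0) = R_inf · cosh(X_<) · cosh(L − X_>) / sinh(L)."""
    lam_cm = math.sqrt(params.rm_ohm_cm2 * diameter_um * 1e-4 / (4 * params.ri_ohm_cm))
    lam_um = lam_cm * 1e4
    L = length_um / lam_um
    xl, xg = sorted((x_um / lam_um, x0_um / lam_um))
    return r_inf_mohm(params, diameter_um) * math.cosh(xl) * math.cosh(L - xg) / math.sinh(L)


@pytest.fixture(scope="session")
def params():
    return PARAMS


@pytest.fixture(scope="session")
def cylinder():
    """d = 2 μm, l = 500 μm: exactly one space constant long."""
    return make_cylinder(2.0, 500.0)


@pytest.fixture(scope="session")
def cylinder_model(cylinder):
    return build_model(cylinder, PARAMS)


@pytest.fixture(scope="session")
def small_vs_tree():
    return make_vs_like_tree(SynthMorphSpec(n_terminals=32, seed=1))


@pytest.fixture(scope="session")
def small_vs_model(small_vs_tree):
    return build_model(small_vs_tree, PARAMS)


@pytest.fixture(scope="session")
def branchlet_rfs():
    return make_branchlet_rfs(SynthRFSpec(n_branchlets=13, seed=7))
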