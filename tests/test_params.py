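"""Tissue-parameter to monodomain-conductivity mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotwin.params import (
    BaselineConductivities,
    TissueParameters,
    effective_conductivity,
    load_baseline,
)


@pytest.fixture(scope="module")
def base():
    return load_baseline()


def test_packaged_baseline_loads(base):
    assert base.r_ref_um == pytest.approx(15.45)
    assert base.ecv_ref == pytest.approx(0.258)
    assert all(s > 0 for s in base.sigma_i + base.sigma_e)
    # monodomain fiber:transverse anisotropy around 7x
    mono = effective_conductivity(TissueParameters(), base).sigma_mono
    assert 5.0 < mono[0] / mono[1] < 10.0


def test_identity_case_reproduces_baseline(base):
    """At the reference (R, ECV, ECF=0) the mapping is the plain harmonic
    combination of the baseline conductivities and beta = 2/R."""
    cond = effective_conductivity(
        TissueParameters(base.r_ref_um, base.ecv_ref, 0.0), base)
    for k in range(3):
        si, se = base.sigma_i[k], base.sigma_e[k]
        assert cond.sigma_mono[k] == pytest.approx(si * se / (si + se))
    assert cond.beta_per_cm == pytest.approx(2.0 / (15.45e-4))
    # D = sigma_mono / (beta Cm), unit-converted
    for k in range(3):
        assert cond.diffusivity[k] == pytest.approx(
            10.0 * cond.sigma_mono[k] / (cond.beta_per_cm * base.cm_uf_per_cm2))


def test_fully_fibrotic_extracellular_space_blocks_conduction(base):
    cond = effective_conductivity(TissueParameters(ecf=1.0), base)
    assert cond.sigma_mono == (0.0, 0.0, 0.0)
    assert not cond.propagating


def test_radius_enters_only_through_surface_to_volume(base):
    c1 = effective_conductivity(TissueParameters(r_um=10.0), base)
    c2 = effective_conductivity(TissueParameters(r_um=20.0), base)
    assert c2.sigma_mono == c1.sigma_mono
    for k in range(3):
        assert c2.diffusivity[k] == pytest.approx(2.0 * c1.diffusivity[k])


@pytest.mark.parametrize("kwargs", [
    {"r_um": -1.0}, {"ecv": 0.0}, {"ecv": 1.0}, {"ecf": -0.1}, {"ecf": 1.5},
])
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        TissueParameters(**kwargs)


@settings(max_examples=50, deadline=None)
@given(si=st.floats(0.01, 2.0), se=st.floats(0.01, 2.0),
       ecv=st.floats(0.05, 0.6), ecf=st.floats(0.0, 0.99),
       r=st.floats(5.0, 25.0))
def test_monodomain_conductivity_bounded_by_both_paths(si, se, ecv, ecf, r):
    """The harmonic combination never exceeds either pathway and is
    symmetric in the two conductivities."""
    base = BaselineConductivities(sigma_i=(si,) * 3, sigma_e=(se,) * 3,
                                  ecv_ref=0.258, r_ref_um=15.45)
    cond = effective_conductivity(TissueParameters(r, ecv, ecf), base)
    se_eff = se * (ecv / 0.258) * (1 - ecf)
    for k in range(3):
        assert cond.sigma_mono[k] <= min(si, se_eff) + 1e-12
    swapped = BaselineConductivities(sigma_i=(se_eff,) * 3, sigma_e=(si,) * 3,
                                     ecv_ref=0.258, r_ref_um=15.45)
    cond_sw = effective_conductivity(TissueParameters(r, 0.258, 0.0), swapped)
    assert cond_sw.sigma_mono[0] == pytest.approx(cond.sigma_mono[0], rel=1e-9)


def test_personalization_bounds_window():
    assert TissueParameters(r_um=12.0).within_personalization_bounds()
    assert not TissueParameters(r_um=9.0).within_personalization_bounds()
    assert not TissueParameters(r_um=18.5).within_personalization_bounds()
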