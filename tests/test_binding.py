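"""Saturation fits, competition closed form, equilibrium solver, ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from galkit.binding import (
    ASSAY_PRESETS,
    PUBLISHED_KD,
    CompetitionMeasurement,
    TitrationData,
    competition_kd,
    fit_saturation,
    preference_ratio,
    preference_ratio_table,
    published_kd,
    simulate_equilibrium_competition,
)
from galkit.errors import (
    FitError,
    InconsistentInputsError,
    NoCompetitionError,
)
from galkit.synthetic import make_binding_dataset, make_competition_dataset


def test_noiseless_fit_recovers_kd_exactly():
    data, truth = make_binding_dataset(kd=10.0, amax=0.8, noise_sd=0.0, seed=0)
    res = fit_saturation(data)
    assert res.kd == pytest.approx(10.0, rel=1e-6)
    assert res.amax_fit == pytest.approx(0.8, rel=1e-6)
    assert res.method == "bli_steady_state" and res.a0_fit is None
    # FP mode floats the baseline
    fp, _ = make_binding_dataset(
        kd=5.0, amax=0.2, a0=0.05, noise_sd=0.0, seed=0,
        top_concentration=250.0, response_type="fp",
    )
    res_fp = fit_saturation(fp)
    assert res_fp.kd == pytest.approx(5.0, rel=1e-5)
    assert res_fp.a0_fit == pytest.approx(0.05, abs=1e-6)


def test_half_saturation_consistency():
    """At [L] = Kd the bound fraction is exactly one half."""
    data, _ = make_binding_dataset(kd=150.0, amax=1.0, noise_sd=0.0, seed=0)
    res = fit_saturation(data)
    half = res.amax_fit * res.kd / (res.kd + res.kd)
    assert half == pytest.approx(res.amax_fit / 2)


def test_fit_scale_equivariance():
    data, _ = make_binding_dataset(kd=40.0, amax=1.0, noise_sd=0.005, seed=3)
    scaled = TitrationData(data.concentrations * 7.0, data.responses, "bli")
    assert fit_saturation(scaled).kd == pytest.approx(
        7.0 * fit_saturation(data).kd, rel=1e-9
    )


def test_fit_precondition_and_warning_flags():
    with pytest.raises(FitError):
        fit_saturation(TitrationData([10, 12, 14, 16], [0.1, 0.2, 0.3, 0.4]))
    conc = np.array([1.0, 10.0, 100.0, 1000.0, 3000.0])
    resp = np.array([0.1, 0.5, 0.9, 0.3, 1.0])  # a gross dip
    res = fit_saturation(TitrationData(conc, resp))
    assert "nonmonotone_responses" in res.flags


def test_competition_inverts_simulator_exactly():
    state = simulate_equilibrium_competition(
        kd_probe=1.0, kd_comp=50.0, **ASSAY_PRESETS["hGal3"]
    )
    m = CompetitionMeasurement(
        a_competitor=state.anisotropy, a0=0.05, a_max=0.25, kd_probe=1.0,
        **ASSAY_PRESETS["hGal3"],
    )
    res = competition_kd(m)
    assert res.kd == pytest.approx(50.0, rel=1e-9)
    assert res.species["CG"] == pytest.approx(state.cg, rel=1e-9)


def test_competition_near_saturation_limit():
    """Large excess of galectin over probe: anisotropy approaches a_max
    but the closed form still matches the simulator."""
    stoich = {"p_total": 0.1, "g_total": 500.0, "c_total": 300.0}
    state = simulate_equilibrium_competition(1.0, 20.0, **stoich)
    m = CompetitionMeasurement(
        a_competitor=state.anisotropy, a0=0.05, a_max=0.25, kd_probe=1.0,
        **stoich,
    )
    assert competition_kd(m).kd == pytest.approx(20.0, rel=1e-6)


def test_competition_error_paths():
    # a competitor too weak to displace anything -> [CG] <= 0
    weak = CompetitionMeasurement(
        a_competitor=0.2499, a0=0.05, a_max=0.25, kd_probe=1.0,
        p_total=0.1, g_total=120.0, c_total=300.0,
    )
    with pytest.raises(NoCompetitionError):
        competition_kd(weak)
    # anisotropy at the boundary is rejected up front
    with pytest.raises(InconsistentInputsError):
        competition_kd(
            CompetitionMeasurement(
                a_competitor=0.05, a0=0.05, a_max=0.25, kd_probe=1.0,
                p_total=0.1, g_total=3.0, c_total=6.0,
            )
        )
    with pytest.raises(InconsistentInputsError):
        CompetitionMeasurement(
            a_competitor=0.3, a0=0.05, a_max=0.25, kd_probe=1.0,
            p_total=0.1, g_total=3.0, c_total=6.0,
        )


def test_simulator_limits_and_mass_balance():
    # no competitor: reduces to the single-ligand closed form
    state = simulate_equilibrium_competition(
        kd_probe=2.0, kd_comp=50.0, p_total=0.1, g_total=3.0, c_total=0.0
    )
    assert state.cg == 0.0
    g = state.g_free
    assert state.pg == pytest.approx(0.1 * g / (2.0 + g), rel=1e-12)
    # infinitely weak competitor: [CG] -> 0
    state2 = simulate_equilibrium_competition(
        kd_probe=2.0, kd_comp=1e9, p_total=0.1, g_total=3.0, c_total=6.0
    )
    assert state2.cg < 1e-7


@given(
    kd_probe=st.floats(0.05, 100),
    kd_comp=st.floats(0.05, 5000),
    g_total=st.floats(0.5, 500),
    c_total=st.floats(0.0, 1000),
)
def test_simulator_conserves_mass(kd_probe, kd_comp, g_total, c_total):
    state = simulate_equilibrium_competition(
        kd_probe, kd_comp, p_total=0.1, g_total=g_total, c_total=c_total
    )
    assert state.p_free + state.pg == pytest.approx(0.1, abs=1e-10)
    assert state.g_free + state.pg + state.cg == pytest.approx(
        g_total, rel=1e-10
    )
    assert state.c_free + state.cg == pytest.approx(c_total, rel=1e-10, abs=1e-10)


def test_synthetic_competition_dataset_roundtrip():
    m, truth = make_competition_dataset(1.0, 50.0, "hGal3", noise_sd=0.0)
    assert (m.p_total, m.g_total, m.c_total) == (0.1, 3.0, 6.0)
    assert competition_kd(m).kd == pytest.approx(50.0, rel=1e-3)
    _, weak_truth = make_competition_dataset(1.0, 1e6, "hGal3", noise_sd=0.0)
    assert weak_truth["weak_competition"]


def test_preference_ratio_convention_reproduces_published_values():
    assert round(preference_ratio(340, 150), 2) == 0.44
    assert round(preference_ratio(270, 410), 2) == 1.52
    assert preference_ratio(123.4, 123.4) == pytest.approx(1.0)
    with pytest.raises(InconsistentInputsError):
        preference_ratio(-1.0, 2.0)


@given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
def test_preference_ratio_reciprocal(a, b):
    assert preference_ratio(a, b) * preference_ratio(b, a) == pytest.approx(1.0)


def test_published_table_and_ratio_summary():
    assert published_kd("hGal7", "bli") == (270.0, 410.0)
    assert published_kd("hGal3-E165A", "bli") == (230.0, 280.0)
    with pytest.raises(KeyError):
        published_kd("hGal9", "bli")
    table = preference_ratio_table().set_index(["protein", "method"])["ratio"]
    assert table[("hGal1", "bli")] == 0.44
    assert table[("hGal3", "fp")] == 0.23
    assert "printed-value convention" in str(
        preference_ratio_table().attrs["convention"]["note"]
    )
    assert "inputs" in PUBLISHED_KD.attrs["source"]
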