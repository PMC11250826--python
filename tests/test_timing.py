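"""Multiplicity, CCF, gain timing and the molecular clock."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somacohort.timing import (
    ClockModel,
    assign_mutation_timing,
    classify_clonal,
    compute_ccf,
    convert_to_real_time,
    estimate_clock_rate,
    estimate_multiplicity,
    pi_grid_mle,
    time_gain,
    time_wgd,
)


@pytest.mark.parametrize("alt,depth,purity,major,minor,expected", [
    (50, 100, 1.0, 1, 1, 1),      # heterozygous diploid
    (50, 100, 0.5, 2, 1, 2),      # m_raw 2.5 rounds up, clamps to major
    (90, 100, 1.0, 1, 1, 1),      # m_raw 1.8 -> 2, clamped to major_cn 1
])
def test_multiplicity_examples(alt, depth, purity, major, minor, expected):
    assert estimate_multiplicity(alt, depth, purity, major, minor) == expected


def test_multiplicity_zero_depth_errors():
    with pytest.raises(ValueError):
        estimate_multiplicity(0, 0, 1.0, 1, 1)


@pytest.mark.parametrize("alt,depth,purity,cnt,m,expected", [
    (50, 100, 1.0, 2, 1, 1.0),
    (25, 100, 0.5, 2, 1, 1.0),
])
def test_ccf_plugin_examples(alt, depth, purity, cnt, m, expected):
    est = compute_ccf(alt, depth, purity, cnt, m)
    assert est.ccf == pytest.approx(expected)
    assert est.ci_low <= est.ccf <= est.ci_high


def test_ccf_monte_carlo_calibration(rng):
    """Mean CCF near truth and Clopper-Pearson coverage in range at a
    true CCF of 0.4 over 1000 simulated mutations."""
    true_ccf, purity, depth = 0.4, 0.8, 120
    vaf = true_ccf * purity / (purity * 2 + 2 * (1 - purity))
    alts = rng.binomial(depth, vaf, size=1000)
    ests = [compute_ccf(a, depth, purity, 2, 1) for a in alts]
    mean_ccf = np.mean([e.ccf for e in ests])
    cover = np.mean([e.ci_low <= true_ccf <= e.ci_high for e in ests])
    assert abs(mean_ccf - true_ccf) < 0.02
    assert 0.92 <= cover <= 0.98


def test_clonal_classification_rule():
    clonal = compute_ccf(50, 100, 1.0, 2, 1)
    assert classify_clonal(clonal) == "clonal"
    sub = compute_ccf(15, 100, 1.0, 2, 1)
    assert classify_clonal(sub) == "subclonal"


@pytest.mark.parametrize("n1,n2,state,expected", [
    (50, 0, "2+1", 0.0),
    (50, 0, "2+0", 0.0),
    (10, 10, "2+0", 20.0 / 30.0),
    (20, 20, "2+1", 1.0),          # closed form hits the cap
])
def test_time_gain_closed_forms(n1, n2, state, expected):
    gt = time_gain(n1, n2, state, n_boot=200)
    assert gt.pi == pytest.approx(expected, abs=1e-12)
    assert gt.ci_low <= gt.pi <= gt.ci_high


def test_time_gain_no_information():
    with pytest.raises(ValueError):
        time_gain(0, 0, "2+1")


@given(n1=st.integers(0, 30), n2=st.integers(0, 30),
       scale=st.integers(1, 5),
       state=st.sampled_from(["2+1", "2+0", "2+2"]))
@settings(max_examples=100, deadline=None)
def test_pi_scale_invariance_and_mle_agreement(n1, n2, scale, state):
    """pi(a*n1, a*n2) = pi(n1, n2) and the closed form agrees with the
    brute-force multinomial ML grid."""
    if n1 + n2 == 0:
        return
    base = time_gain(n1, n2, state, n_boot=10).pi
    scaled = time_gain(scale * n1, scale * n2, state, n_boot=10).pi
    assert scaled == pytest.approx(base, abs=1e-12)
    assert abs(base - pi_grid_mle(n1, n2, state)) <= 0.001


def test_pi_monotone_in_n2():
    pis = [time_gain(20, n2, "2+1", n_boot=10).pi for n2 in range(0, 15)]
    assert all(b >= a for a, b in zip(pis, pis[1:]))


def test_wgd_pooling():
    single = time_wgd([(10, 10)], n_boot=100)
    direct = time_gain(10, 10, "2+2", n_boot=100)
    assert single.pi == direct.pi
    pooled = time_wgd([(10, 10), (30, 30)], n_boot=100)
    assert pooled.pi == pytest.approx(2 * 40 / (40 + 80))


@pytest.mark.parametrize("clonal,state,mult,expected", [
    (False, "2+1", 1, "subclonal"),
    (True, "2+2", 2, "early-clonal"),
    (True, "2+1", 1, "late-clonal"),
    (True, "1+1", 1, "clonal-NA"),
])
def test_assign_mutation_timing(clonal, state, mult, expected):
    assert assign_mutation_timing(clonal, state, mult) == expected


def test_clock_rate():
    assert estimate_clock_rate(3000, 60) == 50
    with pytest.warns(UserWarning):
        assert estimate_clock_rate(0, 60) == 0
    with pytest.raises(ValueError):
        estimate_clock_rate(100, 0)


def test_real_time_conversion():
    const = ClockModel(acceleration=1.0, initiation_fraction=1.0)
    assert convert_to_real_time(0.5, 60, const).years_before_sampling == \
        pytest.approx(30.0)
    assert convert_to_real_time(1.0, 60, const).years_before_sampling == \
        pytest.approx(0.0)
    varying = ClockModel(acceleration=5.0, initiation_fraction=0.9)
    assert convert_to_real_time(0.5, 60, varying).years_before_sampling == \
        pytest.approx(18.0)


@given(k=st.floats(1.0, 20.0), c=st.floats(0.0, 1.0))
@settings(max_examples=50, deadline=None)
def test_real_time_monotone_decreasing_in_pi(k, c):
    clock = ClockModel(acceleration=k, initiation_fraction=c)
    pis = np.linspace(0, 1, 21)
    years = [convert_to_real_time(p, 70, clock).years_before_sampling
             for p in pis]
    assert all(b <= a + 1e-9 for a, b in zip(years, years[1:]))
    assert years[0] == pytest.approx(70.0)
    assert years[-1] == pytest.approx(0.0, abs=1e-9)
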