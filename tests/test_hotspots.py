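"""SV breakpoint binning, background fit, segmentation, hotspot calls."""

import numpy as np
import pandas as pd
import pytest

from somacohort.cohort import CovariateTrack
from somacohort.hotspots import (
    BreakpointTrack,
    _optimal_partition,
    call_hotspots,
    collect_breakpoints,
    filter_fragile,
    fit_background,
    segment_density,
    HotspotSegment,
)
from somacohort.simulate import (
    HotspotSpec,
    SimulationConfig,
    make_covariate_track,
    plant_sv_hotspots,
)


def _flat_track(n_bins=200, bin_size=100_000, n_chroms=2):
    rows = []
    per = n_bins // n_chroms
    for c in range(1, n_chroms + 1):
        for b in range(per):
            rows.append((str(c), b * bin_size, (b + 1) * bin_size))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    values = {"gc": np.zeros(len(bins)), "rt": np.zeros(len(bins))}
    return CovariateTrack(bins=bins, values=values)


def _sv(chrom1, pos1, chrom2, pos2, complexity="simple"):
    return dict(chrom1=chrom1, start1=pos1, end1=pos1 + 1, chrom2=chrom2,
                start2=pos2, end2=pos2 + 1, sample_id="s", score=".",
                strand1=".", strand2=".", sv_class="DEL",
                complexity=complexity)


def test_collect_counts_both_breakends_and_filters_complex():
    track = _flat_track()
    svs = pd.DataFrame([
        _sv("1", 50_000, "1", 150_000),
        _sv("2", 50_000, "2", 250_000, complexity="complex"),
    ])
    bt = collect_breakpoints(svs, track)
    assert bt.total_breakends == 2  # complex SV contributes nothing
    assert bt.counts[0] == 1 and bt.counts[1] == 1


def test_collect_conserves_breakend_totals(rng):
    cfg = SimulationConfig(n_tumours=20, n_chroms=3, chrom_length=3_000_000)
    track = make_covariate_track(cfg, rng)
    svs = plant_sv_hotspots(track, 0.5, [], 20, rng, simple_fraction=1.0)
    bt = collect_breakpoints(svs, track)
    assert bt.total_breakends == 2 * len(svs)


def test_background_flat_poisson_recovery(rng):
    track = _flat_track(n_bins=2000)
    counts = rng.poisson(2.0, size=2000)
    bt = BreakpointTrack(bins=track.bins, counts=counts,
                         covariates=pd.DataFrame(track.values),
                         bin_size=100_000)
    bg = fit_background(bt)
    assert np.allclose(bg.mean.mean(), 2.0, rtol=0.1)
    assert bg.dispersion < 0.05  # Poisson limit


def test_background_covariate_effect_recovery(rng):
    n = 20_000
    x = rng.normal(size=n)
    mu = 2.0 * np.exp(np.log(2.0) * x)
    counts = rng.poisson(mu)
    bins = pd.DataFrame({"chrom": "1", "start": np.arange(n) * 10,
                         "end": (np.arange(n) + 1) * 10})
    bt = BreakpointTrack(bins=bins, counts=counts,
                         covariates=pd.DataFrame({"x": x}), bin_size=10)
    bg = fit_background(bt)
    assert bg.coefficients["x"] == pytest.approx(np.log(2.0), rel=0.2)


def test_background_all_zero_errors():
    track = _flat_track(n_bins=100)
    bt = BreakpointTrack(bins=track.bins, counts=np.zeros(100, int),
                         covariates=pd.DataFrame(track.values),
                         bin_size=100_000)
    with pytest.raises(ValueError, match="degenerate"):
        fit_background(bt)


def test_partition_homogeneous_single_segment(rng):
    z = rng.normal(5.0, 0.1, size=100)
    assert _optimal_partition(z, penalty=10.0) == [0]


def test_partition_step_profile_changepoints(rng):
    y = np.concatenate([rng.poisson(1.0, 100), rng.poisson(10.0, 20),
                        rng.poisson(1.0, 80)])
    z = 2.0 * np.sqrt(y + 0.375)
    starts = _optimal_partition(z, penalty=10.0)
    assert any(abs(s - 100) <= 2 for s in starts)
    assert any(abs(s - 120) <= 2 for s in starts)


def test_partition_infinite_penalty_no_changepoints(rng):
    z = rng.normal(size=50) + np.repeat([0, 5.0], 25)
    assert _optimal_partition(z, penalty=1e12) == [0]


def test_call_hotspots_depleted_segment_p_near_one(rng):
    track = _flat_track(n_bins=100, n_chroms=1)
    counts = rng.poisson(5.0, size=100)
    counts[:10] = 0
    bt = BreakpointTrack(bins=track.bins, counts=counts,
                         covariates=pd.DataFrame(track.values),
                         bin_size=100_000)
    bg = fit_background(bt)
    cand = pd.DataFrame([dict(chrom="1", start=0, end=1_000_000, n_bins=10,
                              observed=0, expected=float(bg.mean[:10].sum()),
                              candidate=True)])
    res = call_hotspots(cand, bt, bg, n_perm=200, seed=0, q_threshold=1.1)
    assert res[0].p_value > 0.99


def test_call_hotspots_refuses_low_permutations(rng):
    track = _flat_track(n_bins=10, n_chroms=1)
    bt = BreakpointTrack(bins=track.bins, counts=np.ones(10, int),
                         covariates=pd.DataFrame(track.values),
                         bin_size=100_000)
    bg = fit_background(bt)
    with pytest.raises(ValueError):
        call_hotspots(pd.DataFrame([dict(chrom="1", start=0, end=100_000,
                                         n_bins=1, observed=1, expected=1.0,
                                         candidate=True)]),
                      bt, bg, n_perm=10)


def test_fragile_filter_rules():
    hs = [HotspotSegment("1", 0, 200_000, 30, 3.0, 10.0, 0.001, 0.01),
          HotspotSegment("2", 0, 200_000, 30, 3.0, 10.0, 0.001, 0.01)]
    genes = pd.DataFrame([
        ("1", 0, 700_000, "FRAGILE1", 4),       # large, latest quartile
        ("2", 0, 700_000, "EARLY1", 1),         # large but early-replicating
    ], columns=["chrom", "start", "end", "gene",
                "replication_timing_quartile"])
    retained, flagged = filter_fragile(hs, genes)
    assert [h.chrom for h in flagged] == ["1"]
    assert [h.chrom for h in retained] == ["2"]
    r2, f2 = filter_fragile(hs, genes.iloc[0:0])
    assert len(f2) == 0 and len(r2) == 2


def test_planted_hotspot_detected_end_to_end(rng):
    cfg = SimulationConfig(n_tumours=100, n_chroms=4, chrom_length=5_000_000)
    track = make_covariate_track(cfg, rng)
    hs = [HotspotSpec("2", 20, 25, 10.0)]
    svs = plant_sv_hotspots(track, 0.01, hs, 100, rng, simple_fraction=1.0)
    bt = collect_breakpoints(svs, track)
    bg = fit_background(bt)
    cand = segment_density(bt, penalty=8.0, background=bg)
    called = call_hotspots(cand, bt, bg, n_perm=300, seed=1)
    hit = [s for s in called if s.chrom == "2"
           and s.start < 2_500_000 and s.end > 2_000_000]
    assert hit, "planted 10x hotspot not recovered"
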