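"""Structural-variant breakpoint hotspots against a covariate background.

Simple-SV breakends are binned genome-wide, a negative-binomial
regression on local genomic covariates (chromatin accessibility,
repeats, GC, replication timing, gene density, expression) supplies the
expected background density, per-chromosome count profiles are
segmented by penalised piecewise-constant fitting, and elevated
segments are tested by permutation: breakends are redistributed within
each chromosome proportional to the fitted background, so a hotspot is
an elevation beyond what the covariates explain. Candidates overlapping
large late-replicating genes are flagged as likely fragile sites and
excluded from the retained list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from somacohort.burden import bh_adjust
from somacohort.cohort import CovariateTrack


@dataclass
class BreakpointTrack:
    """Cohort breakend counts per genomic bin plus the covariate matrix."""

    bins: pd.DataFrame              # chrom, start, end
    counts: np.ndarray              # per-bin breakend counts over the cohort
    covariates: pd.DataFrame        # one column per covariate, aligned to bins
    bin_size: int

    @property
    def total_breakends(self) -> int:
        return int(self.counts.sum())


@dataclass
class BackgroundModel:
    """Fitted per-bin background mean and NB dispersion (alpha)."""

    mean: np.ndarray
    dispersion: float
    coefficients: pd.Series
    converged: bool


@dataclass
class HotspotSegment:
    chrom: str
    start: int
    end: int
    observed: int
    expected: float
    fold: float
    p_value: float
    q_value: float = float("nan")
    fragile_flag: bool = False


def collect_breakpoints(svs: pd.DataFrame, track: CovariateTrack) -> BreakpointTrack:
    """Bin the breakends of simple SVs over the cohort.

    Only ``complexity == "simple"`` records contribute; each SV adds
    both of its breakends. Breakends outside the binned genome are
    dropped.
    """
    bin_size = track.bin_size
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = track.bins.reset_index(drop=True)
    key = {}
    for i, r in bins.iterrows():
        key[(r["chrom"], r["start"] // bin_size)] = i
    counts = np.zeros(len(bins), int)
    simple = svs[svs["complexity"] == "simple"]
    for _, r in simple.iterrows():
        for chrom, pos in ((r["chrom1"], r["start1"]), (r["chrom2"], r["start2"])):
            idx = key.get((str(chrom), int(pos) // bin_size))
            if idx is not None:
                counts[idx] += 1
    cov = pd.DataFrame({name: np.asarray(vals, float)
                        for name, vals in sorted(track.values.items())})
    return BreakpointTrack(bins=bins, counts=counts, covariates=cov,
                           bin_size=bin_size)


def fit_background(track: BreakpointTrack) -> BackgroundModel:
    """Negative-binomial regression of per-bin counts on the covariates.

    Log link with a log bin-width offset; the NB dispersion alpha is
    profiled by method of moments from a Poisson pre-fit, then the NB
    model is refit. Falls back to Poisson with a warning if the NB fit
    does not converge.
    """
    y = track.counts.astype(float)
    if y.sum() == 0:
        raise ValueError("all-zero breakpoint track: degenerate background fit")
    x = sm.add_constant(track.covariates)
    offset = np.full(len(y), np.log(track.bin_size))
    pois = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
    mu = pois.fittedvalues
    alpha = float(np.clip((((y - mu) ** 2 - mu) / mu ** 2).mean(), 0.0, 10.0))
    if alpha <= 1e-8:
        # dispersion at the Poisson limit
        return BackgroundModel(mean=np.asarray(mu), dispersion=0.0,
                               coefficients=pois.params, converged=True)
    try:
        nb = sm.GLM(y, x, family=sm.families.NegativeBinomial(alpha=alpha),
                    offset=offset).fit()
        if not np.isfinite(nb.params).all():
            raise ValueError("non-finite NB coefficients")
        return BackgroundModel(mean=np.asarray(nb.fittedvalues),
                               dispersion=alpha, coefficients=nb.params,
                               converged=True)
    except Exception as exc:
        warnings.warn(f"NB background fit failed ({exc}); using Poisson",
                      stacklevel=2)
        return BackgroundModel(mean=np.asarray(mu), dispersion=0.0,
                               coefficients=pois.params, converged=False)


def _optimal_partition(z: np.ndarray, penalty: float) -> list[int]:
    """Exact penalised least-squares changepoint DP.

    Minimises sum of within-segment squared error + penalty per segment;
    returns segment start indices (always includes 0).
    """
    n = len(z)
    s1 = np.concatenate([[0.0], np.cumsum(z)])
    s2 = np.concatenate([[0.0], np.cumsum(z ** 2)])

    def cost(i: int, j: int) -> float:  # z[i:j]
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    best = np.full(n + 1, np.inf)
    best[0] = -penalty
    prev = np.zeros(n + 1, int)
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + cost(i, j) + penalty
            if c < best[j]:
                best[j] = c
                prev[j] = i
    cuts = []
    j = n
    while j > 0:
        cuts.append(prev[j])
        j = prev[j]
    return sorted(cuts)


def segment_density(track: BreakpointTrack, penalty: float = 10.0,
                    background: BackgroundModel | None = None) -> pd.DataFrame:
    """Piecewise-constant segmentation of each chromosome's count profile.

    Counts pass through the Anscombe transform 2*sqrt(y + 3/8) to
    stabilise the variance before least-squares segmentation. Segments
    whose mean count exceeds the (local mean of the) background are
    flagged as hotspot candidates.
    """
    rows = []
    bg_mean = (background.mean if background is not None
               else np.full(len(track.counts), track.counts.mean()))
    bins = track.bins
    for chrom in bins["chrom"].unique():
        mask = (bins["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        y = track.counts[idx].astype(float)
        z = 2.0 * np.sqrt(y + 0.375)
        starts = _optimal_partition(z, penalty)
        bounds = starts + [len(y)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_idx = idx[a:b]
            obs = float(track.counts[seg_idx].sum())
            exp = float(bg_mean[seg_idx].sum())
            rows.append(dict(
                chrom=chrom,
                start=int(bins["start"].iloc[seg_idx[0]]),
                end=int(bins["end"].iloc[seg_idx[-1]]),
                n_bins=b - a, observed=int(obs), expected=exp,
                candidate=bool(obs > exp)))
    return pd.DataFrame(rows)


def call_hotspots(candidates: pd.DataFrame, track: BreakpointTrack,
                  background: BackgroundModel, n_perm: int = 1000,
                  seed: int | None = 0, q_threshold: float = 0.05,
                  ) -> list[HotspotSegment]:
    """Permutation test of candidate segments against the background.

    Per chromosome, each permutation redistributes the observed breakend
    total across bins with probability proportional to the background
    mean; for a candidate spanning L bins, p is the fraction of
    permutations whose maximal L-bin window count reaches the observed
    count. BH across candidates; ``retained`` hotspots are q < threshold.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a p-value resolution")
    rng = np.random.default_rng(seed)
    cand = candidates[candidates["candidate"]].reset_index(drop=True)
    bins = track.bins
    results: list[HotspotSegment] = []
    pvals = []
    for chrom in sorted(cand["chrom"].unique()):
        mask = (bins["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        n_c = int(track.counts[idx].sum())
        probs = background.mean[idx]
        probs = probs / probs.sum()
        perms = rng.multinomial(n_c, probs, size=n_perm)  # conserves totals
        csum = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)],
                              axis=1)
        chrom_cand = cand[cand["chrom"] == chrom]
        for _, r in chrom_cand.iterrows():
            length = int(r["n_bins"])
            windows = csum[:, length:] - csum[:, :-length]
            max_window = windows.max(axis=1) if windows.size else np.zeros(n_perm)
            obs = int(r["observed"])
            p = float((np.sum(max_window >= obs) + 1.0) / (n_perm + 1.0))
            if obs < r["expected"]:
                p = 1.0
            exp = float(r["expected"])
            results.append(HotspotSegment(
                chrom=chrom, start=int(r["start"]), end=int(r["end"]),
                observed=obs, expected=exp,
                fold=obs / exp if exp > 0 else float("inf"), p_value=p))
            pvals.append(p)
    qs = bh_adjust(np.array(pvals)) if pvals else np.array([])
    out = []
    for seg, q in zip(results, qs):
        seg.q_value = float(q)
        if q < q_threshold:
            out.append(seg)
    return out


def filter_fragile(hotspots: list[HotspotSegment], genes: pd.DataFrame,
                   min_length: int = 600_000, latest_quartile: int = 4,
                   ) -> tuple[list[HotspotSegment], list[HotspotSegment]]:
    """Flag hotspots overlapping large, latest-replicating genes.

    Returns (retained, flagged). A hotspot is fragile-flagged iff it
    overlaps a gene with length >= ``min_length`` whose replication
    timing quartile equals ``latest_quartile``.
    """
    if genes is None or len(genes) == 0:
        return list(hotspots), []
    frag = genes[((genes["end"] - genes["start"]) >= min_length)
                 & (genes["replication_timing_quartile"] == latest_quartile)]
    retained, flagged = [], []
    for hs in hotspots:
        g = frag[(frag["chrom"].astype(str) == str(hs.chrom))
                 & (frag["start"] < hs.end) & (frag["end"] > hs.start)]
        hs.fragile_flag = len(g) > 0
        (flagged if hs.fragile_flag else retained).append(hs)
    return retained, flagged
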