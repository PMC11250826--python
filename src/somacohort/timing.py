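"""Mutation multiplicity, cancer cell fraction and molecular-clock timing.

The timing of a copy-number gain is read off the multiplicity spectrum of
clonal point mutations in the gained region. Mutations acquired before a
gain are carried on the duplicated allele and appear at multiplicity 2;
mutations after the gain at multiplicity 1. With pi the fraction of clonal
mutational time elapsed at the gain, the expected counts are:

  2+1 (single-copy gain, CNt=3): E[n2] = pi (pre-gain, duplicated allele),
      E[n1] = pi + 3(1-pi) (pre-gain other allele + post-gain on 3 copies)
      => pi = 3 n2 / (n1 + 2 n2)
  2+0 (copy-neutral LOH): E[n2] = pi, E[n1] = 2(1-pi) (the other parental
      allele is lost) => pi = 2 n2 / (n1 + 2 n2)
  2+2 (whole-genome duplication, pooled over segments): E[n2] = 2 pi,
      E[n1] = 4(1-pi) => the same 2 n2 / (n1 + 2 n2) estimator

Molecular time pi converts to years before sampling through a two-phase
clock: unit rate up to the tumour-initiation fraction c of calendar life,
rate k >= 1 afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

GAIN_STATES = ("2+1", "2+0", "2+2")


@dataclass
class CCFEstimate:
    """Cancer cell fraction of one mutation with multiplicity and CI."""

    ccf: float
    ci_low: float
    ci_high: float
    multiplicity: int
    clonal_flag: bool = False


@dataclass
class GainTiming:
    """Molecular-time estimate of one gain (or pooled WGD)."""

    sample_id: str
    region: str
    state: str
    n1: int
    n2: int
    pi: float
    ci_low: float
    ci_high: float


@dataclass
class ClockModel:
    """Two-phase mutational clock.

    rate: clonal mutations per year (mu); acceleration: fold-increase k of
    the rate after tumour initiation (k >= 1, k=1 is a constant clock);
    initiation_fraction: fraction c of calendar life elapsed at initiation.
    """

    rate: float = 50.0
    acceleration: float = 1.0
    initiation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")
        if self.acceleration < 1:
            raise ValueError("acceleration factor k must be >= 1")
        if not 0 <= self.initiation_fraction <= 1:
            raise ValueError("initiation fraction c must lie in [0, 1]")


@dataclass
class RealTimeEstimate:
    event_id: str
    years_before_sampling: float
    ci_low: float
    ci_high: float


def estimate_multiplicity(alt_count: int, total_depth: int, purity: float,
                          major_cn: int, minor_cn: int) -> int:
    """Integer mutation multiplicity from the VAF decomposition.

    m_raw = VAF / purity * (purity*CNt + 2*(1-purity)), rounded half-up
    and clamped into [1, major_cn].
    """
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    cnt = major_cn + minor_cn
    if cnt < 1:
        raise ValueError("total copy number must be >= 1")
    vaf = alt_count / total_depth
    m_raw = vaf / purity * (purity * cnt + 2.0 * (1.0 - purity))
    m = int(np.floor(m_raw + 0.5))  # round half-up, not banker's
    return int(np.clip(m, 1, max(major_cn, 1)))


def compute_ccf(alt_count: int, total_depth: int, purity: float, total_cn: int,
                multiplicity: int, *, alpha: float = 0.05,
                cap: float = 1.5) -> CCFEstimate:
    """Cancer cell fraction with a Clopper-Pearson interval.

    ccf = VAF * (purity*CNt + 2*(1-purity)) / (purity * m); the binomial
    CI on alt/depth passes through the same linear map. Values are capped
    at ``cap`` to absorb sampling noise above 1.
    """
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    scale = (purity * total_cn + 2.0 * (1.0 - purity)) / (purity * multiplicity)
    vaf = alt_count / total_depth
    lo, hi = _clopper_pearson(alt_count, total_depth, alpha)
    ccf = min(vaf * scale, cap)
    return CCFEstimate(ccf=ccf, ci_low=min(lo * scale, cap),
                       ci_high=min(hi * scale, cap), multiplicity=multiplicity)


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple[float, float]:
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


def classify_clonal(est: CCFEstimate, *, ci_threshold: float = 0.9,
                    ccf_threshold: float = 0.7) -> str:
    """Clonal iff the CI upper bound reaches ``ci_threshold`` and the point
    estimate reaches ``ccf_threshold``; otherwise subclonal."""
    clonal = est.ci_high >= ci_threshold and est.ccf >= ccf_threshold
    est.clonal_flag = clonal
    return "clonal" if clonal else "subclonal"


def _pi_closed_form(n1: int, n2: int, state: str) -> float:
    denom = n1 + 2.0 * n2
    if state == "2+1":
        pi = 3.0 * n2 / denom
    else:  # 2+0 and 2+2 share the estimator
        pi = 2.0 * n2 / denom
    return float(np.clip(pi, 0.0, 1.0))


def time_gain(n1: int, n2: int, state: str, *, sample_id: str = "",
              region: str = "", n_boot: int = 1000,
              seed: int | None = 0) -> GainTiming:
    """Molecular time pi of a gain from clonal multiplicity counts.

    CI is a percentile bootstrap over the (n1, n2) multinomial. Counts
    must come from clonal mutations inside the gained region only.
    """
    if state not in GAIN_STATES:
        raise ValueError(f"state must be one of {GAIN_STATES}")
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    n = n1 + n2
    if n == 0:
        raise ValueError("no clonal mutations in region: pi is unidentifiable")
    pi = _pi_closed_form(n1, n2, state)
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, n2 / n, size=n_boot)
    boot = np.array([_pi_closed_form(n - d, d, state) for d in draws])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return GainTiming(sample_id=sample_id, region=region, state=state,
                      n1=n1, n2=n2, pi=pi, ci_low=float(lo), ci_high=float(hi))


def time_wgd(gain_counts: list[tuple[int, int]], *, sample_id: str = "",
             n_boot: int = 1000, seed: int | None = 0) -> GainTiming:
    """Time whole-genome duplication by pooling (n1, n2) over 2+2 segments."""
    if not gain_counts:
        raise ValueError("no 2+2 segments: WGD timing not applicable")
    n1 = int(sum(c[0] for c in gain_counts))
    n2 = int(sum(c[1] for c in gain_counts))
    return time_gain(n1, n2, "2+2", sample_id=sample_id, region="WGD",
                     n_boot=n_boot, seed=seed)


def assign_mutation_timing(clonal: bool, state: str, multiplicity: int) -> str:
    """Place one mutation in {early-clonal, late-clonal, clonal-NA, subclonal}.

    Subclonal mutations are late by definition. In a gained region a
    clonal mutation at multiplicity 2 predates the gain (early); at
    multiplicity 1 it postdates it (late). Outside gained states the
    clonal epoch is not resolvable.
    """
    if not clonal:
        return "subclonal"
    if state in GAIN_STATES:
        return "early-clonal" if multiplicity >= 2 else "late-clonal"
    return "clonal-NA"


def estimate_clock_rate(clonal_burden: float, age: float) -> float:
    """Clonal mutations per year, mu = B / A; optionally restrict B to a
    clock-like (SBS1/SBS5/SBS40-attributed) subset upstream."""
    if age <= 0:
        raise ValueError("age must be positive")
    if clonal_burden == 0:
        warnings.warn("zero clonal burden: clock rate is 0", stacklevel=2)
    return clonal_burden / age


def convert_to_real_time(pi: float, age: float, clock: ClockModel, *,
                         pi_ci: tuple[float, float] | None = None,
                         event_id: str = "") -> RealTimeEstimate:
    """Map molecular time pi to years before sampling through the clock.

    With M = c + k(1-c) total mutation-units over life, calendar fraction
    t = pi*M while pi*M <= c (pre-initiation), else c + (pi*M - c)/k.
    k=1 reduces exactly to age*(1-pi). Output is monotone decreasing in pi.
    """
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")

    def _years(p: float) -> float:
        k, c = clock.acceleration, clock.initiation_fraction
        m_total = c + k * (1.0 - c)
        mu_t = p * m_total
        t_cal = mu_t if mu_t <= c else c + (mu_t - c) / k
        return age * (1.0 - t_cal)

    years = _years(pi)
    if pi_ci is not None:
        lo, hi = _years(min(max(pi_ci[1], 0.0), 1.0)), _years(min(max(pi_ci[0], 0.0), 1.0))
    else:
        lo = hi = years
    return RealTimeEstimate(event_id=event_id, years_before_sampling=years,
                            ci_low=lo, ci_high=hi)


def count_clonal_multiplicities(alt: np.ndarray, depth: np.ndarray,
                                purity: float, major_cn: int, minor_cn: int,
                                *, cap: float = 1.5, alpha: float = 0.05,
                                ci_threshold: float = 0.9,
                                ccf_threshold: float = 0.7) -> tuple[int, int]:
    """Vectorised (n1, n2) clonal multiplicity counts for one region.

    Applies estimate_multiplicity, compute_ccf and classify_clonal to
    arrays of read counts and returns the clonal multiplicity-1 and
    multiplicity>=2 totals used by time_gain.
    """
    alt = np.asarray(alt, float)
    depth = np.asarray(depth, float)
    if (depth <= 0).any():
        raise ValueError("total_depth must be positive")
    cnt = major_cn + minor_cn
    vaf = alt / depth
    m_raw = vaf / purity * (purity * cnt + 2.0 * (1.0 - purity))
    m = np.clip(np.floor(m_raw + 0.5), 1, max(major_cn, 1)).astype(int)
    scale = (purity * cnt + 2.0 * (1.0 - purity)) / (purity * m)
    ccf = np.minimum(vaf * scale, cap)
    hi = np.where(alt == depth, 1.0,
                  stats.beta.ppf(1 - alpha / 2, alt + 1, depth - alt))
    ci_high = np.minimum(hi * scale, cap)
    clonal = (ci_high >= ci_threshold) & (ccf >= ccf_threshold)
    n2 = int(np.sum(clonal & (m >= 2)))
    n1 = int(np.sum(clonal & (m == 1)))
    return n1, n2


def pi_grid_mle(n1: int, n2: int, state: str, grid_step: float = 1e-4) -> float:
    """Brute-force multinomial maximum-likelihood estimate of pi.

    Independent check of the closed forms: maximises the two-category
    multinomial likelihood over a pi grid using the accrual model's
    expected category probabilities.
    """
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    if state == "2+1":
        e2, e1 = grid, 3.0 - 2.0 * grid
    else:  # 2+0 and 2+2 normalise to the same category probability
        e2, e1 = grid, 2.0 * (1.0 - grid)
    total = e1 + e2
    p2 = np.where(total > 0, e2 / total, 0.0)
    p1 = 1.0 - p2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = n1 * np.log(p1) + n2 * np.log(p2)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    if n1 == 0:
        ll[p2 == 1.0] = 0.0
    if n2 == 0:
        ll[p2 == 0.0] = 0.0
    return float(grid[int(np.argmax(ll))])
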