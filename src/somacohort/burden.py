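"""Non-coding element burden testing.

Per-element expected mutation counts come from 96-channel trinucleotide
context rates fitted on passenger mutations, scaled by per-sample
exposure factors; the observed count is tested against a negative
binomial background. P-values from several methods are combined with
Empirical Brown's method (an empirically scaled chi-square that accounts
for inter-method correlation) and adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from somacohort.simulate import CHANNELS_96, TRINUCLEOTIDES


@dataclass
class BurdenResult:
    element_id: str
    observed: int
    expected: float
    p_value: float
    q_value: float = float("nan")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone enforced)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def context_rates(passengers: pd.DataFrame,
                  opportunity: dict[str, float]) -> pd.Series:
    """Per-channel mutation rate = count / context opportunity.

    ``passengers`` needs a ``trinucleotide`` column (pyrimidine-centred
    3-mer); with an ``alt`` column the full 96-channel spectrum
    ("ACA>T"-keyed) is returned, otherwise the 32 collapsed contexts.
    ``opportunity`` maps context -> number of genome positions
    presenting that context. By construction
    sum(rate * opportunity(context)) equals the total count.
    """
    if "alt" in passengers.columns:
        keys = [f"{c}>{a}" for c, a in CHANNELS_96]
        counts = (passengers["trinucleotide"] + ">"
                  + passengers["alt"]).value_counts()
    else:
        keys = list(TRINUCLEOTIDES)
        counts = passengers["trinucleotide"].value_counts()
    rates = {}
    for key in keys:
        ctx = key.split(">")[0]
        opp = opportunity.get(ctx, 0.0)
        k = int(counts.get(key, 0))
        if opp <= 0:
            if k:
                warnings.warn(f"context {ctx} has zero opportunity", stacklevel=2)
            rates[key] = 0.0
        else:
            rates[key] = k / opp
    return pd.Series(rates)


def collapse_context_rates(rates: pd.Series) -> pd.Series:
    """Sum 96-channel rates down to the 32 trinucleotide contexts."""
    if not any(">" in str(k) for k in rates.index):
        return rates
    ctx = pd.Index([str(k).split(">")[0] for k in rates.index])
    return rates.groupby(ctx).sum().reindex(TRINUCLEOTIDES).fillna(0.0)


def sample_exposure_factors(passengers: pd.DataFrame) -> pd.Series:
    """Per-sample passenger burden divided by the cohort mean burden."""
    burden = passengers.groupby("sample_id").size().astype(float)
    return burden / burden.mean()


def element_burden_test(elements: pd.DataFrame, observed: pd.Series,
                        rates: pd.Series, sample_factors: pd.Series,
                        dispersion: float = 0.1) -> list[BurdenResult]:
    """Negative-binomial upper-tail burden test per element.

    ``elements`` maps element_id -> context opportunity columns (one per
    trinucleotide, giving positions of that context in the element).
    expected = sum_ctx rate(ctx) * opportunity(ctx) * sum(sample factors).
    p = P(X >= observed) under NB(mean=expected, alpha=dispersion);
    dispersion alpha is the var=(mu + alpha mu^2) parameterisation and
    should be fitted upstream on passenger elements.
    """
    ctx_rates = collapse_context_rates(rates)
    total_exposure = float(sample_factors.sum())
    results = []
    for _, row in elements.iterrows():
        eid = row["element_id"]
        opp = np.array([row.get(ctx, 0.0) for ctx in TRINUCLEOTIDES], float)
        if opp.sum() <= 0:
            raise ValueError(f"element {eid} has zero opportunity")
        mu = float(np.sum(opp * ctx_rates.reindex(TRINUCLEOTIDES).fillna(0.0)
                          .to_numpy()) * total_exposure)
        obs = int(observed.get(eid, 0))
        p = _nb_upper_tail(obs, mu, dispersion)
        results.append(BurdenResult(element_id=eid, observed=obs,
                                    expected=mu, p_value=p))
    qs = bh_adjust(np.array([r.p_value for r in results]))
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def _nb_upper_tail(k: int, mu: float, alpha: float) -> float:
    """P(X >= k) for NB with mean mu and variance mu + alpha*mu^2."""
    if mu <= 0:
        return 1.0
    if alpha <= 0:
        return float(stats.poisson.sf(k - 1, mu))
    size = 1.0 / alpha
    prob = size / (size + mu)
    return float(stats.nbinom.sf(k - 1, size, prob))


def combine_empirical_brown(p_matrix: np.ndarray,
                            force_independent: bool = False) -> np.ndarray:
    """Empirical Brown's method across columns (methods) of a p matrix.

    Per element the statistic is S = sum_m -2 ln p_m. The empirical
    covariance of -2 ln p across elements gives E[S] = 2k and
    Var[S] = 4k + 2 sum_{i<j} cov_ij; the combined p is the upper tail
    of a scaled chi-square with scale c = Var/(2E) and df f = 2E^2/Var.
    With a diagonal covariance (``force_independent``) this is exactly
    Fisher's method.
    """
    p = np.asarray(p_matrix, float)
    if p.ndim == 1:
        p = p[:, None]
    n_elem, k = p.shape
    if (p <= 0).any():
        warnings.warn("zero p-values clamped to machine minimum", stacklevel=2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if k == 1:
        return p[:, 0].copy()
    if n_elem < 20 and not force_independent:
        warnings.warn("fewer than 20 elements: covariance estimate is noisy",
                      stacklevel=2)
    x = -2.0 * np.log(p)
    s = x.sum(axis=1)
    expected = 2.0 * k
    if force_independent:
        cov_sum = 0.0
    else:
        cov = np.cov(x, rowvar=False)
        iu = np.triu_indices(k, 1)
        cov_sum = float(cov[iu].sum())
    variance = 4.0 * k + 2.0 * cov_sum
    variance = max(variance, 1e-12)
    c = variance / (2.0 * expected)
    f = 2.0 * expected ** 2 / variance
    return stats.chi2.sf(s / c, f)
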