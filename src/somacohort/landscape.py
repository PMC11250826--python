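"""Driver-landscape summaries: frequencies, co-occurrence/exclusivity,
pathogenicity contrast and the headline-fraction report."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from somacohort.burden import bh_adjust


@dataclass
class TestResult:
    pair: tuple[str, str]
    statistic: float  # odds ratio of the 2x2
    p_value: float
    q_value: float
    direction: str  # co-occurring | exclusive


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, for report parity (72.35 -> 72.4)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: float, n: float, ndigits: int = 1) -> float:
    if n <= 0:
        raise ZeroDivisionError("zero denominator")
    return round_half_up(100.0 * k / n, ndigits)


def driver_frequencies(mutations: pd.DataFrame, sample_ids: list[str],
                       gene_list: list[str],
                       nonsynonymous=("missense", "truncating", "inframe"),
                       ) -> pd.DataFrame:
    """Fraction of tumours with >= 1 nonsynonymous mutation per gene.

    A sample counts once per gene regardless of mutation count.
    """
    if not gene_list:
        raise ValueError("gene list must be non-empty")
    n = len(sample_ids)
    sub = mutations[mutations["consequence"].isin(nonsynonymous)
                    & mutations["gene"].isin(gene_list)]
    hits = sub.drop_duplicates(["sample_id", "gene"]).groupby("gene").size()
    rows = [dict(gene=g, n_mutated=int(hits.get(g, 0)),
                 frequency=float(hits.get(g, 0)) / n) for g in gene_list]
    return pd.DataFrame(rows)


def cooccurrence_test(matrix: pd.DataFrame) -> list[TestResult]:
    """Pairwise Fisher exact tests on a binary sample x gene matrix.

    Two-sided p per pair; direction from the sample odds ratio;
    Benjamini-Hochberg across all tested pairs. Genes constant across
    the cohort are skipped (their tables are degenerate).
    """
    genes = list(matrix.columns)
    if len(genes) < 2 or len(matrix) < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    usable = [g for g in genes if 0 < matrix[g].sum() < len(matrix)]
    skipped = sorted(set(genes) - set(usable))
    if skipped:
        import warnings
        warnings.warn(f"constant genes skipped: {skipped}", stacklevel=2)
    pairs, pvals, ors = [], [], []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            x = matrix[usable[i]].astype(bool)
            y = matrix[usable[j]].astype(bool)
            a = int((x & y).sum())
            b = int((x & ~y).sum())
            c = int((~x & y).sum())
            d = int((~x & ~y).sum())
            or_, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            pairs.append((usable[i], usable[j]))
            pvals.append(p)
            ors.append(or_)
    qvals = bh_adjust(np.array(pvals)) if pvals else np.array([])
    return [TestResult(pair=pr, statistic=float(o), p_value=float(p),
                       q_value=float(q),
                       direction="co-occurring" if o > 1 else "exclusive")
            for pr, o, p, q in zip(pairs, ors, pvals, qvals)]


def pathogenicity_contrast(k_driver: int, n_driver: int,
                           k_nondriver: int | None = None,
                           n_nondriver: int | None = None) -> dict:
    """Pathogenic proportions among driver vs non-driver missense SNVs.

    Returns percentages rounded half-up to one decimal, plus (when both
    groups are given) a two-sided chi-squared association p with
    continuity correction on the 2x2.
    """
    if n_driver <= 0:
        raise ZeroDivisionError("zero driver denominator")
    out = {"driver_percent": percent(k_driver, n_driver)}
    if n_nondriver is not None:
        if n_nondriver <= 0:
            raise ZeroDivisionError("zero non-driver denominator")
        out["nondriver_percent"] = percent(k_nondriver, n_nondriver)
        table = [[k_driver, n_driver - k_driver],
                 [k_nondriver, n_nondriver - k_nondriver]]
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        out["chi2"] = float(chi2)
        out["p_value"] = float(p)
    return out


def cohort_report(fractions: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Headline fraction table: name -> (numerator, denominator) in,
    counts and one-decimal percentages out."""
    rows = []
    for name, (k, n) in fractions.items():
        rows.append(dict(quantity=name, count=k, total=n,
                         percent=percent(k, n) if n > 0 else float("nan")))
    return pd.DataFrame(rows, columns=["quantity", "count", "total", "percent"])
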