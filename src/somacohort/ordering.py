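"""Cohort-level relative ordering of driver events (league model).

Per tumour, co-occurring events play pairwise "matches" decided by their
timing class (early-clonal beats late-clonal beats subclonal; copy-number
events compare by molecular time pi). Cohort-wide win/loss/tie counts are
fit with a Bradley-Terry model by minorisation-maximisation, events are
ranked by strength, and confidence intervals on the average finishing
position come from a bootstrap over tumours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# timing-class rank: lower = earlier; clonal-NA ties with both clonal classes
_CLASS_RANK = {"early-clonal": 0, "late-clonal": 1, "subclonal": 2}
PI_TIE_MARGIN = 0.05


@dataclass
class LeagueResult:
    event: str
    mean_position: float
    ci_low: float
    ci_high: float
    n_tumours: int


@dataclass
class OddsResult:
    event: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_clonal: int
    n_subclonal: int
    rest_clonal: int
    rest_subclonal: int


def _match(call_a, call_b) -> int:
    """Return +1 if a precedes b, -1 if b precedes a, 0 for a tie.

    Calls are either timing-class strings or floats (pi for CNAs).
    pi values compare with a tie margin; a CNA against a mutation class
    maps pi to early/late at 0.5 (a coarse but symmetric rule).
    """
    a_num, b_num = isinstance(call_a, float), isinstance(call_b, float)
    if a_num and b_num:
        if abs(call_a - call_b) <= PI_TIE_MARGIN:
            return 0
        return 1 if call_a < call_b else -1
    if a_num:
        call_a = "early-clonal" if call_a <= 0.5 else "late-clonal"
    if b_num:
        call_b = "early-clonal" if call_b <= 0.5 else "late-clonal"
    if call_a == "clonal-NA" or call_b == "clonal-NA":
        if call_a == "subclonal":
            return -1
        if call_b == "subclonal":
            return 1
        return 0
    ra, rb = _CLASS_RANK[call_a], _CLASS_RANK[call_b]
    return 0 if ra == rb else (1 if ra < rb else -1)


def pairwise_precedence(event_calls: pd.DataFrame) -> pd.DataFrame:
    """Win/loss/tie counts per ordered event pair across tumours.

    ``event_calls`` has columns sample_id, event, call (timing class or
    pi float). Returns a DataFrame indexed by (event_a, event_b) with
    wins (a before b), losses and ties; wins+losses+ties equals the
    number of tumours where both events are called.
    """
    counts: dict[tuple[str, str], np.ndarray] = {}
    for _, grp in event_calls.groupby("sample_id", sort=False):
        evs = grp["event"].to_list()
        calls = grp["call"].to_list()
        for i in range(len(evs)):
            for j in range(i + 1, len(evs)):
                a, b = evs[i], evs[j]
                res = _match(calls[i], calls[j])
                if a > b:
                    a, b, res = b, a, -res
                rec = counts.setdefault((a, b), np.zeros(3, int))
                rec[0 if res > 0 else (1 if res < 0 else 2)] += 1
    rows = [dict(event_a=a, event_b=b, wins=int(v[0]), losses=int(v[1]),
                 ties=int(v[2])) for (a, b), v in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["event_a", "event_b", "wins",
                                       "losses", "ties"])


def _bt_strengths(events: list[str], matrix: pd.DataFrame,
                  n_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Bradley-Terry strengths by MM iteration; ties count half a win
    for each side. Events with no comparisons get strength NaN."""
    idx = {e: i for i, e in enumerate(events)}
    k = len(events)
    wins = np.zeros((k, k))
    for _, r in matrix.iterrows():
        a, b = idx[r["event_a"]], idx[r["event_b"]]
        wins[a, b] += r["wins"] + 0.5 * r["ties"]
        wins[b, a] += r["losses"] + 0.5 * r["ties"]
    n_games = wins + wins.T
    played = n_games.sum(axis=1) > 0
    p = np.ones(k)
    w_tot = wins.sum(axis=1)
    for _ in range(n_iter):
        denom = np.zeros(k)
        for i in range(k):
            if not played[i]:
                continue
            js = n_games[i] > 0
            denom[i] = np.sum(n_games[i, js] / (p[i] + p[js]))
        new = np.where(denom > 0, w_tot / np.maximum(denom, 1e-300), p)
        new = np.clip(new, 1e-12, None)
        new = new / np.exp(np.mean(np.log(new[played]))) if played.any() else new
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    p[~played] = np.nan
    return p


def _positions(strengths: np.ndarray) -> np.ndarray:
    """Finishing positions (1 = earliest/strongest), average ranks on ties."""
    order = pd.Series(-strengths).rank(method="average").to_numpy()
    return order


def run_league(event_calls: pd.DataFrame, n_boot: int = 1000,
               seed: int | None = 0) -> list[LeagueResult]:
    """Fit the league model and bootstrap finishing-position CIs.

    The bootstrap resamples tumours (the independent units), recomputes
    the precedence matrix and re-ranks.
    """
    events = sorted(event_calls["event"].unique())
    matrix = pairwise_precedence(event_calls)
    base_pos = _positions(_bt_strengths(events, matrix))
    n_contrib = event_calls.groupby("event")["sample_id"].nunique()

    samples = event_calls["sample_id"].unique()
    rng = np.random.default_rng(seed)
    groups = {s: g for s, g in event_calls.groupby("sample_id", sort=False)}
    boot_pos = np.full((n_boot, len(events)), np.nan)
    for b in range(n_boot):
        pick = rng.choice(samples, size=len(samples), replace=True)
        parts = []
        for r, s in enumerate(pick):
            g = groups[s].copy()
            g["sample_id"] = f"b{r}"
            parts.append(g)
        calls_b = pd.concat(parts, ignore_index=True)
        boot_pos[b] = _positions(_bt_strengths(events, pairwise_precedence(calls_b)))
    results = []
    for i, e in enumerate(events):
        col = boot_pos[:, i]
        col = col[~np.isnan(col)]
        lo, hi = (np.percentile(col, [2.5, 97.5]) if len(col)
                  else (np.nan, np.nan))
        results.append(LeagueResult(event=e, mean_position=float(base_pos[i]),
                                    ci_low=float(lo), ci_high=float(hi),
                                    n_tumours=int(n_contrib.get(e, 0))))
    return results


def clonality_odds(counts: pd.DataFrame) -> list[OddsResult]:
    """Per-gene odds of clonality relative to all other driver genes.

    ``counts`` has columns gene, clonal, subclonal. OR from the 2x2 of
    (gene vs rest) x (clonal vs subclonal) with a Haldane-Anscombe 0.5
    correction when any cell is zero; Wald CI on the log OR.
    """
    tot_c = counts["clonal"].sum()
    tot_s = counts["subclonal"].sum()
    out = []
    for _, r in counts.iterrows():
        a, b = float(r["clonal"]), float(r["subclonal"])
        c, d = float(tot_c - r["clonal"]), float(tot_s - r["subclonal"])
        cells = np.array([a, b, c, d])
        if (cells == 0).any():
            cells = cells + 0.5
        aa, bb, cc, dd = cells
        or_ = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        out.append(OddsResult(
            event=r["gene"], odds_ratio=float(or_),
            ci_low=float(or_ * np.exp(-1.959964 * se)),
            ci_high=float(or_ * np.exp(1.959964 * se)),
            n_clonal=int(r["clonal"]), n_subclonal=int(r["subclonal"]),
            rest_clonal=int(tot_c - r["clonal"]),
            rest_subclonal=int(tot_s - r["subclonal"])))
    return out
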