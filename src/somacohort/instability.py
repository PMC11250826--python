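"""Genome instability: WGD calling, wGII, TMB and arm-level recurrence."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from somacohort.burden import bh_adjust


def call_wgd(ploidy: float, loh_fraction: float) -> bool:
    """Whole-genome duplication iff ploidy > 2.9 - 2 * loh_fraction.

    The common pan-cancer rule: genome-doubled tumours sit above a line
    trading ploidy against the fraction of the genome with LOH.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if not 0 <= loh_fraction <= 1:
        raise ValueError("loh_fraction must lie in [0, 1]")
    return ploidy > 2.9 - 2.0 * loh_fraction


def compute_wgii(segments: pd.DataFrame, ploidy: float | None = None,
                 baseline: int | None = None) -> float:
    """Weighted genome instability index.

    Per autosome: length-weighted fraction of the covered genome whose
    total copy number differs from the baseline (round(ploidy) by
    default, or 2). wGII is the unweighted mean over autosomes so large
    and small chromosomes contribute equally.
    """
    if baseline is None:
        if ploidy is None:
            raise ValueError("provide ploidy or an explicit baseline")
        base = int(np.floor(ploidy + 0.5))
    else:
        base = int(baseline)
    fractions = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        lengths = (grp["end"] - grp["start"]).to_numpy(float)
        covered = lengths.sum()
        if covered <= 0:
            warnings.warn(f"chromosome {chrom} has zero covered length; excluded",
                          stacklevel=2)
            continue
        total_cn = (grp["major_cn"] + grp["minor_cn"]).to_numpy()
        aberrant = lengths[total_cn != base].sum()
        fractions.append(aberrant / covered)
    if not fractions:
        raise ValueError("no covered autosomes")
    return float(np.mean(fractions))


def compute_tmb(mutations: pd.DataFrame, callable_mb: float,
                hypermutator_threshold: float = 10.0) -> dict:
    """SNV/Mb and indel/Mb over a callable-genome denominator.

    SNVs are single-base ref/alt rows; everything else counts as indel.
    Values are reported to two decimals; an SNV/Mb above the threshold
    sets the hypermutator flag.
    """
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    is_snv = (mutations["ref"].str.len() == 1) & (mutations["alt"].str.len() == 1)
    snv_mb = round(float(is_snv.sum()) / callable_mb, 2)
    indel_mb = round(float((~is_snv).sum()) / callable_mb, 2)
    return {"snv_per_mb": snv_mb, "indel_per_mb": indel_mb,
            "hypermutator": snv_mb > hypermutator_threshold}


def call_arms(segments: pd.DataFrame, arm_bounds: pd.DataFrame,
              baseline: int = 2, fraction: float = 0.5) -> pd.DataFrame:
    """Arm-level gain/loss/neutral calls from segments.

    ``arm_bounds`` has columns chrom/arm/start/end (0-based half-open).
    An arm is called gained (lost) if >= ``fraction`` of its covered
    length has total CN above (below) the baseline.
    """
    rows = []
    for sid, sgrp in segments.groupby("sample_id", sort=False):
        for _, a in arm_bounds.iterrows():
            seg = sgrp[sgrp["chrom"] == a["chrom"]]
            ov_start = np.maximum(seg["start"].to_numpy(), a["start"])
            ov_end = np.minimum(seg["end"].to_numpy(), a["end"])
            ov = np.maximum(ov_end - ov_start, 0).astype(float)
            covered = ov.sum()
            call = "neutral"
            if covered > 0:
                total_cn = (seg["major_cn"] + seg["minor_cn"]).to_numpy()
                gain = ov[total_cn > baseline].sum() / covered
                loss = ov[total_cn < baseline].sum() / covered
                if gain >= fraction:
                    call = "gain"
                elif loss >= fraction:
                    call = "loss"
            rows.append(dict(sample_id=sid, arm=a["arm"], call=call))
    return pd.DataFrame(rows, columns=["sample_id", "arm", "call"])


def arm_recurrence(arm_calls: pd.DataFrame, n_perm: int = 10_000,
                   seed: int | None = 0) -> pd.DataFrame:
    """Per-arm recurrence test against a within-sample permutation null.

    Each permutation shuffles the arm labels within every sample,
    preserving that sample's total number of gains and losses exactly.
    Per arm and direction, p = fraction of permutations with frequency
    >= observed; BH across arms x directions.
    """
    samples = arm_calls["sample_id"].unique()
    if len(samples) < 2:
        raise ValueError("need >= 2 samples for a permutation null")
    arms = sorted(arm_calls["arm"].unique())
    arm_ix = {a: i for i, a in enumerate(arms)}
    mats = {"gain": np.zeros((len(samples), len(arms)), int),
            "loss": np.zeros((len(samples), len(arms)), int)}
    for si, sid in enumerate(samples):
        grp = arm_calls[arm_calls["sample_id"] == sid]
        for _, r in grp.iterrows():
            if r["call"] in mats:
                mats[r["call"]][si, arm_ix[r["arm"]]] = 1

    rng = np.random.default_rng(seed)
    rows = []
    pvals = []
    exceed = {d: np.zeros(len(arms)) for d in mats}
    obs = {d: mats[d].sum(axis=0) for d in mats}
    for _ in range(n_perm):
        perm_counts = {d: np.zeros(len(arms)) for d in mats}
        for si in range(len(samples)):
            order = rng.permutation(len(arms))
            for d in mats:
                row = mats[d][si]
                assert row.sum() == row[order].sum()  # row sums preserved
                perm_counts[d] += row[order]
        for d in mats:
            exceed[d] += perm_counts[d] >= obs[d]
    for d in mats:
        p = (exceed[d] + 1.0) / (n_perm + 1.0)
        for ai, arm in enumerate(arms):
            rows.append(dict(arm=arm, direction=d, n_altered=int(obs[d][ai]),
                             frequency=float(obs[d][ai]) / len(samples),
                             p_value=float(p[ai])))
            pvals.append(float(p[ai]))
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(np.array(pvals))
    return df
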