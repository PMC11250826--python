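"""Synthetic tumour-cohort generator with planted ground truth.

Emulates the inputs of a whole-genome renal-cancer cohort study on a
reduced synthetic genome: per-tumour SNV tables with read counts,
allele-specific copy-number segments with purity/ploidy, structural
variants over covariate tracks, immune-escape annotations and clinical
outcome columns. Every latent quantity a downstream stage estimates
(gain time pi, mutation multiplicity, clonality, hotspot intervals,
escape mechanisms, log hazard ratios, driver interaction log-odds) is
recorded in a TruthSet so that recovery can be tested.

Defaults follow the cohort the package models: 778 tumours, mean age 63
(range 25-88), driver marginals VHL 0.80 / PBRM1 0.50 / SETD2 0.18 /
BAP1 0.12, whole-genome duplication in 16.6% of tumours, HLA LOH 5.9%,
HLA mutation 0.5%, APG inactivation 3.1%, and a protective VHL log
hazard ratio of ln 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from somacohort.cohort import (
    CLINICAL_COLUMNS,
    GENE_COLUMNS,
    MUTATION_COLUMNS,
    SEGMENT_COLUMNS,
    SV_COLUMNS,
    CohortBundle,
    CovariateTrack,
)

TRINUCLEOTIDES = [
    f"{five}{mid}{three}"
    for mid in "CT" for five in "ACGT" for three in "ACGT"
]
_PYRIMIDINE_SUBS = {"C": ["A", "G", "T"], "T": ["A", "C", "G"]}
CHANNELS_96 = [
    (ctx, alt) for ctx in TRINUCLEOTIDES for alt in _PYRIMIDINE_SUBS[ctx[1]]
]

STATE_TOTAL_CN = {"2+1": 3, "2+0": 2, "2+2": 4, "1+1": 2}
STATE_MAJOR_MINOR = {"2+1": (2, 1), "2+0": (2, 0), "2+2": (2, 2), "1+1": (1, 1)}


def multiplicity_two_probability(state: str, pi: float) -> float:
    """P(multiplicity 2) for a clonal mutation in a gained region.

    From the accrual model: 2+1 -> pi/(3-pi); 2+0 and 2+2 -> pi/(2-pi).
    """
    if state == "2+1":
        return pi / (3.0 - pi)
    if state in ("2+0", "2+2"):
        return pi / (2.0 - pi)
    raise ValueError(f"not a timeable gain state: {state}")


@dataclass
class GainSpec:
    """One planted gain: state, true molecular time, expected mutations."""

    state: str
    pi_true: float
    n_expected: float = 500.0


@dataclass
class HotspotSpec:
    """A planted SV hotspot: bin index range [start, end) and fold >= 1."""

    chrom: str
    bin_start: int
    bin_end: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("hotspot fold must be >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    n_tumours: int = 778
    purity_range: tuple[float, float] = (0.3, 0.9)
    mean_depth: float = 80.0
    driver_genes: dict[str, float] = field(default_factory=lambda: {
        "VHL": 0.80, "PBRM1": 0.50, "SETD2": 0.18, "BAP1": 0.12})
    interaction_log_odds: dict[tuple[str, str], float] = field(default_factory=dict)
    driver_subclonal_fraction: float = 0.10
    gain_specs: list[GainSpec] = field(default_factory=lambda: [
        GainSpec("2+1", 0.25, 500.0), GainSpec("2+0", 0.45, 500.0)])
    wgd_probability: float = 0.166
    wgd_pi: float = 0.75
    wgd_n_expected: float = 800.0
    passenger_per_tumour: float = 150.0
    context_weights: np.ndarray | None = None  # 96-channel, default uniform
    # reduced genome
    n_chroms: int = 22
    chrom_length: int = 10_000_000
    bin_size: int = 100_000
    # structural variants
    sv_base_rate: float = 0.02  # breakends per bin per tumour-free scale
    sv_covariate_effects: dict[str, float] = field(default_factory=dict)
    hotspots: list[HotspotSpec] = field(default_factory=list)
    # immune escape
    hla_loh_rate: float = 0.059
    hla_mutation_rate: float = 0.005
    apg_inactivation_rate: float = 0.031
    apg_genes: tuple[str, ...] = ("TAP1", "TAP2", "TAPBP", "B2M", "CALR", "ERAP1")
    # survival
    baseline_hazard: float = 1.0 / 2000.0  # per day
    log_hrs: dict[str, float] = field(default_factory=lambda: {
        "VHL": math.log(0.6)})
    censoring_rate: float = 0.4
    # clock
    mutations_per_year: float = 50.0
    clock_acceleration: float = 1.0
    initiation_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_tumours < 1:
            raise ValueError("n_tumours must be >= 1")
        for g, p in self.driver_genes.items():
            if not 0 <= p <= 1:
                raise ValueError(f"marginal frequency of {g} outside [0, 1]")
        if not 0 <= self.wgd_probability <= 1:
            raise ValueError("wgd_probability outside [0, 1]")


@dataclass
class TruthSet:
    """Planted latent values, keyed so every truth maps to emitted records."""

    gain_truth: pd.DataFrame       # sample_id, region, state, pi_true
    mutation_truth: pd.DataFrame   # aligned to bundle.mutations rows
    hotspot_truth: pd.DataFrame    # chrom, start, end, fold
    escape_truth: pd.DataFrame     # sample_id, escape, mechanisms
    log_hrs: dict[str, float]
    interaction_log_odds: dict[tuple[str, str], float]
    driver_status: pd.DataFrame    # sample_id x gene binary


# ---------------------------------------------------------------------------
# driver genotypes: exact Ising-like sampler

def _ising_distribution(h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Probability over all 2^G binary genotypes for fields h, couplings J."""
    g = len(h)
    configs = ((np.arange(2 ** g)[:, None] >> np.arange(g)) & 1).astype(float)
    energy = configs @ h
    for i in range(g):
        for j in range(i + 1, g):
            if J[i, j] != 0.0:
                energy = energy + J[i, j] * configs[:, i] * configs[:, j]
    energy -= energy.max()
    w = np.exp(energy)
    return w / w.sum()


def _calibrate_fields(targets: np.ndarray, J: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Per-gene fields hit the target marginals under couplings J, by
    coordinate-wise damped fixed-point iteration (logit matching)."""
    g = len(targets)
    h = np.log(np.clip(targets, 1e-12, 1 - 1e-12) /
               np.clip(1 - targets, 1e-12, 1))
    configs = ((np.arange(2 ** g)[:, None] >> np.arange(g)) & 1).astype(float)
    for _ in range(max_iter):
        p = _ising_distribution(h, J)
        marg = configs.T @ p
        if np.abs(marg - targets).max() < tol:
            return h
        with np.errstate(divide="ignore"):
            adjust = (np.log(np.clip(targets, 1e-12, 1)) - np.log(np.clip(marg, 1e-300, 1))
                      - np.log(np.clip(1 - targets, 1e-12, 1))
                      + np.log(np.clip(1 - marg, 1e-300, 1)))
        h = h + adjust
        if not np.isfinite(h).all():
            break
    p = _ising_distribution(h, J)
    marg = configs.T @ p
    if np.abs(marg - targets).max() > 1e-3:
        raise ValueError("interaction spec infeasible: target marginals "
                         f"unreachable (closest: {np.round(marg, 4)})")
    return h


def sample_driver_genotypes(genes: dict[str, float],
                            interactions: dict[tuple[str, str], float],
                            n_tumours: int, rng: np.random.Generator) -> pd.DataFrame:
    """Binary gene-by-sample driver matrix with calibrated marginals and
    pairwise interaction log-odds (negative = mutual exclusivity)."""
    names = list(genes)
    targets = np.array([genes[g] for g in names])
    J = np.zeros((len(names), len(names)))
    for (a, b), lo in interactions.items():
        i, j = names.index(a), names.index(b)
        J[i, j] = J[j, i] = lo
    J = np.where(np.isneginf(J), -1e6, J)  # -inf log-odds: forbid co-occurrence
    h = _calibrate_fields(targets, J)
    p = _ising_distribution(h, J)
    draws = rng.choice(len(p), size=n_tumours, p=p)
    configs = ((draws[:, None] >> np.arange(len(names))) & 1).astype(bool)
    return pd.DataFrame(configs, columns=names)


# ---------------------------------------------------------------------------
# timed segments

def simulate_timed_segment(state: str, pi_true: float, n_expected: float,
                           purity: float, mean_depth: float,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Clonal mutations in a gained region under the accrual model.

    Multiplicities are Bernoulli with the state's P(m=2); read depths are
    Poisson around ``mean_depth``; alt counts binomial at the expected
    VAF = purity*m / (purity*CNt + 2(1-purity)).
    """
    if n_expected <= 0:
        raise ValueError("n_expected must be positive")
    if not 0 <= pi_true <= 1:
        raise ValueError("pi_true must lie in [0, 1]")
    p2 = multiplicity_two_probability(state, pi_true)
    n = rng.poisson(n_expected)
    mult = np.where(rng.random(n) < p2, 2, 1)
    cnt = STATE_TOTAL_CN[state]
    depth = np.maximum(rng.poisson(mean_depth, size=n), 1)
    vaf = purity * mult / (purity * cnt + 2.0 * (1.0 - purity))
    alt = rng.binomial(depth, vaf)
    return pd.DataFrame({"alt_count": alt, "total_depth": depth,
                         "true_multiplicity": mult})


# ---------------------------------------------------------------------------
# structural variants over covariate tracks

def make_covariate_track(config: SimulationConfig,
                         rng: np.random.Generator) -> CovariateTrack:
    """Binned tracks for the six background covariates, standardised."""
    names = ["accessibility", "expression", "gc", "gene_density",
             "repeats", "replication_timing"]
    rows = []
    for c in range(1, config.n_chroms + 1):
        n_bins = config.chrom_length // config.bin_size
        for b in range(n_bins):
            rows.append((str(c), b * config.bin_size, (b + 1) * config.bin_size))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    values = {}
    for name in names:
        raw = rng.normal(size=len(bins))
        # mild smoothing: local genomic features are spatially correlated
        kernel = np.ones(5) / 5.0
        sm = np.convolve(raw, kernel, mode="same")
        values[name] = (sm - sm.mean()) / sm.std()
    return CovariateTrack(bins=bins, values=values)


def plant_sv_hotspots(track: CovariateTrack, base_rate: float,
                      hotspots: list[HotspotSpec], n_tumours: int,
                      rng: np.random.Generator,
                      covariate_effects: dict[str, float] | None = None,
                      simple_fraction: float = 0.85) -> pd.DataFrame:
    """SV records whose per-bin breakend counts are Poisson with mean
    base_rate * n_tumours * exp(covariate effects) * fold(bin).

    The SV count is Poisson(total/2) and both breakends of every SV are
    drawn iid proportional to the bin intensity, which Poissonises the
    per-bin counts exactly at the planted mean.
    """
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    log_mu = np.full(track.n_bins, np.log(max(base_rate * n_tumours, 1e-300)))
    for name, beta in (covariate_effects or {}).items():
        log_mu = log_mu + beta * np.asarray(track.values[name], float)
    fold = np.ones(track.n_bins)
    bins = track.bins
    for hs in hotspots:
        mask = (bins["chrom"] == hs.chrom).to_numpy()
        idx = np.flatnonzero(mask)[hs.bin_start:hs.bin_end]
        fold[idx] *= hs.fold
    mu = np.exp(log_mu) * fold
    if base_rate == 0:
        return pd.DataFrame(columns=SV_COLUMNS)
    total = mu.sum()
    n_sv = rng.poisson(total / 2.0)
    if n_sv == 0:
        return pd.DataFrame(columns=SV_COLUMNS)
    ends = rng.choice(track.n_bins, size=2 * n_sv, p=mu / total)
    starts = bins["start"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    width = track.bin_size
    pos = starts[ends] + rng.integers(0, width, size=2 * n_sv)
    e1, e2 = ends[:n_sv], ends[n_sv:]
    p1, p2 = pos[:n_sv], pos[n_sv:]
    classes = rng.choice(["DEL", "TD", "UNCLASSIFIED"], size=n_sv)
    complexity = np.where(rng.random(n_sv) < simple_fraction, "simple", "complex")
    sample_ids = [f"S{int(i):04d}" for i in rng.integers(0, n_tumours, size=n_sv)]
    return pd.DataFrame({
        "chrom1": chroms[e1], "start1": p1, "end1": p1 + 1,
        "chrom2": chroms[e2], "start2": p2, "end2": p2 + 1,
        "sample_id": sample_ids, "score": ".", "strand1": ".", "strand2": ".",
        "sv_class": classes, "complexity": complexity,
    }, columns=SV_COLUMNS)


# ---------------------------------------------------------------------------
# survival

def simulate_survival(features: pd.DataFrame, log_hrs: dict[str, float],
                      baseline_hazard: float, censoring_rate: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Event times from a proportional-hazards exponential model with
    independent exponential censoring tuned to the requested rate."""
    for f, b in log_hrs.items():
        if not np.isfinite(b):
            raise ValueError(f"non-finite log hazard ratio for {f}")
    lin = np.zeros(len(features))
    for f, b in log_hrs.items():
        lin = lin + b * features[f].to_numpy(float)
    hazard = baseline_hazard * np.exp(lin)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate >= 1.0:
        return t_event, np.zeros(len(features), dtype=bool)
    if censoring_rate <= 0.0:
        return t_event, np.ones(len(features), dtype=bool)
    cens_hazard = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
    t_cens = rng.exponential(1.0 / cens_hazard, size=len(features))
    observed = np.minimum(t_event, t_cens)
    return observed, t_event <= t_cens


# ---------------------------------------------------------------------------
# whole-cohort assembly

def _draw_context(rng: np.random.Generator, weights: np.ndarray | None,
                  size: int) -> tuple[np.ndarray, np.ndarray]:
    w = (np.ones(96) / 96.0 if weights is None
         else np.asarray(weights, float) / np.sum(weights))
    idx = rng.choice(96, size=size, p=w)
    ctx = np.array([CHANNELS_96[i][0] for i in idx])
    alt = np.array([CHANNELS_96[i][1] for i in idx])
    return ctx, alt


def generate_cohort(config: SimulationConfig, seed: int) -> tuple[CohortBundle, TruthSet]:
    """Deterministically generate a full cohort bundle plus its TruthSet."""
    rng = np.random.default_rng(seed)
    n = config.n_tumours
    sample_ids = [f"S{i:04d}" for i in range(n)]

    driver_status = sample_driver_genotypes(
        config.driver_genes, config.interaction_log_odds, n, rng)
    driver_status.insert(0, "sample_id", sample_ids)

    purity = rng.uniform(*config.purity_range, size=n)
    ages = np.clip(rng.normal(63.0, 10.0, size=n), 25, 88)
    wgd = rng.random(n) < config.wgd_probability

    chrom_len = config.chrom_length
    driver_names = list(config.driver_genes)
    gene_rows = []
    for gi, gene in enumerate(driver_names):
        chrom = str((gi % config.n_chroms) + 1)
        start = 1_000_000 + 200_000 * (gi // config.n_chroms)
        gene_rows.append((chrom, start, start + 60_000, gene, 2))
    genes_df = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)

    mut_rows: list[pd.DataFrame] = []
    seg_rows: list[tuple] = []
    gain_truth_rows: list[dict] = []
    ploidy_rows: list[dict] = []

    gain_chroms = [str(c) for c in range(config.n_chroms, 0, -1)]
    for si, sid in enumerate(sample_ids):
        rho = purity[si]
        state_by_chrom: dict[str, str] = {str(c): "1+1"
                                          for c in range(1, config.n_chroms + 1)}
        if wgd[si]:
            for c in state_by_chrom:
                state_by_chrom[c] = "2+2"
            gains = [("WGD", "2+2", config.wgd_pi, config.wgd_n_expected,
                      list(state_by_chrom))]
        else:
            gains = []
            for k, spec in enumerate(config.gain_specs):
                chrom = gain_chroms[k % len(gain_chroms)]
                state_by_chrom[chrom] = spec.state
                gains.append((f"chr{chrom}", spec.state, spec.pi_true,
                              spec.n_expected, [chrom]))
        for c in range(1, config.n_chroms + 1):
            major, minor = STATE_MAJOR_MINOR[state_by_chrom[str(c)]]
            seg_rows.append((sid, str(c), 0, chrom_len, major, minor))

        frac_loh = sum(1 for s in state_by_chrom.values() if s == "2+0")
        ploidy_rows.append(dict(
            sample_id=sid, purity=round(float(rho), 4),
            ploidy=round(float(np.mean([STATE_TOTAL_CN[s]
                                        for s in state_by_chrom.values()])), 4),
            loh_fraction=round(frac_loh / config.n_chroms, 4),
            wgd_flag=bool(wgd[si])))

        for region, state, pi_true, n_exp, chrom_list in gains:
            per_chrom = n_exp / len(chrom_list)
            tot1 = tot2 = 0
            for chrom in chrom_list:
                sim = simulate_timed_segment(state, pi_true, per_chrom, rho,
                                             config.mean_depth, rng)
                m = len(sim)
                ctx, alts = _draw_context(rng, config.context_weights, m)
                df = pd.DataFrame({
                    "sample_id": sid, "chrom": chrom,
                    "pos": rng.integers(1, chrom_len, size=m),
                    "ref": [c[1] for c in ctx], "alt": alts,
                    "gene": "", "consequence": "noncoding",
                    "alt_count": sim["alt_count"],
                    "total_depth": sim["total_depth"],
                    "trinucleotide": ctx, "is_driver_gene": False,
                    "pathogenic_flag": False,
                    "true_multiplicity": sim["true_multiplicity"],
                    "true_clonal": True, "region": region,
                })
                tot1 += int((sim["true_multiplicity"] == 1).sum())
                tot2 += int((sim["true_multiplicity"] == 2).sum())
                mut_rows.append(df)
            gain_truth_rows.append(dict(sample_id=sid, region=region,
                                        state=state, pi_true=pi_true,
                                        n1_true=tot1, n2_true=tot2))

        # driver point mutations on diploid (or WGD) chromosomes
        for gene in driver_names:
            if not driver_status.loc[si, gene]:
                continue
            grow = genes_df[genes_df["gene"] == gene].iloc[0]
            subclonal = rng.random() < config.driver_subclonal_fraction
            ccf = rng.uniform(0.15, 0.45) if subclonal else 1.0
            state = state_by_chrom[grow["chrom"]]
            cnt = STATE_TOTAL_CN[state]
            mult = 1
            vaf = ccf * rho * mult / (rho * cnt + 2 * (1 - rho))
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            alt = rng.binomial(depth, vaf)
            ctx, alts = _draw_context(rng, config.context_weights, 1)
            mut_rows.append(pd.DataFrame([{
                "sample_id": sid, "chrom": grow["chrom"],
                "pos": int(rng.integers(grow["start"] + 1, grow["end"])),
                "ref": ctx[0][1], "alt": alts[0], "gene": gene,
                "consequence": rng.choice(["missense", "truncating"], p=[0.6, 0.4]),
                "alt_count": alt, "total_depth": depth,
                "trinucleotide": ctx[0], "is_driver_gene": True,
                "pathogenic_flag": bool(rng.random() < 0.724),
                "true_multiplicity": mult, "true_clonal": not subclonal,
                "region": "",
            }]))

        # neutral diploid passengers (clonal and subclonal mix)
        n_pass = rng.poisson(config.passenger_per_tumour)
        if n_pass:
            sub = rng.random(n_pass) < 0.3
            ccf = np.where(sub, rng.uniform(0.1, 0.5, size=n_pass), 1.0)
            depth = np.maximum(rng.poisson(config.mean_depth, size=n_pass), 1)
            vaf = ccf * rho / (rho * 2 + 2 * (1 - rho))
            alt = rng.binomial(depth, vaf)
            ctx, alts = _draw_context(rng, config.context_weights, n_pass)
            diploid = [c for c, s in state_by_chrom.items() if s == "1+1"] or \
                list(state_by_chrom)
            mut_rows.append(pd.DataFrame({
                "sample_id": sid,
                "chrom": rng.choice(diploid, size=n_pass),
                "pos": rng.integers(1, chrom_len, size=n_pass),
                "ref": [c[1] for c in ctx], "alt": alts, "gene": "",
                "consequence": "noncoding", "alt_count": alt,
                "total_depth": depth, "trinucleotide": ctx,
                "is_driver_gene": False, "pathogenic_flag": False,
                "true_multiplicity": 1, "true_clonal": ~sub, "region": "",
            }))

    mutations = pd.concat(mut_rows, ignore_index=True)
    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    ploidy = pd.DataFrame(ploidy_rows)

    track = make_covariate_track(config, rng)
    svs = plant_sv_hotspots(track, config.sv_base_rate, config.hotspots, n,
                            rng, config.sv_covariate_effects)

    # immune escape truth
    hla_loh = rng.random(n) < config.hla_loh_rate
    hla_mut = rng.random(n) < config.hla_mutation_rate
    apg_inact = rng.random(n) < config.apg_inactivation_rate
    escape_truth = pd.DataFrame({
        "sample_id": sample_ids, "hla_loh": hla_loh, "hla_mutation": hla_mut,
        "apg_inactivation": apg_inact,
        "escape": hla_loh | hla_mut | apg_inact})

    # clinical + survival
    feat = driver_status.set_index("sample_id").astype(float)
    feat = feat.loc[sample_ids]
    known = {f: b for f, b in config.log_hrs.items() if f in feat.columns}
    os_time, os_event = simulate_survival(feat, known, config.baseline_hazard,
                                          config.censoring_rate, rng)
    css_time, css_event = simulate_survival(feat, known, config.baseline_hazard * 0.7,
                                            config.censoring_rate, rng)
    pfs_time, pfs_event = simulate_survival(feat, known, config.baseline_hazard * 1.5,
                                            config.censoring_rate, rng)
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "age_at_sampling": np.round(ages, 1),
        "sex": rng.choice(["M", "F"], size=n),
        "stage": rng.choice([1, 2, 3, 4], size=n, p=[0.35, 0.2, 0.35, 0.1]),
        "grade": rng.choice([1, 2, 3, 4], size=n, p=[0.1, 0.35, 0.4, 0.15]),
        "sarcomatoid": rng.random(n) < 0.1,
        "necrosis": rng.random(n) < 0.3,
        "os_time": np.round(os_time, 1), "os_event": os_event,
        "css_time": np.round(css_time, 1), "css_event": css_event,
        "pfs_time": np.round(pfs_time, 1), "pfs_event": pfs_event,
        "tcra_fraction": np.round(rng.beta(2, 18, size=n), 4),
        "leibovich_group": rng.choice(["low", "intermediate", "high"], size=n),
    }, columns=CLINICAL_COLUMNS)

    bundle = CohortBundle(
        mutations=mutations[MUTATION_COLUMNS].copy(),
        segments=segments, ploidy=ploidy, svs=svs, clinical=clinical,
        track=track, genes=genes_df)
    bundle.validate()

    hotspot_truth = pd.DataFrame([
        dict(chrom=h.chrom, start=h.bin_start * config.bin_size,
             end=h.bin_end * config.bin_size, fold=h.fold)
        for h in config.hotspots],
        columns=["chrom", "start", "end", "fold"])
    truth = TruthSet(
        gain_truth=pd.DataFrame(gain_truth_rows, columns=[
            "sample_id", "region", "state", "pi_true", "n1_true", "n2_true"]),
        mutation_truth=mutations[["sample_id", "chrom", "pos",
                                  "true_multiplicity", "true_clonal",
                                  "region"]].copy(),
        hotspot_truth=hotspot_truth,
        escape_truth=escape_truth,
        log_hrs=dict(known),
        interaction_log_odds=dict(config.interaction_log_odds),
        driver_status=driver_status)
    return bundle, truth
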