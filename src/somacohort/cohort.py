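"""Cohort data model: tables, readers/writers and validation.

A cohort bundle holds five tables (mutations, copy-number segments,
sample purity/ploidy, structural variants, clinical) plus optional
binned covariate tracks and a gene annotation. All interval arithmetic
inside the package is 0-based half-open; 1-based inclusive coordinates
(segment TSVs) are converted at the file boundary. SNV positions are
kept 1-based, as in VCF. Sex chromosomes are dropped at load because
every downstream formula assumes a normal copy number of 2.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSEQUENCES = ("missense", "truncating", "inframe", "synonymous", "noncoding")
SV_CLASSES = ("DEL", "TD", "UNCLASSIFIED")
SEX_CHROMS = {"X", "Y", "chrX", "chrY"}

MUTATION_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "alt_count", "total_depth", "trinucleotide", "is_driver_gene",
    "pathogenic_flag",
]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "major_cn", "minor_cn"]
PLOIDY_COLUMNS = ["sample_id", "purity", "ploidy", "loh_fraction", "wgd_flag"]
SV_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "sample_id", "score", "strand1", "strand2", "sv_class", "complexity",
]
CLINICAL_COLUMNS = [
    "sample_id", "age_at_sampling", "sex", "stage", "grade", "sarcomatoid",
    "necrosis", "os_time", "os_event", "css_time", "css_event", "pfs_time",
    "pfs_event", "tcra_fraction", "leibovich_group",
]
GENE_COLUMNS = ["chrom", "start", "end", "gene", "replication_timing_quartile"]


class CohortValidationError(ValueError):
    """A table violates a cohort invariant (bad row, broken cross-reference)."""


@dataclass
class CovariateTrack:
    """Fixed-width genomic bins with one numeric value per bin per covariate.

    ``bins`` has columns chrom/start/end (0-based half-open, tiling each
    chromosome); ``values`` maps covariate name -> array aligned to bins.
    """

    bins: pd.DataFrame
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def bin_size(self) -> int:
        widths = (self.bins["end"] - self.bins["start"]).unique()
        return int(widths.max())

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else sorted(self.values)
        return np.column_stack([np.asarray(self.values[n], float) for n in names])

    def validate(self) -> None:
        b = self.bins
        if (b["start"] >= b["end"]).any():
            raise CohortValidationError("covariate track has empty or inverted bins")
        for chrom, grp in b.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] != g["end"].to_numpy()[:-1]).any():
                raise CohortValidationError(f"bins do not tile chromosome {chrom}")
        for name, vals in self.values.items():
            arr = np.asarray(vals, float)
            if len(arr) != len(b):
                raise CohortValidationError(f"covariate {name!r} length mismatch")
            if not np.isfinite(arr).all():
                raise CohortValidationError(f"covariate {name!r} has missing values")


@dataclass
class CohortBundle:
    """The validated in-memory cohort: five tables plus optional annotation."""

    mutations: pd.DataFrame
    segments: pd.DataFrame
    ploidy: pd.DataFrame
    svs: pd.DataFrame
    clinical: pd.DataFrame
    track: CovariateTrack | None = None
    genes: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical["sample_id"])

    def validate(self) -> None:
        _validate_mutations(self.mutations)
        _validate_segment_table(self.segments)
        _validate_ploidy(self.ploidy)
        _validate_svs(self.svs)
        _validate_clinical(self.clinical)
        known = set(self.clinical["sample_id"])
        for name, df in (("mutations", self.mutations), ("segments", self.segments),
                         ("svs", self.svs), ("ploidy", self.ploidy)):
            missing = sorted(set(df["sample_id"]) - known)
            if missing:
                raise CohortValidationError(
                    f"{name} reference samples absent from clinical table: {missing}")
        if self.track is not None:
            self.track.validate()


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{table} table missing columns {missing}")


def _validate_mutations(df: pd.DataFrame) -> None:
    _require_columns(df, MUTATION_COLUMNS[:9], "mutations")
    bad = df.index[df["alt_count"] > df["total_depth"]]
    if len(bad):
        raise CohortValidationError(
            f"mutations rows {list(bad[:5])}: alt_count > total_depth")
    if (df["pos"] < 1).any():
        raise CohortValidationError("mutation pos must be >= 1")
    if (df["alt_count"] < 0).any() or (df["total_depth"] < 0).any():
        raise CohortValidationError("negative read counts")
    bad_cons = set(df["consequence"]) - set(CONSEQUENCES)
    if bad_cons:
        raise CohortValidationError(f"unknown consequence labels: {sorted(bad_cons)}")


def _validate_segment_table(df: pd.DataFrame) -> None:
    _require_columns(df, SEGMENT_COLUMNS, "segments")
    if (df["start"] >= df["end"]).any():
        raise CohortValidationError("segment with start >= end")
    if (df["major_cn"] < df["minor_cn"]).any():
        raise CohortValidationError("segment with major_cn < minor_cn")
    if (df["minor_cn"] < 0).any():
        raise CohortValidationError("negative copy number")


def _validate_ploidy(df: pd.DataFrame) -> None:
    _require_columns(df, PLOIDY_COLUMNS[:4], "ploidy")
    if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
        raise CohortValidationError("purity outside (0, 1]")
    if (df["ploidy"] <= 0).any():
        raise CohortValidationError("ploidy must be positive")
    if ((df["loh_fraction"] < 0) | (df["loh_fraction"] > 1)).any():
        raise CohortValidationError("loh_fraction outside [0, 1]")


def _validate_svs(df: pd.DataFrame) -> None:
    _require_columns(df, ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                          "sample_id", "sv_class", "complexity"], "svs")
    if ((df["start1"] > df["end1"]) | (df["start2"] > df["end2"])).any():
        raise CohortValidationError("SV with inverted interval")
    if (df["start1"] < 0).any() or (df["start2"] < 0).any():
        raise CohortValidationError("negative SV coordinate")
    bad = set(df["sv_class"]) - set(SV_CLASSES)
    if bad:
        raise CohortValidationError(f"unknown sv_class labels: {sorted(bad)}")
    bad = set(df["complexity"]) - {"simple", "complex"}
    if bad:
        raise CohortValidationError(f"unknown complexity labels: {sorted(bad)}")


def _validate_clinical(df: pd.DataFrame) -> None:
    _require_columns(df, CLINICAL_COLUMNS[:14], "clinical")
    if df["sample_id"].duplicated().any():
        raise CohortValidationError("duplicate sample_id in clinical table")
    for col in ("os_time", "css_time", "pfs_time"):
        if (df[col] < 0).any():
            raise CohortValidationError(f"negative {col}")
    if ((df["tcra_fraction"] < 0) | (df["tcra_fraction"] > 1)).any():
        raise CohortValidationError("tcra_fraction outside [0, 1]")


def _drop_sex_chroms(df: pd.DataFrame, *chrom_cols: str) -> pd.DataFrame:
    mask = np.ones(len(df), bool)
    for col in chrom_cols:
        mask &= ~df[col].astype(str).isin(SEX_CHROMS)
    return df.loc[mask].reset_index(drop=True)


def _read_tsv(path: str, table: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str,
                                                  "chrom1": str, "chrom2": str})
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise CohortValidationError(f"failed to parse {table} file {path}: {exc}")


def load_cohort(paths: dict[str, str], *, keep_sex_chroms: bool = False) -> CohortBundle:
    """Load and validate a cohort from a dict of file paths.

    ``paths`` keys: mutations, segments, ploidy, svs, clinical and
    optionally tracks (directory of bedGraph files) and genes (BED).
    Segment TSVs are 1-based inclusive on disk and converted to 0-based
    half-open; BEDPE and BED are already 0-based half-open.
    """
    for key in ("mutations", "segments", "ploidy", "svs", "clinical"):
        if key not in paths:
            raise CohortValidationError(f"missing path for table {key!r}")
        if not os.path.exists(paths[key]):
            raise FileNotFoundError(paths[key])

    muts = _read_tsv(paths["mutations"], "mutations")
    if "gene" in muts.columns:  # empty gene symbols round-trip as ""
        muts["gene"] = muts["gene"].fillna("")
    segs = _read_tsv(paths["segments"], "segments")
    segs = segs.assign(start=segs["start"] - 1)  # 1-based incl -> 0-based half-open
    ploidy = _read_tsv(paths["ploidy"], "ploidy")
    svs = pd.read_csv(paths["svs"], sep="\t", comment="#", header=None,
                      names=SV_COLUMNS, dtype={"chrom1": str, "chrom2": str,
                                               "sample_id": str})
    clin = _read_tsv(paths["clinical"], "clinical")

    if not keep_sex_chroms:
        muts = _drop_sex_chroms(muts, "chrom")
        segs = _drop_sex_chroms(segs, "chrom")
        svs = _drop_sex_chroms(svs, "chrom1", "chrom2")

    track = None
    if "tracks" in paths and paths["tracks"]:
        track = _load_tracks(paths["tracks"])
    genes = None
    if "genes" in paths and paths["genes"]:
        genes = pd.read_csv(paths["genes"], sep="\t", header=None,
                            names=GENE_COLUMNS, dtype={"chrom": str})

    bundle = CohortBundle(muts, segs, ploidy, svs, clin, track=track, genes=genes)
    bundle.validate()
    return bundle


def _load_tracks(track_dir: str) -> CovariateTrack:
    bins = None
    values: dict[str, np.ndarray] = {}
    for fname in sorted(os.listdir(track_dir)):
        if not fname.endswith(".bedgraph"):
            continue
        name = fname[: -len(".bedgraph")]
        df = pd.read_csv(os.path.join(track_dir, fname), sep="\t", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
        if bins is None:
            bins = df[["chrom", "start", "end"]].copy()
        values[name] = df["value"].to_numpy(float)
    if bins is None:
        raise CohortValidationError(f"no .bedgraph files under {track_dir}")
    return CovariateTrack(bins=bins, values=values)


def write_cohort(bundle: CohortBundle, out_dir: str) -> dict[str, str]:
    """Write a bundle to TSV/BEDPE/bedGraph with deterministic formatting.

    Inverse of :func:`load_cohort`: segment starts go back to 1-based
    inclusive, column order is fixed, floats use repr-stable formatting,
    so ``load(write(x)) == x`` and a second write is byte-identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "segments": os.path.join(out_dir, "segments.tsv"),
        "ploidy": os.path.join(out_dir, "ploidy.tsv"),
        "svs": os.path.join(out_dir, "svs.bedpe"),
        "clinical": os.path.join(out_dir, "clinical.tsv"),
    }
    muts = bundle.mutations.reindex(columns=[c for c in MUTATION_COLUMNS
                                             if c in bundle.mutations.columns])
    muts.to_csv(paths["mutations"], sep="\t", index=False)
    segs = bundle.segments.copy()
    segs["start"] = segs["start"] + 1  # back to 1-based inclusive
    segs.reindex(columns=SEGMENT_COLUMNS).to_csv(paths["segments"], sep="\t",
                                                 index=False)
    bundle.ploidy.reindex(columns=[c for c in PLOIDY_COLUMNS
                                   if c in bundle.ploidy.columns]).to_csv(
        paths["ploidy"], sep="\t", index=False)
    svs = bundle.svs.copy()
    for col, default in (("score", "."), ("strand1", "."), ("strand2", ".")):
        if col not in svs.columns:
            svs[col] = default
    svs.reindex(columns=SV_COLUMNS).to_csv(paths["svs"], sep="\t", index=False,
                                           header=False)
    bundle.clinical.reindex(columns=[c for c in CLINICAL_COLUMNS
                                     if c in bundle.clinical.columns]).to_csv(
        paths["clinical"], sep="\t", index=False)

    if bundle.track is not None:
        track_dir = os.path.join(out_dir, "tracks")
        os.makedirs(track_dir, exist_ok=True)
        paths["tracks"] = track_dir
        for name in sorted(bundle.track.values):
            df = bundle.track.bins.copy()
            df["value"] = bundle.track.values[name]
            df.to_csv(os.path.join(track_dir, f"{name}.bedgraph"), sep="\t",
                      index=False, header=False)
    if bundle.genes is not None:
        paths["genes"] = os.path.join(out_dir, "genes.bed")
        bundle.genes.reindex(columns=GENE_COLUMNS).to_csv(paths["genes"], sep="\t",
                                                          index=False, header=False)
    return paths


def validate_segments(segments: pd.DataFrame, gap_tolerance: int = 0) -> pd.DataFrame:
    """Report-only per-sample segment QC.

    Returns a DataFrame of findings with columns sample_id/chrom/kind/
    detail, one row per overlap, gap beyond tolerance, or
    major_cn < minor_cn inversion. Empty report means clean.
    """
    findings: list[dict] = []
    inv = segments[segments["major_cn"] < segments["minor_cn"]]
    for _, row in inv.iterrows():
        findings.append(dict(sample_id=row["sample_id"], chrom=row["chrom"],
                             kind="inversion",
                             detail=f"major {row['major_cn']} < minor {row['minor_cn']}"))
    for (sid, chrom), grp in segments.groupby(["sample_id", "chrom"], sort=False):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        for i in range(1, len(g)):
            if starts[i] < ends[i - 1]:
                findings.append(dict(sample_id=sid, chrom=chrom, kind="overlap",
                                     detail=f"[{starts[i]},{ends[i-1]}) shared"))
            elif starts[i] - ends[i - 1] > gap_tolerance:
                findings.append(dict(sample_id=sid, chrom=chrom, kind="gap",
                                     detail=f"{starts[i] - ends[i-1]} bp"))
    return pd.DataFrame(findings, columns=["sample_id", "chrom", "kind", "detail"])


def read_mutations_vcf(path: str, sample_id: str | None = None) -> pd.DataFrame:
    """Read a minimal VCF (CHROM POS REF ALT + per-sample AD) into the
    mutation table dialect. Gene/consequence/context columns are filled
    with defaults; the flat TSV is the canonical dialect for tests."""
    rows = []
    with open(path) as fh:
        samples: list[str] = []
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                parts = line.rstrip("\n").split("\t")
                samples = parts[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise CohortValidationError(f"VCF row too short: {line[:60]!r}")
            chrom, pos, _id, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            if "AD" not in fmt:
                raise CohortValidationError("VCF FORMAT lacks AD field")
            ad_idx = fmt.index("AD")
            for sname, sval in zip(samples, parts[9:]):
                ad = sval.split(":")[ad_idx]
                ref_n, alt_n = (int(x) for x in ad.split(",")[:2])
                rows.append(dict(sample_id=sample_id or sname, chrom=chrom, pos=pos,
                                 ref=ref, alt=alt, gene="", consequence="noncoding",
                                 alt_count=alt_n, total_depth=ref_n + alt_n,
                                 trinucleotide="NNN", is_driver_gene=False,
                                 pathogenic_flag=False))
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)
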