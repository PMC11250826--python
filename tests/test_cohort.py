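"""Cohort table I/O, coordinate conventions and validation."""

import numpy as np
import pandas as pd
import pytest

from somacohort.cohort import (
    CohortValidationError,
    load_cohort,
    read_mutations_vcf,
    validate_segments,
    write_cohort,
)


def _paths(out_dir):
    return {k: str(out_dir / f) for k, f in (
        ("mutations", "mutations.tsv"), ("segments", "segments.tsv"),
        ("ploidy", "ploidy.tsv"), ("svs", "svs.bedpe"),
        ("clinical", "clinical.tsv"))} | {"tracks": str(out_dir / "tracks")}


def test_write_load_roundtrip_identity(small_cohort, tmp_path):
    bundle, _ = small_cohort
    write_cohort(bundle, str(tmp_path))
    loaded = load_cohort(_paths(tmp_path))
    pd.testing.assert_frame_equal(loaded.mutations, bundle.mutations,
                                  check_dtype=False)
    pd.testing.assert_frame_equal(loaded.segments, bundle.segments,
                                  check_dtype=False)
    pd.testing.assert_frame_equal(loaded.clinical, bundle.clinical,
                                  check_dtype=False)
    pd.testing.assert_frame_equal(
        loaded.svs.reset_index(drop=True), bundle.svs.reset_index(drop=True),
        check_dtype=False)


def test_second_write_is_byte_identical(small_cohort, tmp_path):
    bundle, _ = small_cohort
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_cohort(bundle, str(d1))
    loaded = load_cohort(_paths(d1))
    write_cohort(loaded, str(d2))
    for f in ("mutations.tsv", "segments.tsv", "clinical.tsv", "svs.bedpe"):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes()


def test_segment_coordinate_roundtrip(small_cohort, tmp_path, rng):
    """1-based inclusive file end E maps to half-open internal end E and
    re-serialises to E, on random intervals."""
    bundle, _ = small_cohort
    write_cohort(bundle, str(tmp_path))
    on_disk = pd.read_csv(tmp_path / "segments.tsv", sep="\t")
    internal = bundle.segments
    pick = rng.choice(len(internal), size=10, replace=False)
    for i in pick:
        assert on_disk["end"].iloc[i] == internal["end"].iloc[i]
        assert on_disk["start"].iloc[i] == internal["start"].iloc[i] + 1


def test_alt_exceeding_depth_rejected(small_cohort, tmp_path):
    bundle, _ = small_cohort
    write_cohort(bundle, str(tmp_path))
    muts = pd.read_csv(tmp_path / "mutations.tsv", sep="\t")
    muts.loc[0, "alt_count"] = muts.loc[0, "total_depth"] + 5
    muts.to_csv(tmp_path / "mutations.tsv", sep="\t", index=False)
    with pytest.raises(CohortValidationError, match="alt_count > total_depth"):
        load_cohort(_paths(tmp_path))


def test_unknown_sample_crossreference_rejected(small_cohort, tmp_path):
    bundle, _ = small_cohort
    write_cohort(bundle, str(tmp_path))
    segs = pd.read_csv(tmp_path / "segments.tsv", sep="\t")
    segs.loc[0, "sample_id"] = "GHOST"
    segs.to_csv(tmp_path / "segments.tsv", sep="\t", index=False)
    with pytest.raises(CohortValidationError, match="GHOST"):
        load_cohort(_paths(tmp_path))


def test_sex_chromosomes_dropped_at_load(small_cohort, tmp_path):
    bundle, _ = small_cohort
    write_cohort(bundle, str(tmp_path))
    muts = pd.read_csv(tmp_path / "mutations.tsv", sep="\t",
                       dtype={"chrom": str})
    extra = muts.iloc[[0]].assign(chrom="X")
    pd.concat([muts, extra]).to_csv(tmp_path / "mutations.tsv", sep="\t",
                                    index=False)
    loaded = load_cohort(_paths(tmp_path))
    assert "X" not in set(loaded.mutations["chrom"])


def test_validate_segments_findings():
    segs = pd.DataFrame({
        "sample_id": ["s", "s", "s"],
        "chrom": ["1", "1", "2"],
        "start": [0, 50, 0],
        "end": [100, 150, 100],
        "major_cn": [1, 2, 1],
        "minor_cn": [1, 1, 2],
    })
    report = validate_segments(segs)
    kinds = set(report["kind"])
    assert "overlap" in kinds
    assert "inversion" in kinds
    clean = segs.iloc[[0]].assign(minor_cn=1)
    assert len(validate_segments(clean)) == 0


def test_minimal_vcf_reader(tmp_path):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "1\t100\t.\tC\tT\t.\tPASS\t.\tGT:AD\t0/1:60,40\n"
        "2\t200\t.\tT\tG\t.\tPASS\t.\tGT:AD\t0/1:70,30\n")
    df = read_mutations_vcf(str(vcf))
    assert list(df["pos"]) == [100, 200]
    assert list(df["alt_count"]) == [40, 30]
    assert list(df["total_depth"]) == [100, 100]
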