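"""Genetic immune-escape classification.

A tumour is classed as immune-evading if it carries any of: loss of
heterozygosity at an HLA class-I gene (HLA-A/B/C), a nonsynonymous HLA
class-I mutation, or an inactivating alteration of an antigen-presenting
gene (APG). "Inactivating" means a truncating mutation (stop-gain,
frameshift, canonical splice) or a biallelic nonsynonymous alteration.
HLA LOH flags and neoantigen counts are upstream inputs, not computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from somacohort.landscape import percent

HLA_GENES = ("HLA-A", "HLA-B", "HLA-C")

# 22-gene antigen presentation / processing set (config-overridable)
DEFAULT_APG_LIST = (
    "B2M", "CALR", "CANX", "CIITA", "ERAP1", "ERAP2", "HSPA5", "HSP90AA1",
    "IRF1", "JAK1", "JAK2", "NLRC5", "PDIA3", "PSMB8", "PSMB9", "RFX5",
    "RFXANK", "RFXAP", "STAT1", "TAP1", "TAP2", "TAPBP",
)

MECHANISMS = ("HLA-LOH", "HLA-mutation", "APG-inactivation")


@dataclass
class ImmuneInput:
    """Per-tumour immune annotation consumed by the classifier."""

    sample_id: str
    hla_loh: dict[str, bool] = field(default_factory=dict)  # per HLA gene
    hla_nonsyn_mutation: bool = False
    apg_mutations: pd.DataFrame | None = None  # gene, consequence, biallelic
    neoantigen_count: int = 0


@dataclass
class EscapeCall:
    sample_id: str
    escape: bool
    mechanisms: frozenset[str]


def apg_inactivation(apg_mutations: pd.DataFrame | None,
                     apg_list: tuple[str, ...] = DEFAULT_APG_LIST) -> bool:
    """True iff any listed APG has a truncating mutation or a biallelic
    nonsynonymous alteration. Genes outside the list are ignored."""
    if apg_mutations is None or len(apg_mutations) == 0:
        return False
    outside = sorted(set(apg_mutations["gene"]) - set(apg_list))
    if outside:
        warnings.warn(f"non-APG genes ignored: {outside}", stacklevel=2)
    rec = apg_mutations[apg_mutations["gene"].isin(apg_list)]
    truncating = (rec["consequence"] == "truncating").any()
    nonsyn = rec["consequence"].isin(["missense", "truncating", "inframe"])
    biallelic = (nonsyn & rec["biallelic"].astype(bool)).any()
    return bool(truncating or biallelic)


def classify_escape(inp: ImmuneInput,
                    apg_list: tuple[str, ...] = DEFAULT_APG_LIST) -> EscapeCall:
    """Apply the three-mechanism escape rule to one tumour."""
    mechanisms = set()
    if any(inp.hla_loh.get(g, False) for g in HLA_GENES):
        mechanisms.add("HLA-LOH")
    if inp.hla_nonsyn_mutation:
        mechanisms.add("HLA-mutation")
    if apg_inactivation(inp.apg_mutations, apg_list):
        mechanisms.add("APG-inactivation")
    return EscapeCall(sample_id=inp.sample_id, escape=bool(mechanisms),
                      mechanisms=frozenset(mechanisms))


def escape_summary(calls: list[EscapeCall]) -> pd.DataFrame:
    """Cohort counts and one-decimal percentages, overall and per mechanism."""
    if not calls:
        raise ValueError("no escape calls to summarise")
    n = len(calls)
    rows = [dict(quantity="escape", count=sum(c.escape for c in calls), total=n)]
    for mech in MECHANISMS:
        rows.append(dict(quantity=mech,
                         count=sum(mech in c.mechanisms for c in calls), total=n))
    df = pd.DataFrame(rows)
    df["percent"] = [percent(k, n) for k in df["count"]]
    return df
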