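# somacohort

Analysis toolkit for whole-genome-sequenced tumour cohorts, built around the
questions a clear cell renal cell carcinoma (ccRCC) WGS study asks: **when**
did the driver events happen, **where** do structural variants recur beyond
what local genome biology explains, **which** drivers co-occur or exclude one
another, and **how** do genomic features relate to immune escape and patient
survival.

It is written for computational cancer-genomics researchers who have
per-tumour somatic calls (SNV/indel tables with read counts, allele-specific
copy-number segments, structural variants, clinical follow-up) and want the
bespoke cohort-level statistics as tested, reusable code. Because real
cohorts of this kind are usually restricted-access, the package ships a
synthetic-cohort generator that emulates every input with known planted
truth, so each stage can be validated end to end.

## What it computes

**Molecular timing of copy-number gains.** A clonal mutation inside a gained
region sits on either the duplicated allele (multiplicity 2) or a single copy
(multiplicity 1). With π the fraction of clonal mutational time elapsed when
the gain occurred, the expected multiplicity-2 and multiplicity-1 counts
(n₂, n₁) give closed-form estimators:

- single-copy gain (2+1): π = 3·n₂ / (n₁ + 2·n₂)
- copy-neutral LOH (2+0) and whole-genome duplication (2+2, pooled over
  segments): π = 2·n₂ / (n₁ + 2·n₂)

Multiplicity comes from the standard VAF decomposition
m ≈ VAF/ρ · (ρ·CN_t + 2(1−ρ)), cancer cell fraction CCF = VAF · (ρ·CN_t +
2(1−ρ)) / (ρ·m) with a Clopper–Pearson interval, and a two-phase molecular
clock (unit rate before tumour initiation, k-fold faster after) converts π to
years before sampling.

**League-model event ordering.** Per tumour, co-occurring driver events play
pairwise matches (early-clonal beats late-clonal beats subclonal; gains
compare by π). A Bradley–Terry model fit by minorisation–maximisation turns
cohort win/loss/tie counts into average finishing positions with
tumour-resampling bootstrap intervals.

**SV hotspots.** Simple-SV breakends are binned genome-wide; a
negative-binomial regression on local covariates (chromatin accessibility,
repeats, GC, replication timing, gene density, expression) gives the expected
background; penalised piecewise-constant fitting segments each chromosome's
profile; candidate segments are tested by permutation (breakends
redistributed within chromosome proportional to the background) with
Benjamini–Hochberg control, and hotspots over large late-replicating genes
are flagged as likely fragile sites.

**Cohort statistics.** Driver frequencies and pairwise Fisher-exact
co-occurrence/exclusivity tests; non-coding burden testing against
trinucleotide-context-adjusted negative-binomial expectations with Empirical
Brown combination of per-method p-values; WGD calling (ψ > 2.9 − 2·hom),
weighted genome instability index, TMB, arm-level recurrence; the
three-mechanism immune-escape classifier (HLA LOH, HLA mutation,
antigen-presenting-gene inactivation); Kaplan–Meier/log-rank and Cox
survival models plus adjusted regression scans.

## Worked example

Generate a 60-tumour synthetic cohort and time one planted single-copy gain:

```python
from somacohort.simulate import SimulationConfig, generate_cohort
from somacohort.timing import (ClockModel, convert_to_real_time,
                               count_clonal_multiplicities, time_gain)

bundle, truth = generate_cohort(SimulationConfig(n_tumours=60), seed=7)
row = truth.gain_truth.iloc[0]                     # S0000, chr22, state 2+1
muts = bundle.mutations.query("sample_id == @row.sample_id and chrom == '22'")
rho = bundle.ploidy.set_index("sample_id").loc[row.sample_id, "purity"]

n1, n2 = count_clonal_multiplicities(muts.alt_count, muts.total_depth,
                                     rho, major_cn=2, minor_cn=1)
gt = time_gain(n1, n2, "2+1")
age = bundle.clinical.set_index("sample_id").loc[row.sample_id,
                                                 "age_at_sampling"]
rt = convert_to_real_time(gt.pi, age, ClockModel(),
                          pi_ci=(gt.ci_low, gt.ci_high))
print(n1, n2, round(gt.pi, 3), round(rt.years_before_sampling, 1))
```

This prints `433 43 0.249 48.8`: of 476 clonal mutations in the gained
region, 43 sit at multiplicity 2, giving π = 0.249 (95% CI 0.183–0.316)
against a planted truth of 0.25 — the gain happened a quarter of the way
through this tumour's clonal mutational history, i.e. an estimated 48.8 years
before sampling for this 64.9-year-old patient under a constant clock.

A command-line surface wraps the main entry points:

```sh
somacohort simulate --seed 3 --out cohort/
somacohort validate cohort/
somacohort gains cohort/ --k 1 --c 1
somacohort hotspots cohort/ --perm 1000 --seed 3
```

## Layout

- `somacohort.cohort` — tables, readers/writers, validation
- `somacohort.simulate` — synthetic cohorts with planted truth
- `somacohort.timing` — multiplicity, CCF, gain/WGD timing, clock
- `somacohort.ordering` — precedence matches, Bradley–Terry league, odds
- `somacohort.landscape` — frequencies, co-occurrence, report fractions
- `somacohort.hotspots` — binning, NB background, segmentation, permutation
- `somacohort.instability` — WGD, wGII, TMB, arm recurrence
- `somacohort.burden` — context rates, NB burden, Empirical Brown, BH
- `somacohort.immune` — escape classifier and summary
- `somacohort.clinical` — KM/log-rank, Cox, regression scans

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
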