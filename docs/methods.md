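# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices that affect results.

## Mutation multiplicity, CCF and clonality

For a mutation with variant allele fraction VAF = alt/depth in a region of
total tumour copy number CN_t at purity ρ, the expected VAF of a mutation
present in all tumour cells on m copies is ρ·m / (ρ·CN_t + 2(1−ρ)), assuming
a normal copy number of 2 — which is why sex chromosomes are excluded at
load. Inverting gives the multiplicity estimate, rounded half-up (explicit
floor(x+0.5), so results do not depend on the platform's banker's rounding)
and clamped into [1, major_cn]. CCF applies the same linear map at the
estimated m; its interval is the Clopper–Pearson binomial interval on
alt/depth passed through that map, capped at 1.5 to absorb sampling noise
above 1.

Clonality uses a per-mutation rule: clonal iff the CCF interval's upper
bound reaches 0.9 and the point estimate reaches 0.7. A full
Dirichlet-process subclonal reconstruction would pool information across
mutations; the per-mutation rule is deterministic, desk-scale and calibrated
on the generator (a 70/30 clonal/subclonal split at depth 80 is recovered
within ±5 points), at the price of noisier per-mutation calls near the
threshold.

## Timing copy-number gains

Only states reachable by one gain or one duplication are timed: 2+1, 2+0,
2+2. Higher states have multiple non-identifiable copy-number paths. The
accrual model counts each allele-lineage's mutational exposure; with π the
fraction of clonal mutational time elapsed at the gain,

| state | E[n₂] | E[n₁] | estimator |
|-------|-------|-------|-----------|
| 2+1   | π     | π + 3(1−π) | π = 3n₂/(n₁+2n₂) |
| 2+0   | π     | 2(1−π)     | π = 2n₂/(n₁+2n₂) |
| 2+2   | 2π    | 4(1−π)     | π = 2n₂/(n₁+2n₂) |

estimates are clipped into [0,1]. These closed forms equal the maximum of
the two-category multinomial likelihood (verified exhaustively against a
grid search for all n₁+n₂ ≤ 60). WGD timing pools (n₁, n₂) across all 2+2
segments of a sample. Confidence intervals are percentile bootstrap
(B = 1000, seeded) over the binomial resampling of (n₁, n₂).

The bootstrap CI quantifies count sampling noise given the multiplicity
assignments. When multiplicities are themselves estimated from reads, low
purity adds an assignment bias the CI does not model: in simulation at the
default conditions (purity uniform 0.3–0.9, depth 80, 500 mutations per
segment) the full pipeline's mean |π̂ − π| is ≈ 0.03, while CI coverage is
≈ 0.93 for the estimator on accrual-model counts and lower (≈ 0.79) end to
end. Users who need calibrated intervals at low purity should widen them or
restrict to higher-purity samples.

## The molecular clock

Conversion from molecular time π to years assumes mutations accrue at unit
relative rate until tumour initiation at calendar-life fraction c, and at
rate k ≥ 1 thereafter. With M = c + k(1−c) total mutation-units over a life
of length A years, calendar fraction t = πM if πM ≤ c, else c + (πM − c)/k,
and the event happened A(1−t) years before sampling. k = 1 reduces exactly
to A(1−π); output is monotone decreasing in π for any valid (k, c). This
two-phase piecewise-linear form is the minimal model expressing "faster
clock after initiation"; both parameters are configuration, defaulting to
the constant clock. The clock rate itself (clonal mutations/year) is burden
divided by age, optionally restricted to a clock-like-signature-attributed
subset supplied by the caller.

## League-model ordering

Timing classes order as early-clonal < late-clonal < subclonal; clonal-NA
(clonal in an untimed region) ties with either clonal class and beats
subclonal; copy-number events compare by π with a tie margin of 0.05
(below typical π CI width at a few hundred mutations per segment). Mixed
pairs map π ≤ 0.5 to early and π > 0.5 to late. Strengths come from a
Bradley–Terry model fit by minorisation–maximisation with ties split
half/half, which is deterministic given the count matrix and invariant to
event relabelling and tumour duplication. Finishing position is the rank of
strength (average rank on ties); intervals are a bootstrap over tumours,
the independent sampling units. Gene mutations and CNAs can be ranked in a
single league or separately — both are just different event-call inputs.

## SV hotspots

Breakends of simple SVs (complexity labels are inputs) are counted in
100 kb bins — a default that resolves locus-scale hotspots while keeping
the background regression stable. The background is a negative-binomial GLM
(log link, log bin-width offset) on the six standard covariates, with
dispersion α profiled by method of moments from a Poisson pre-fit; if the
NB fit fails the model falls back to Poisson with a warning. Segmentation
minimises penalised within-segment squared error on Anscombe-transformed
counts (2√(y+3/8), stabilising Poisson-like variance) with an exact
dynamic-programming partition; the penalty (default 10) trades resolution
against over-segmentation, and an infinite penalty yields one segment per
chromosome.

Candidates (segments above their expected background sum) are tested by
permutation: each chromosome's breakend total is redistributed across its
bins proportional to the fitted background mean (a multinomial draw, so
totals are conserved exactly), and a candidate spanning L bins scores the
fraction of permutations whose maximal L-bin window matches the observed
count — testing elevation *beyond* covariate-explained density. p-values
use the (r+1)/(B+1) estimator; fewer than 100 permutations are refused. BH
across candidates retains q < 0.05. Hotspots overlapping a gene ≥ 600 kb in
the latest replication-timing quartile are flagged as likely fragile sites
and excluded from the retained list; both the length threshold and the
quartile are configuration, since fragile-site definitions vary.

In simulation (200 tumours, 4×5 Mb chromosomes, base mean 1 breakend/bin,
planted 10× five-bin hotspots) power exceeds 90% and the empirical FDR at
q < 0.05 stays below 0.07.

## Driver landscape and non-coding burden

Pairwise co-occurrence/exclusivity uses the two-sided Fisher exact test
with BH adjustment — the simplest defensible choice; because raw Fisher can
report spurious exclusivity when mutation burden varies strongly across
tumours, burden-matched permutation is the natural extension for real
cohorts. Report percentages round half-up to one decimal.

Non-coding burden expectations multiply per-trinucleotide context rates
(96-channel spectrum when alt alleles are available, collapsed to 32
contexts for opportunity-weighting) fitted on passenger mutations, context
opportunities of each element, and per-sample exposure factors (sample
passenger burden over cohort mean). The observed count is tested against a
negative-binomial upper tail with dispersion fitted on passenger elements.
Empirical Brown's method combines per-method p-values using the empirical
covariance of −2·ln p across elements: S = Σ −2 ln pₘ is referred to a
scaled χ² with scale Var/(2E) and df 2E²/Var, E = 2k,
Var = 4k + 2Σcov. With a diagonal covariance this is exactly Fisher's
method; with duplicated methods it correctly discounts to the
single-method p.

## Genome instability and immune escape

WGD is called when ploidy ψ > 2.9 − 2·hom (hom = genome LOH fraction), the
common pan-cancer rule; the inequality is strict. wGII is the unweighted
mean over autosomes of the length-weighted fraction of covered genome whose
total copy number differs from baseline (round(ψ) by default, or 2), making
it invariant to segment subdivision. Arm calls use a 50%-of-arm-length
majority rule (configurable); arm recurrence is tested against a
within-sample label permutation that preserves each sample's total gain and
loss burden exactly.

Immune escape is the OR of three mechanisms: HLA class-I LOH (flags are
inputs, as allele-specific HLA copy number needs a dedicated caller), an
HLA nonsynonymous mutation, or APG inactivation — a truncating mutation or
biallelic nonsynonymous alteration in any gene of the configurable 22-gene
antigen-presentation set. The classifier is deterministic, so generator
truth is recovered exactly.

## Survival and association scans

Kaplan–Meier and the log-rank test come from lifelines; Cox models use the
partial likelihood with Efron tie handling, appropriate for day-granular
times with many ties. Covariates of interest and adjusters enter one
multivariable model; Wald intervals and two-sided z p-values are reported,
and separation or non-convergence yields flagged NaN results rather than
estimates. Association scans fit one model per feature (logistic, linear or
negative binomial with moment-profiled dispersion) with the adjusters, then
BH across features.

## The synthetic generator

The generator's defaults are the cohort conditions the package models:
778 tumours, ages N(63, 10) clipped to 25–88, purity uniform 0.3–0.9, mean
depth 80, driver marginals VHL 0.80 / PBRM1 0.50 / SETD2 0.18 / BAP1 0.12,
WGD probability 0.166, HLA-LOH 5.9% / HLA-mutation 0.5% / APG-inactivation
3.1%, and a VHL log hazard ratio of ln 0.6 with 40% independent censoring.
The genome is reduced to 22 autosomes of 10 Mb at 100 kb bins so a full
cohort generates in seconds; gains are whole-chromosome events with
configured (state, π, expected mutations) and WGD samples are uniformly
2+2.

Driver genotypes come from an exact Ising-like sampler: with ≤ ~15 genes
all 2^G configurations are enumerated, pairwise interaction log-odds set
the couplings, and per-gene fields are calibrated by damped logit fixed-
point iteration to hit the target marginals (unreachable marginals raise).
Sampling is exact, so −∞ log-odds yields literally zero co-mutated tumours.
Depth is Poisson around the mean; alt counts binomial at the expected VAF;
trinucleotide contexts draw from a configurable 96-channel distribution
(uniform by default). SV breakends Poissonise exactly at the planted
per-bin mean (base rate × exp(covariate effects) × hotspot fold) by drawing
the SV count Poisson at half the total and both breakends iid proportional
to intensity. Survival times are exponential proportional-hazards draws
with independent exponential censoring tuned to the requested rate.

What the generator does **not** emulate: sequence context at real genomic
positions, karyotype evolution (gains are single whole-chromosome events),
subclonal phylogenies deeper than one clonal/subclonal split, mutational
signatures, inter-chromosomal SV structure (breakend pairs are
independent), and correlated clinical covariates. Tests passing on this
generator therefore demonstrate correctness of the estimators under their
stated models, not robustness to real-data violations such as subclonal
copy number, purity estimation error or covariate measurement noise.

## Problem sizes used in checks

Estimator-equivalence checks run exhaustively (all count pairs with
n₁+n₂ ≤ 60; all 2×2 tables with n ≤ 40). Simulation-based checks use 200
segments per state at 500 mutations each for π recovery, 50 seeds at 300
tumours for league recovery, 30 replicates of the reduced 4-chromosome
genome for hotspot power/FDR, 2000 elements × 3 methods for the Brown/
Fisher comparison, and 10 replicates of n = 600 for Cox recovery — sizes at
which the Monte-Carlo error is well below each check's tolerance.

## Known limitations

- π is only identifiable for 2+1, 2+0 and 2+2; higher or subclonal gains
  are excluded.
- The clonality rule is per-mutation; borderline CCFs near 0.7 are noisy at
  depth < 60.
- The two-phase clock is a stand-in for richer rate-variation models; k and
  c are not estimated from data.
- Fisher-based exclusivity can inflate under heterogeneous tumour mutation
  burden.
- TMB depends on the callable-genome denominator, which is configuration.
- The fragile-site rule (length ≥ 600 kb, latest quartile) is a heuristic
  proxy; curated fragile-site catalogues should be preferred when
  available.
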