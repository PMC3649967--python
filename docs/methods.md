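# Methods

## Gene-set construction

A mouse gene is *essential* when it carries at least one homozygous
annotation with a code from the lethal-phenotype code set; annotations
observed only in the heterozygous state are disregarded, and a gene with both
lethal and non-lethal homozygous annotations is essential (lethal wins). The
lethal-code set is a configuration file, not hard-coded — the file shipped by
the synthetic bundle contains 46 synthetic placeholder codes (`MP:L0001` …)
because the curated code list is a resource callers supply; all
classification logic is code-set-agnostic.

Mouse→human mapping uses only strictly one-to-one rows of the supplied
ortholog table: a mouse gene mapping to several human genes, or a human gene
hit by several mouse genes, is dropped with a logged warning. This is a
deliberate resolution rule; curated orthology resources differ on how they
break such ties, and dropping is the conservative choice. Human genes whose
ortholog has homozygous non-lethal annotations only form the non-lethal set
(NLG); everything else in the universe is OTHER. The three classes partition
the universe and classification is idempotent and row-order independent.

Annotation flags: `ubiquitous_top10` marks genes whose expression coefficient
of variation (sample sd / mean) ranks within the lowest floor(10% × n) of
ranked genes; `brain_overexpressed` uses an inclusive p ≤ 1e-4 threshold;
membership flags come from ID lists; a `chr_y` flag lets variant analyses
exclude Y-linked genes when a call set carries no Y genotypes.

## Variant typing

The broad exonic-missense class comprises the seven annotation tokens
`SPLICE_SITE_ACCEPTOR`, `SPLICE_SITE_DONOR`, `STOP_GAINED`,
`NON_SYNONYMOUS_CODING`, `STOP_LOST`, `START_LOST`, `START_GAINED`;
its loss-of-function subset is the stop-codon and splice-site tokens only —
start-codon changes are broad-missense but not LoF. Damaging status requires
both PolyPhen2 and SIFT to call the variant damaging; a missing call on
either side is treated as not damaging (conservative). Allele frequency is
the alt-allele count over 2 × called diploid samples (missing genotypes
shrink the denominator; no imputation), and *rare* means af < 0.01 strictly.
Coordinates are 1-based (VCF convention); multi-allelic records are split per
alt allele with per-alt dosages.

## Statistics

* Group comparisons are distribution-free: one-sided Wilcoxon rank-sum
  between gene sets, one-sided signed-rank when comparing two properties
  within the same samples (exact where sample sizes and ties allow, normal
  approximation with continuity correction otherwise). Paired comparisons
  with all-zero differences carry no evidence and return p = 1.
* 2×2 tables use the two-sided Fisher exact test. The reported odds ratio is
  the conditional maximum-likelihood estimate (what R's `fisher.test`
  prints); the sample cross-product ad/bc is available. The default 95% CI is
  Woolf's logit interval on the sample OR,
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), with the conditional exact interval
  behind a flag. Zero cells get a 0.5 continuity correction (flagged).
* Length-corrected rates are per-gene counts divided by total exonic bp;
  Z-scores are taken relative to all genes with the sample sd. A log(count+1)
  pseudo-count transform is provided because per-gene counts are zero-heavy;
  whether raw rates or log1p-transformed counts are standardized is a
  presentation choice, so both transforms are exposed.
* The SFS excess profile is the difference in per-bin frequency shares
  between a gene set and a comparator (right-closed bins, default edges 0,
  0.001, 0.005, 0.01, 0.05, 0.1, 0.5); the shares sum to one on each side so
  the excess sums to zero. The accompanying test is a one-sided Wilcoxon that
  the set's frequencies are lower.
* Promoter conservation is the arithmetic mean of per-base track scores in
  TSS ± 100 bp, strand-symmetric (a symmetric window needs no strand
  handling); uncovered bases are omitted and fully uncovered genes get a
  missing value.

## Matched-gene permutation test for de novo enrichment

Longer and more GC-rich genes accumulate more de novo events, so raw in-set
event counts are confounded. For each event, the match pool is every universe
gene within ±100 bp total exon length and ±2.5 percentage points GC of the
event's gene, *including the gene itself* (sampling with replacement; a gene
whose only match is itself self-swaps and stays in the analysis). Each of
`n_perm` replicates independently redraws every event's gene uniformly from
its pool — a gene hit by several events is resampled independently per event
(a per-gene mode that carries one draw across all of a gene's events is
available behind a flag). With `obs` observed in-set events, `exp` the
replicate mean, and `n` events:

    adjusted OR = [obs / (n − obs)] / [exp / (n − exp)]

The one-sided (enrichment) permutation p is add-one, (1 + #{count ≥ obs}) /
(1 + n_perm) — never exactly zero and monotone in obs; the two-sided value
doubles it, capped at 1. The study's SE for meta-analysis is the standard
deviation of replicate log-odds with a 0.5 continuity clip at counts 0 or n —
the permutation spread is the natural scale of the null odds, and it is
deliberately conservative (it slightly exceeds the sampling sd of the
estimate in our calibration experiments). When every pool is a singleton the
replicate spread is zero and the SE is reported as NaN; such studies are
skipped by the meta-analysis. An exact-expectation mode computes
Σ_events |pool ∩ set| / |pool| directly and agrees with the Monte-Carlo mean
within Monte-Carlo error.

**What the adjusted OR estimates.** When set membership is independent of
the matching covariates, the marginal adjusted OR equals the generative
enrichment odds. When the gene set differs systematically in length or GC —
essential genes are longer — the in-set probability varies across events and
the marginal odds ratio is attenuated relative to a per-event odds
multiplier (a mixture of odds is not the odds of the mixture). This is a
property of the estimand, not an implementation artifact; the parameter-
recovery experiment therefore uses a universe whose essential genes follow
the genome-wide length law. A second, smaller attenuation comes from
self-inclusion: in sparse regions of the length×GC plane the pool approaches
{the gene itself}, transferring observed enrichment into the expectation. At
the 20,029-gene scale both effects together bias the recovered odds ratio
about 4% low at a generative odds of 1.4, well inside the permutation SE.

**Meta-analysis.** Per-study log adjusted ORs are combined with inverse-
variance weights w_i = 1/se_i²: combined = Σwθ/Σw, SE = (Σw)^(−1/2), 95% CI
exp(combined ± 1.96 SE), two-sided normal p. Heterogeneity is Cochran's
Q = Σw(θ − combined)² on k − 1 df; a single study returns Q = 0, q_p = 1.
The implementation is cross-checked against statsmodels' `combine_effects`.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular genome:

* **Universe** — default 20,029 genes; total exon lengths log-normal
  (log-mean 7.3, log-sd 0.8 → median ≈ 1.5 kb), essential-gene lengths
  multiplied by 1.5 (essential genes are longer); GC% truncated-normal
  (46 ± 8, clipped to [20, 80]); class fractions 0.1234 EG / 0.1903 NLG
  (≈ 2,472 and 3,811 of 20,029). Lengths are clipped at 100 bp.
* **Phenotype tables** — every EG gene gets ≥1 homozygous lethal row (with
  optional extra non-lethal and heterozygous rows so the lethal-wins and
  het-disregard rules are exercised); NLG genes get homozygous non-lethal
  rows; some OTHER genes are mapped with no or het-only rows; a few ambiguous
  one-to-many ortholog rows are injected without changing any truth label, so
  classification recovers the generated labels exactly.
* **Cohort** — per gene and effect class, site counts are Poisson with mean
  site_rate × exon_length × multiplier(gene class, effect class). Default
  unconstrained rates: 2×10⁻³ synonymous and missense, 2×10⁻⁴ LoF per bp;
  default constraint multipliers: EG missense 0.5, EG LoF 0.2, synonymous
  neutral, NLG/OTHER neutral. The paper-gap here is real — no quantitative
  effect sizes exist for these reductions — so the defaults are free,
  documented parameters chosen to give clear but not overwhelming constraint
  signatures; they are not fitted to any published quantity. Allele
  frequencies are drawn from a discretized law f(x) ∝ x^(−α) on the grid
  i/(2N), α = 1 (neutral-like), with EG non-synonymous sites using α + 1
  (the rare shift); genotypes are Binomial(2, f) per sample (Hardy–Weinberg).
  Sites monomorphic in the sampled cohort are dropped, as in a real call set.
  PolyPhen/SIFT calls are drawn independently given a latent damaging state
  (P(damaging) = 0.3, concordance 0.9 per predictor, 2% missing) so the
  consensus logic is exercised; LoF sites carry no predictor calls.
* **De novo studies** — event genes are drawn with weight exon_length ×
  gc_weight × (true_or if EG and case arm), where gc_weight =
  clip(1 + 0.2·(GC − mean)/sd, 0.1, ∞) models the positive GC–event-count
  correlation (reported without a coefficient; γ = 0.2 is a free parameter).
  Mutation types are 30% synonymous and a fixed coding mix otherwise.
* **Auxiliary tables** — per-gene dN/dS per species pair (log-normal around
  0.25, EG scaled by 0.6), transcript counts, a per-base conservation track
  around each TSS with a +0.8 EG shift, expression CV (EG lower) and brain
  over-expression p-values (per-class over-expression probabilities 0.16 /
  0.15 / 0.10, chosen so EG vs NLG brain over-expression is nearly null, as
  observed).

What the generator does **not** emulate: linkage disequilibrium, multi-allelic
sites, indel realism, population structure, genotype-calling error, or any
coupling between a gene's constraint and its expression beyond the class
means. Passing tests therefore demonstrate the pipeline's statistical
correctness and calibration under the assumed structure, not performance on
real cohort artifacts.

## Validation experiments and problem sizes

* Null calibration: 1,000 single-arm studies of 300 events (the scale of the
  real studies' case arms) on an exchangeable 200-gene universe, 200
  permutations each; the one-sided rejection rate at α = 0.05 stays within
  [0.03, 0.07] (the add-one estimator and count ties make it mildly
  conservative, 0.03–0.06 across seeds).
* Parameter recovery: 100 replicates of 4 studies × 300 case events ×
  2,000 permutations on 20,029-gene universes with length-neutral essential
  genes; the fixed-effects CI covers the generative odds 1.4 in ≈95% of
  replicates (700-replicate estimate) and excludes the null in the large
  majority.
* Directional reproduction: 40 cohorts of 200 genes per class × 100 samples
  under the default constraint multipliers; the lower EG missense rate,
  rare-shifted EG spectrum and lower within-sample missense/synonymous ratio
  reproduce in every replicate. The lower-LoF-fraction finding reproduces in
  95.0% of replicates (200-replicate estimate): with only ~15–25 polymorphic
  EG LoF sites per cohort, the frequency law occasionally places one EG LoF
  site at common frequency, inverting the per-sample fraction — a small-set
  instability of the estimand at 200 genes, not of the test.
* Oracle equivalence: the exact-expectation mode matches full joint-pool
  enumeration to 1e-12 and the Monte-Carlo mean to within 3 SE on a six-gene
  universe; Fisher exact p matches full hypergeometric enumeration to 1e-12
  over all 635,376 tables with n ≤ 60; the meta-analysis reproduces its
  closed-form worked example (combined 0.24, SE 0.08944, Q 0.8, q_p 0.3711).

## Numerical choices and degenerate inputs

* Zero-variance Z-scores return 0; ns_ratio and lof_fraction with zero
  denominators are missing and excluded from paired tests.
* Permutation replicate counts at 0 or n are clipped to 0.5 / n − 0.5 before
  taking log-odds.
* CV ties in the ubiquitous-expression ranking break by gene ID for
  determinism.
* All generators and the permutation machinery are deterministic for a fixed
  seed; multi-study runs derive per-study streams from one master seed.

## Known limitations

* The adjusted OR is a marginal odds contrast; for gene sets with atypical
  length/GC profiles it attenuates relative to a per-event odds multiplier
  (quantified above). Interpret it as enrichment relative to the matched
  expectation, not as a structural odds parameter.
* The per-study SE from permutation spread is a null-spread proxy; it is
  mildly conservative under enrichment.
* Rarity uses the combined-cohort allele frequency by default; per-population
  rarity is a flag on the parser threshold, and population stratification of
  counts is left to the caller.
* The pipeline consumes dN/dS and conservation scores as precomputed tables;
  it does not compute substitution rates or conservation from alignments.
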