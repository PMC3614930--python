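# Methods

## Model and procedure

The pipeline treats prognosis-marker discovery as a three-stage selection
problem over a gene universe measured twice: once across normal
mammary-gland development (a time-course of linear-scale intensities with
Present/Absent detection calls) and once across tumor cohorts (log2 ratios
versus a reference pool, with clinical follow-up).

**Stage 1 — developmental selection.** Genes Present on at least half the
arrays enter a per-gene one-way fixed-effects ANOVA with time points as
groups; p-values come from the F distribution with (T−1, N−T) degrees of
freedom for T time points and N arrays. Because nearly all expressed genes
vary detectably across the pregnancy cycle, the ANOVA (p < 0.01, strict) is
a permissive pre-filter and the discriminating statistic is the max/min fold
of time-point mean expression. The fold cutoff is selected by maximizing
the odds ratio of a reference gene list between the selected (fold ≥ c) and
rejected subsets over a grid of candidates (default 1.5–6.0, step 0.5). The
odds ratio is the cross-product ratio a·d/(b·c) of the 2×2 table of
selection × reference membership, equivalently (p₁/(1−p₁))/(p₂/(1−p₂)) on
the within-subset reference fractions.

**Stage 2 — phase assignment.** Selected genes are standardized per gene to
mean 0, variance 1 (population convention, ddof = 0) across all arrays —
PCA then operates on individual replicate arrays rather than time-point
means, so a 10-time-point × 2-replicate design yields 19 nonzero
components. Genes are observations; arrays are variables. Since PCA signs
are arbitrary, components are oriented deterministically: PC1 is flipped if
needed so genes peaking in the growth block average positive on it, then
PC2 likewise for the involution block; if a block contains no peaking gene
the axis is oriented by correlating its loadings with the array time order.
Phases follow the quadrant rule (growth: PC1 > 0; involution: PC1 ≤ 0 and
PC2 > 0; lactation: PC1 ≤ 0 and PC2 ≤ 0), with the measure-zero boundaries
closed as PC1 = 0 → growth and PC1 < 0, PC2 = 0 → lactation (logged when
hit). Peak times are argmaxes of unstandardized time-point means
(standardization preserves the argmax); ties resolve to the earliest time
point in design order.

**Stage 3 — classifier and outcome.** Per cohort, a gene is altered when
|mean log2 ratio| ≥ 1 and a two-sided one-sample t-test against zero gives
p < 0.01 (both thresholds configurable; pre-computed altered lists can be
supplied instead). Genes absent from a cohort's platform count as
not-altered there, keeping alteration counts on a uniform 0..K range; the
classifier is the set with count ≥ 2. Validation tumors are clustered on
the classifier genes with agglomerative average linkage on 1 − Pearson
correlation distance (Euclidean and complete linkage available), the
dendrogram cut at its top split into exactly two groups; tumors are
processed in sorted-id order so the partition is independent of input
order. The cluster with the larger event fraction is labeled high risk (a
tie falls back to the larger cluster, flagged). Survival comparison uses
the Kaplan–Meier product-limit estimator, the two-group log-rank test, and
a univariate proportional-hazards fit on the high/low indicator by partial
likelihood (Efron tie handling, the lifelines convention; survival times
here are continuous so tie handling is immaterial), reporting exp(β) with a
Wald 95% CI. Clinical factors are dichotomized by declared positive levels
(grade ∈ {3}, ER ∈ {negative}, size ∈ {2–5cm, >5cm}, …) and passed through
the identical HR machinery; a factor missing in more than 20% of tumors is
rejected.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_present_frac` | 0.5 | minimum fraction of Present calls per gene (boundary inclusive) |
| `p_cut` | 0.01 | ANOVA threshold, strict (p < cut) |
| fold grid | 1.5…6.0 step 0.5 | candidate max/min cutoffs (fold ≥ cut, inclusive) |
| fold floor | 1st percentile of positive values | denominator floor for max/min |
| `abs_log2fc_cut`, `altered_p_cut` | 1.0, 0.01 | alteration call thresholds |
| `min_count` | 2 | cohorts required for classifier membership |
| `n_cohorts` (K) | 5 | derivation cohorts (Sub0…Sub5) |
| cluster metric / linkage | correlation / average | tumor clustering options |
| endpoint | metastasis | outcome flag used for risk labeling |

## Numerical conventions

- **Degenerate ANOVA:** zero total variance → p = 1; zero within-group with
  nonzero between-group variance → p = 0 (both logged). The vectorized
  F-test is verified against `scipy.stats.f_oneway` per gene.
- **Zero cells in the odds ratio:** when b = 0 or c = 0 the
  Haldane–Anscombe 0.5 correction is applied to all four cells and the
  result flagged; with no annotated genes at all the ratio is undefined
  (NaN, flagged). When optimizing the fold cutoff, flagged grid points stay
  in the curve but enter the argmax only if no uncorrected point exists: a
  maximum resting on an empty contingency cell is an artifact of the grid's
  tails (where a handful of genes are selected or rejected), not an
  enrichment peak. Argmax ties break toward the smaller cutoff.
- **Fisher's exact test** uses the point-probability two-sided convention
  (sum of probabilities of all same-margin tables no more likely than the
  observed one), matching an exhaustive hypergeometric enumeration oracle
  to 1e−9 on all tables with N ≤ 40.
- **Time-point summary** is the arithmetic mean of replicate linear
  intensities.
- **Degenerate tumors in clustering:** a zero-variance tumor profile has no
  defined correlation; it is held out, the rest are clustered, and it joins
  the nearest Euclidean centroid (logged).
- **Complete separation in the Cox fit** (all events in one group) returns
  an infinite or zero HR with a one-sided CI, flagged, instead of a
  non-converged fit.

## The synthetic-data generator

`SimulationConfig` defaults define the study conditions at desk scale:
2000 genes standing in for a ~12k-probe chip with 35% low-expressed
(Absent) probes, so ~1500 Present probes mirror the real filtered universe;
ten pregnancy-cycle time points with two replicate arrays each (19–20
arrays, hence ~19 nonzero PCs); 30% of genes developmental (growth 15%,
lactation 10%, involution 5%) with a planted max/min amplitude of 3.0;
log-normal replicate noise with log-scale sd 0.1; a reference list
recalling 75% of true developmental genes with 30% contamination; tumor
cohorts of 100 with 44% high-risk tumors, a ±1.5 log2 classifier shift,
exponential survival at 0.01/month baseline hazard with a planted hazard
ratio of 3.5, independent exponential censoring at 0.01/month and 120
months of follow-up.

What it emulates, and how:

- **Developmental genes** get a raised-cosine bump (half-width 2.5
  time-point indices — expression programs span whole phases) peaking at a
  uniformly random time point within their phase block, scaled so the
  max/min of noiseless time-point means equals the planted fold exactly.
- **Non-developmental Present genes are not flat:** they carry
  low-amplitude temporal bumps with fold log-uniform on [1.6, 2.8]. On real
  chips ~90% of Present probes pass the ANOVA filter while the fold cutoff
  does the real discriminating, and the odds-ratio curve is only
  well-defined over a populated fold continuum; perfectly flat background
  genes would empty the rejected subsets below the planted fold and
  degenerate the curve.
- **Tumor cohorts** draw two latent classes whose classifier-gene profiles
  shift in opposite directions (+fc and −fc per gene-fixed sign), making
  each class an internally coherent expression block — the structure
  correlation-distance clustering actually needs. Derivation cohorts are
  generated with `frac_high_risk = 1` so the alteration is a cohort-level
  property (a tumor-vs-reference-pool contrast), while validation cohorts
  keep the two-class mixture; each pipeline derivation cohort additionally
  alters a cohort-specific random subset of developmental genes so
  alteration counts populate the full Sub0…SubK range.
- **Streams:** every artifact draws from its own generator seeded by
  (seed, artifact-tag), so adding artifacts never perturbs existing ones;
  identical configs reproduce identical bytes on disk.

What it does **not** emulate: probe-level chip physics and normalization,
batch effects, correlated gene-gene noise, non-proportional hazards,
platform differences between cohorts, or informative censoring. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under its own model assumptions, not that those assumptions hold for any
particular real dataset.

## Problem sizes and verification

The test suite runs the generator defaults for recovery checks: fold-cutoff
recovery over 50 seeds, phase recovery over 20 seeds, alteration-call and
classifier recovery over 20 seeds (cohorts of 50 tumors, log2fc 2, sd 0.5),
and the end-to-end survival chain over 50 seeds at 300 tumors with a
planted hazard ratio of 3.5. At ~59% observed events per 300-tumor cohort
the Cox estimate of a true log HR has standard error ≈ 0.15, so individual
estimates scatter roughly ±30% around the planted value even when the risk
partition is recovered exactly; single-seed hazard ratios should be read
with that width in mind.

## Known limitations

- The hazard-ratio machinery is strictly univariate (as is the comparison
  it supports); no multivariate Cox, time-dependent covariates, or
  competing risks.
- The quadrant rule projects a three-phase cycle onto two components;
  genes peaking near phase boundaries are intrinsically ambiguous, and the
  short involution phase (one time point) is the least well separated.
- Alteration calls reconstruct, with a t-test and fold rule, what source
  databases typically provide as pre-computed lists; when such lists exist
  they can and should be supplied directly.
- Homolog mapping is many-to-one by design; paralog fan-outs must be
  resolved upstream.
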