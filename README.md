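# mamprog

Prognosis classification of breast tumors from mammary-gland developmental
expression programs.

Normal mammary-gland development and breast tumorigenesis reuse the same
cellular machinery — proliferation, differentiation, invasion, angiogenesis,
apoptosis — and genes regulated across the pregnancy cycle are therefore a
principled pool from which to draw prognosis markers. `mamprog` implements
that idea as a tested, reusable pipeline for transcriptomics researchers:

1. **Developmentally associated genes.** From a mouse mammary-gland
   time-course matrix (time points Vir, P1, P3, P7, P12, P17, L1, L2, L9,
   Invol2), probes called Absent are filtered out, each gene is tested by
   one-way ANOVA across time points (p < 0.01), and the max/min fold of its
   time-point mean expression is thresholded. The fold cutoff is not fixed a
   priori: over a grid of candidate cutoffs *c*, genes split into selected
   (fold ≥ *c*) and rejected subsets, and the cutoff maximizing the odds
   ratio of a literature-based reference list,

   OR = (p₁/(1−p₁)) / (p₂/(1−p₂)) = a·d / (b·c),

   where p₁ and p₂ are the reference fractions in the selected and rejected
   subsets, is chosen.
2. **Developmental phases.** Each selected gene's profile is standardized to
   mean 0 / variance 1 across arrays; PCA (genes as observations) places
   genes in the PC1–PC2 plane; after deterministic sign orientation against
   the peak-time structure, quadrants define the phases: growth (PC1 > 0),
   involution (PC1 ≤ 0, PC2 > 0), lactation (PC1 ≤ 0, PC2 ≤ 0).
3. **Prognosis classifier.** In each of K tumor cohorts (log2 ratios vs a
   reference pool), a gene is "altered" when |mean log2 ratio| ≥ 1 with a
   one-sample t-test p < 0.01. Developmental genes partition into
   Sub0…SubK by their alteration count; those altered in ≥ 2 cohorts form
   the prognosis classifier.
4. **Outcome prediction.** Tumors of a validation cohort are clustered into
   two groups on the classifier genes (1 − Pearson distance, average
   linkage, dendrogram cut at the top split); the cluster with the larger
   event fraction is the high-risk group. Prediction quality is quantified
   by accuracy, Fisher's exact test, Kaplan–Meier curves, the log-rank test,
   and the univariate proportional-hazards hazard ratio, with the same HR
   machinery applied to clinical risk factors (size, grade, ER status, …)
   for comparison.

A synthetic-data module generates all inputs with known ground truth —
phase-structured time courses with a planted fold amplitude, reference lists
with controlled recall/contamination, and tumor cohorts with two latent risk
classes and a planted hazard ratio — so every stage is testable end to end
without external data.

## Worked example

Run the whole pipeline on synthetic data (2000 genes, ten time points with
two replicate arrays each, five derivation cohorts and one validation cohort
of 100 tumors):

```sh
mamprog run-all --workdir demo --seed 7
```

which prints one JSON line of key numbers per stage:

```
{"devgenes": {"best_cutoff": 3.0, "best_odds_ratio": 9.31, "n_developmental": 584,
              "n_present": 1510, "n_p_passing": 1496, "dev_fraction_of_present": 0.387}}
{"phases": {"n_growth": 292, "n_lactation": 130, "n_involution": 162,
            "n_nonzero_components": 19, "pc1_variance_fraction": 0.331}}
{"enrich": {"odds_ratio": 6.54, "fisher_p": 1.5e-14, "cancer_gene_coverage": 0.788}}
{"classifier": {"classifier_size": 123, "sub0_n": 327, "sub1_n": 134, "sub2_n": 31,
                "sub3_n": 4, "sub4_n": 0, "sub5_n": 88}}
{"prognosis": {"accuracy": 0.68, "fisher_p": 2.2e-4, "hazard_ratio": 3.48,
               "hr_ci_low": 2.00, "hr_ci_high": 6.05, "logrank_p": 3.0e-6}}
```

Reading these numbers: the odds-ratio curve peaks at the 3-fold cutoff —
exactly the amplitude planted in the simulated developmental genes — and
584 of 1510 Present genes (39%) are called developmentally associated. The
simulated involution phase is deliberately short (one time point), so its
phase count overshoots at this noise level while growth and lactation are
recovered closely. 123 genes are altered in at least two derivation cohorts
and become the classifier; clustering the validation cohort with them splits
it into groups whose observed outcomes differ strongly (hazard ratio 3.5,
log-rank p ≈ 3×10⁻⁶), and 68% of tumors have their eventual outcome
predicted correctly — outcome is stochastic given risk class, so this is
far below the perfect recovery of the latent classes themselves.

Every stage is also exposed as a library function (`mamprog.devgenes`,
`mamprog.phase_pca`, `mamprog.enrichment`, `mamprog.classifier`,
`mamprog.prognosis`) and as an individual CLI subcommand operating on the
TSV formats documented in `mamprog.data_model`, including a standalone 2×2
enrichment mode:

```sh
mamprog enrich --selected dev.txt --annotated cancer.txt --universe present.txt
```

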