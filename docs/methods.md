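# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the procedure was genuinely open.

## The catalogue

The registry covers genes directly executing or supporting glycan assembly.
Each gene carries a non-empty subset of the five pathways {N_linked,
O_linked, GPI, Lipid, GAG}; the *effective class* is the single pathway, or
`Multiple` for genes in two or more (per-pathway double counting is
available behind `class_counts(per_pathway=True)` but off by default, so
class counts sum to the catalogue size). Percentages are rounded
half-away-from-zero to whole numbers, matching how such compositions are
conventionally printed. pLI categories use the community cutpoints 0.1/0.9
(tolerant < 0.1 ≤ intermediate < 0.9 ≤ intolerant). Missing pLI/ClinVar
annotations are logged and tolerated; missing ClinVar flags count as
not-pathogenic in fractions.

The packaged table is a **synthetic reconstruction**: real HGNC-style gene
symbols with plausible pathway and function assignments, constrained so the
aggregate composition (242 genes; 70/74/21/30/15/32 across the six
effective classes; 74% transferases, 10% hydrolases; 41% pathogenic overall,
81% in GPI, 23% in O-linked) is exact. Per-gene annotations are not claimed
to be individually authoritative — analyses that consume the catalogue use
only the aggregate structure.

## Tissue specificity

Classification uses tissue-level arithmetic means. With fold *f* = 5 and
expression floor 1 (matrix units):

- **Tissue Enriched**: top tissue ≥ f × max(other tissues). Comparisons are
  inclusive (≥), so a ratio of exactly 5 qualifies.
- **Group Enriched**: a group of 2–7 tissues, every member ≥ f × max outside
  the group. The search is greedy over the descending-mean order; for f > 1
  any qualifying group must be a top-k prefix of that order (a member below
  an outside tissue would need mean ≥ f × something larger than itself), so
  the greedy scan is equivalent to exhaustive subset search — the test suite
  verifies this against full enumeration on ≤ 8 tissues.
- **Tissue Enhanced**: top tissue ≥ f × mean(other tissues). Only the top
  tissue needs checking: for any other tissue the inequality implies it for
  the top.
- Genes under the floor in every tissue are Not Specific.

The predictive benchmark trains one random forest (500 trees, stock feature
subsampling) per model on a fresh per-tissue stratified 75/25 split
(train size floored, ≥ 1 test sample per tissue; tissues under 4 samples
are an error) over a random panel of 30 pool genes, and scores the pooled
test confusion matrix with the Gorodkin multiclass MCC. One MCC per model;
the seed drives gene sampling, splitting and forest fitting, so results are
reproducible. Degenerate confusion matrices (single observed class) return
NaN with a warning rather than a fabricated score.

## Co-expression

Pearson correlations are computed across samples within each tissue
(minimum 10 samples; constant genes dropped per tissue), with p-values from
t = r·√((n−2)/(1−r²)) on n−2 df. Edges with |r| > 0.8 and raw p < 0.05 are
aggregated per (pair, sign) into tissue-support counts; a BH option exists
but defaults off since the filtering convention uses raw p. Both the count
of unique pairs and of pair-tissue records are exposed, since "number of
correlated pairs" is ambiguous between the two.

Anti-correlated clusters in one tissue: build the graph of |r| > 0.8 edges,
take connected components of the positive-edge subgraph, and report the
component pair with the most negative edges between them. A negative edge
inside a component marks the signed graph frustrated; the partition is
still returned, flagged `balanced=False`.

Multiplicative (log-scale) co-regulation only appears as *negative linear*
correlation after a log transform — on the raw abundance scale the
correlation of x and 1/x-type relations is compressed toward zero. The
`log2_transform` option of `tissue_correlations` applies log2(x+1) first
and is used wherever anti-correlation structure matters.

## Evolution

Duplication epochs are compressed along an ordered human lineage: taxa
ancestral to Vertebrata → *chordates*; ancestral to Mammalia (but not
Vertebrata) → *vertebrates*; everything later → *mammals*, with
human-terminal duplications excluded. The divergence score z-scores one
gene's expression across **all** species × tissue observations (global
scaling; per-species scaling is available behind a flag since either
reading is defensible), computes each tissue's SD across species (sample
SD, n−1), and returns the minimum with its tissue. The global z-score makes
the score invariant to affine rescaling of the raw values; species–tissue
pairs absent from the panel are skipped, not imputed; a panel with zero
overall variance scores 0 by convention.

## Age/sex covariate scan

Per tissue and gene, OLS of expression (normalized abundance scale, no log)
on age in decades (decade code = lower bound / 10) and sex (F=0, M=1, so
the coefficient is the M−F difference). Two-sided t-test p-values are BH-
adjusted within tissue across genes, separately for the age and sex
vectors; the family is configurable to global. Single-sex tissues drop the
sex term; tissues under 10 samples are skipped; constant responses return
coefficient 0 with p = 1; collinear designs raise.

## Oncogenomics

Alteration prevalence counts each patient once per gene: mutated (any SNV),
amplified (focal score ≥ +1), deleted (≤ −1); the ±2-only convention is a
flag. Ranking pools cancer types by averaging per-type percentages with
equal weights, ties broken lexicographically.

TMM normalization follows the published recipe: reference = library whose
75th-percentile scaled count is closest to the mean of those quantiles;
per-library trimmed (30% of M, 5% of A, from each tail, rank-based),
precision-weighted mean of M values; factors scaled to geometric mean 1.
The implementation agrees with edgeR's `calcNormFactors` to 1e-6 and with
an independently written sort-based oracle in the test suite.

Paired differential expression is a per-gene paired t test on within-patient
(tumor − normal) differences of TMM-normalized log2-CPM (prior count 0.5),
BH across genes. This is a deliberate stand-in for moderated linear
modelling (precision weights + empirical-Bayes shrinkage): it is assessed
on direction and fold-change recovery and FDR control on planted data, not
on numerical identity to any specific implementation. With small gene
panels the planted gene can be a visible fraction of the library; TMM
absorbs most of the resulting composition shift, and the fold-change
estimator is unbiased across replicate cohorts (the acceptance script
averages 5 cohorts of 20 pairs).

Survival uses the standard two-group log-rank test (lifelines), altered vs
unaltered per gene, with groups under 5 patients skipped in the scan and BH
across tested genes.

## Microenvironment screens

Correlation counting: per cancer type, Pearson r between each gene's
expression and each immune-cell fraction; per gene × cell type, the number
of cancers with p < 0.05, with positive/negative support kept separately.
Counting is monotone in the threshold.

Lasso screens: features standardized internally; penalty chosen by k-fold
CV (k = 10; plain random, seeded fold assignment) at minimum mean squared
error; per-fold explained variance cv_r2 = 1 − MSE_fold / Var(y_fold);
significance when mean(cv_r2) − SD(cv_r2) > 0 (the across-fold SD).
Importance ranks order |standardized coefficient| among nonzero features.
**eval_r is computed from out-of-fold predictions** at the chosen penalty
rather than from an in-sample refit: measured on null responses, in-sample
refit predictions exceed r = 0.3 in ~14% of runs (the lasso at the
CV-chosen penalty still fits noise in-sample), which would defeat the
display rule's purpose of rejecting uninformative models; out-of-fold
predictions reject null models reliably while admitting planted signals.
The ITH screen applies the same contract to clone counts, with feature set
(expression / alteration flags / both) configurable.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) through one
`numpy.random.Generator`; no global state. Conditions chosen for realism
and stated for reproducibility:

- Baseline expression per gene: 2^N(1,1) (log-normal on the log2 scale);
  residual log2 noise sd 0.5 by default; planted specificity multiplies the
  target-tissue mean by the design fold; co-expression blocks share a
  per-sample latent N(0,1) factor with configurable loading and signs.
- Age decades uniform over codes 2–7; sexes balanced. Age effects are
  additive on the abundance scale; the planted trend is offset to be
  non-negative over the observed age range, because clipping at zero would
  otherwise flatten negative slopes for low-expressed genes (a constant
  offset changes the intercept, never the slope).
- Species panels: conserved genes share a tissue profile across species up
  to log2 noise; divergent genes get independently redrawn, shuffled
  profiles per species.
- Tumor cohorts: SNVs Bernoulli(rate); CNAs non-zero with the stated rate,
  amp/del split 50/50, magnitude 1 vs 2 at 70/30; counts negative binomial
  with dispersion 0.1 and per-library depth in [0.8, 1.2], tumor means
  scaled by 2^lfc; immune fractions Dirichlet over ten cell types plus an
  explicit `Other` component so rows sum to 1, with expression-linked
  shifts renormalized into `Other`; survival exponential (base hazard
  1/1000 days) with per-gene hazard multipliers for altered patients and
  administrative censoring at 3000 days; clone counts 1 + Poisson with
  expression-shifted rate.

What the generators do **not** emulate: read-level sequencing noise, batch
and platform effects, donor-level correlation between tissues, GISTIC
segmentation artifacts, realistic linkage between mutations and expression
in cis, or compositional coupling between immune fractions beyond the
Dirichlet. Passing tests therefore demonstrate that each statistical
procedure recovers the structure it targets under its stated model — not
that consortium-scale results would reproduce numerically; those depend on
the real data's richer covariance structure.

## Problem sizes and determinism

Test and acceptance runs use deliberately compact problem sizes — e.g.
10 tissues × 20 samples for the MCC benchmark (10 models per pool),
n = 1000 patients for rate recovery, 1000 simulations for log-rank null
uniformity, 20 signal seeds and 100 null runs for the lasso screens —
chosen so each stage's recovery or calibration claim is testable with
stable margins. Every stochastic step is seeded; the CLI writes a manifest
(parameters, seed, input checksums) per stage and reruns are byte-identical.

## Known limitations

- The greedy group search's equivalence to exhaustive enumeration holds
  for fold > 1; at fold = 1 ties across the group boundary could admit
  non-prefix groups (not a practically used setting; the classifier
  requires fold ≥ 1).
- The paired-DE stand-in does not share information across genes, so it is
  conservative at very small pair counts relative to moderated approaches.
- `anticorrelated_clusters` reports the best pair of components only;
  more than two mutually opposing programs would need repeated application.
- The catalogue's per-gene annotations are synthetic (see above).
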