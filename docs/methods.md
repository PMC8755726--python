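# Methods

## Read disambiguation

A read's evidence is reduced to its per-organism hits (the alignment TSV
dialect: `read_id, organism, gene_id|-, n_hits`, with up to 50 reported
loci per read).  Classification is purely rule-based: hits on one genome
give `human_only`/`mouse_only`, hits on both give `ambiguous`, no records
give `unmapped`.  The default `paper_asymmetric` split keeps ambiguous
reads in the human (graft) set and removes them only from the mouse (host)
set.  The rationale is asymmetric contamination risk: the graft dominates
the library, so a read cross-mapping to a conserved mouse locus is far more
likely a human read than the reverse, and the small stromal signal is the
one that needs protecting.  `strict_both` removes ambiguous reads from
both sides for sensitivity analysis; by construction the human count under
the asymmetric policy is never smaller, and mouse counts are identical.

Multi-gene reads are assigned to a single gene by a seeded uniform choice
among their hit genes, in sorted read order so the assignment is
reproducible and independent of input ordering.  This is a deliberate
simplification of expectation–maximisation rescue: it preserves column
totals and determinism, at the cost of slightly noisier per-gene counts
for paralogous families.  Intergenic-only reads are dropped.

## Normalisation, filtering and differential expression

Expression is `log2(rpkm + 1)` with `rpkm = count · 1e9 / (length ·
library_size)`; the pseudocount of 1 maps zero counts to 0 on the log
scale.  The expressed-gene filter keeps genes with log2(rpkm) strictly
above 1 in at least one sample — strict, so a gene sitting exactly at the
threshold in every sample is dropped.

The DE stage is a negative-binomial Wald test built for calibrated
p-values and near-unbiased fold changes at small replicate numbers:

* size factors by median-of-ratios against the geometric-mean reference,
  normalised to geometric mean 1;
* per-gene dispersion by method of moments, pooled within groups
  (`alpha = (var − mu·E[1/s]) / mu²`, floored at 1e-8), then shrunk
  halfway in log space toward a parametric trend `alpha(mu) = a0 + a1/mu`
  fitted by least squares over informative genes.  Halfway shrinkage is a
  fixed compromise: full shrinkage erases genuine dispersion differences,
  none leaves 4-vs-4 moment estimates too noisy for a stable Wald test;
* log2 fold change from normalised group means with a 0.5 pseudocount
  (negligible bias at moderate counts, finite at zero), and a delta-method
  standard error `Var(log mû) = Var(mû)/mû²` with
  `Var(mû) = n⁻² Σ_j (mu/s_j + alpha·mu²)`.

On a 2,000-gene null (permuted labels, dispersion 0.05, mean ~150) the
p-value distribution is uniform (KS < 0.05), and planted log2FC = 2 genes
at mean 200, 4 vs 4, are recovered with adjusted p < 0.05 and |error| ≤ 0.5
in ≥ 95% of replicates — the two properties that qualify the stage for the
downstream crossing procedure.  All-zero genes are excluded from testing.

DE thresholds are organism-specific: |log2FC| ≥ 1 (human) or ≥ 0.5
(mouse), FDR < 0.05 for both.  The fold-change comparison is inclusive and
the FDR comparison strict.  The looser mouse cutoff reflects the diluted
stromal signal in bulk xenograft RNA.  Protein-coding restriction is
delegated to the input annotation; no biotype database is bundled.

## Signature derivation and scoring

Correlation with the anchor gene is Pearson on log-scale expression (the
scale the cohort matrices are stored on); the passing rule is strict,
|R| > 0.225.  Zero-variance genes are excluded.  Derivation intersects
passing genes with the DE set by exact label equality and partitions by
sign concordance; discordant genes (R and FC of opposite sign) are kept as
a separate reported list but never scored.  The procedure is deterministic
and order-independent.

The per-sample score z-scores each signature gene across cohort samples
(population SD — these are display/score standardisations, not inferential
quantities) and combines them as `(Σ_up z − Σ_down z) / (n_up + n_down)`,
i.e. each sub-list is weighted by its size.  An unweighted variant
(`(mean_up z − mean_down z)/2`) is available; with balanced sub-lists the
two coincide.  The score is invariant to per-gene affine rescaling of raw
expression, so platform-specific gene scaling cannot move it.

## Survival analysis

Kaplan–Meier estimation is the standard product-limit estimator (via
lifelines); tied event times form a single step, censored subjects shrink
the risk set silently.  Both two-sample tests share one weighted-logrank
core — O−E with hypergeometric variance at each distinct event time —
with weights 1 (logrank) or the number at risk (Gehan–Breslow–Wilcoxon,
early-event emphasis).  Both tests are always reported.

Dichotomisation uses strict `value > cutoff` for "high"; ties go low.
When no cutoff is given, `scan_cutoff` evaluates every inter-sample
midpoint keeping both groups at ≥ 10% of the cohort and returns the
minimum-p cutoff.  Because this minimum is taken over many correlated
tests, its naive p is anti-conservative (empirical type-I error ~0.4 at
nominal 0.05 in the package's own null simulation); the scan therefore
always also returns a permutation-adjusted p (`(1 + #{perm min-p ≤ obs
min-p}) / (B + 1)`, default B = 200) and the full scan table, keeping the
multiple-testing exposure visible.  Time units are caller-declared
metadata and never converted.

## Secretome chain

Ingest converts zero-coded intensities to explicit missing values; the
matrix is log2 LFQ.  Filtering keeps proteins with ≥ 2 supporting peptides
and no missing value in at least one complete condition.  Imputation
draws each missing cell from `Normal(mu_s − 1.8·sigma_s, (0.3·sigma_s)²)`
where `mu_s, sigma_s` are the observed moments of that sample (per-sample
mode is the default; a whole-matrix mode is available by flag).  This
models detection-limit censoring: imputed values sit below the observed
mean with probability > 0.99.  Testing is a per-protein unpaired Student
t on the imputed matrix with BH control at q < 0.01 (a 0.02 preset is also
shipped); reported group means are recomputed from observed cells only, so
output tables never contain imputed numbers.  ΔLFQ is mean(control) −
mean(knockout): positive means higher secretion under the anchor-expressing
condition.

A power caveat documented deliberately: with 3 replicates per arm the
Student t has 4 degrees of freedom, so a true ΔLFQ of 2 at replicate SD
0.5 yields p ≈ 0.008 — real, but far above the ~10⁻³ BH threshold implied
by q < 0.01 with a 10% effect fraction.  In this regime the chain's
discoveries are dominated by censoring-driven proteins (fully missing in
one condition, imputed far down), and sensitivity to moderate complete-case
effects is near zero.  This is a property of the design (n = 3, plain t,
q < 0.01), not of the implementation; the package reports it honestly
rather than substituting a moderated test.

## Statistical primitives

Exact Mann–Whitney uses the enumerated null of U when n1 + n2 ≤ 20 and the
pooled data are tie-free, otherwise a tie-corrected normal approximation
(logged).  The two-sided p is twice the smaller tail, capped at 1, and the
reported U is min(U_x, U_y).  Fisher's exact test is two-sided by the
probability-mass rule (sum of margin-preserving tables with probability ≤
observed) — the convention of mainstream implementations; degenerate
margins return p = 1 with a warning.  Both are verified against
independent brute-force enumeration in the test suite.  BH adjustment is
the standard step-up with cumulative minimum, order-preserving.
Hypergeometric enrichment is one-sided (over-representation only;
depletion is not tested), computed on sets intersected with the universe,
reporting only sets with k ≥ 1; the universe defaults to the post-filter
expressed gene list, and the significance flags use p < 0.001 with
adjusted p < 0.01 (human presets; 0.01/0.1 for mouse analyses).  Tumour
volumes are the printed caliper/ultrasound formulas: `4/3·π·(d·s·t)/6`
(orthotopic, 3 diameters) and `l·w²/2` (subcutaneous).

## Synthetic data

The generators emulate the shapes of the real designs at desk scale:

* **Cohort** (default 498 samples × 2,000 genes): expression is simulated
  directly on the log2 scale — cohort analyses operate on
  platform-normalised expression, so no count layer is simulated.  The
  anchor is a standard-normal latent; 100 + 100 planted genes are
  `±rho·anchor + noise` at rho = 0.6; all other genes are independent.
  The latent score is the mean planted-gene z (anti-correlated genes
  flipped).  Survival is exponential proportional hazards
  (`rate ∝ HR^score`, default HR 2 per score SD, baseline median 60
  months) — the simplest model satisfying the assumptions KM/logrank make
  — with random censoring (probability 0.3 of replacing the event time by
  a uniform draw below it).  MNA/risk/stage labels are drawn with
  score-dependent log-odds (baseline MNA fraction 0.2).
* **Xenograft** (4 vs 4): NB counts, lognormal baseline around mean 200,
  dispersion 0.05, 200 planted genes at |log2FC| = 2 split symmetrically
  around the baseline; the dispersion → 0 limit is Poisson.  Alignment
  records (default 4,000 reads, 10% ambiguous, 25% host) carry exact class
  labels; gene assignment follows the first control sample's count
  proportions.
* **Secretome** (3 vs 3, 1,000 proteins): per-protein abundance
  Normal(25, 2) on the log2 scale, replicate SD 0.5, 10% planted at
  |ΔLFQ| = 2; missingness is logistic in the true cell intensity (ceiling
  0.9, midpoint 1.5 SD below the abundance mean), concentrating ≥ 70% of
  missing cells in the lowest intensity tercile — exactly the
  left-censoring the downshift imputation assumes.  A 10% single-peptide
  fraction exercises the filter.
* **Gene sets / annotations**: random sets plus one set seeded with
  planted DE genes; a random subset of genes is tagged with crosstalk
  categories (growth factor, cytokine/chemokine/inflammatory mediator,
  integrin and ligands, receptors).

Everything is deterministic under the config seed; each generator returns
a ground-truth sidecar (JSON-serialisable), and all recovery tests consume
only the sidecar.  What the generators do **not** emulate: real cohort
correlation structure (gene–gene blocks beyond the anchor), batch and
library-composition effects, isoform structure, peptide-level identity,
non-proportional hazards, or informative censoring.  Passing recovery
tests therefore demonstrate that the chain's logic and calibration are
correct under its stated assumptions, not that any specific biological
list would be reproduced on real downloads.

## Problem sizes

Defaults were chosen to keep every analysis a desk-scale computation: the
full-scale recovery runs use the 498 × 2,000 cohort and 200 planted genes;
DE recovery aggregates 200 replicates of a 300-gene experiment; scan
calibration uses 120 null cohorts of 50 with 100 permutations each; null
uniformity checks use 1,000–2,000 replicates.  The acceptance script
completes in about a minute on one core.

## Known limitations

* The read classifier consumes pre-parsed per-organism hits, not raw SAM;
  a thin adapter is required for aligner output.
* Single-factor DE design only; no covariates, no isoform testing.
* No Cox regression or multivariable survival adjustment.
* Gene-set analysis requires user-supplied GMT files; no ontology
  traversal.
* The whole-matrix vs per-sample imputation choice matters for strongly
  unbalanced missingness; per-sample is the default.
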