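# Methods

This note documents the statistical models implemented in `lactolink`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the conditions under which the
package's operating characteristics are measured.

## Co-occurrence screen

For genes A and B in the cells of one cell type within one sample, let N be
the number of cells, K and n the cells detecting (count ≥ 1) A and B, and k
the cells detecting both. The test statistic is the inclusive
hypergeometric upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n), computed
via the survival function at k − 1. Only enrichment is tested (depletion is
not of interest here), and the tail is symmetric in (K, n).

Eligibility gates the test: each gene must be detected in at least 2% of
the N cells *and* in at least 5 cells. The 2% bound is applied to the
real-valued quantity 0.02·N without rounding. Detection is count ≥ 1
exactly; no normalization enters the screen.

No multiplicity correction is applied across pairs within a sample. The raw
p ≤ α rule (α = 0.05 by default) is intentionally liberal per sample;
reproducibility across independent samples — the percentage of eligible
samples reaching significance — is the guard against false positives, and
results should only ever be read at that level.

Two behaviors worth knowing:

* **Discreteness.** The exact test is conservative: P(p ≤ α) < α, with the
  gap shrinking as the margin standard deviation √N/4 grows. In small
  populations (hundreds of cells) the realized null rate is ≈ 0.035–0.04
  at α = 0.05; with tens of thousands of cells and ~50% detection it is
  ≈ 0.05. Null-calibration checks are therefore run in the large-margin
  regime (see below).
* **Ubiquitous genes.** A gene detected in every cell yields p = 1 by
  construction — universal expression carries no co-variation information.

Top pairs (default 200, ranked by reproducibility percentage with ties
broken by eligible-sample count and then pair name — the ranking rule is a
convention, since no canonical rule exists) are clustered by median linkage
(WPGMC) on Euclidean distances between their reproducibility vectors across
cell types.

## Mixed-model associations

Each HMO concentration is analyzed on the z-score scale (subtract mean,
divide by sample SD; the transform is classic z-scoring) with

    z(y) = β₀ + β₁ z(t) [+ β₂ z(prop)] + u_donor + ε,   u_donor ~ N(0, σ_d²)

fit by maximum likelihood with statsmodels `MixedLM` (lbfgs first; bfgs and
powell as fallbacks when lbfgs stalls, with the convergence flag reporting
only genuine convergence). Wald tests use a t reference with between-within
denominator degrees of freedom, df = n_samples − n_donors − p, where p
counts fixed effects beyond the intercept: at cohort sizes of a few dozen
samples a plain normal reference is measurably anti-conservative (null
rejection ≈ 0.08 at 10 donors × 3 samples), while the between-within t
keeps the null rate at ≈ 0.06. This is the package's small-sample
calibration choice.

BH correction is applied across HMOs as one family for the time model, and
per cell type across HMOs for the proportion models. Samples with missing
time postpartum are rejected explicitly rather than silently dropped.

## Pseudobulk NB-GLM differential expression

Counts are summed over the cells of each (sample, cell type) group; rows
with zero cells are never emitted. Size factors are median-of-ratios over
the genes with nonzero counts in every row (the geometric mean is undefined
otherwise). Each gene is modeled as NB(μ, α) with variance μ + αμ², log
link, and log-size-factor offsets, fit by IRLS (statsmodels GLM).

Dispersion is estimated per gene in two steps. A design-aware moment
estimate first fits per-gene means by a Poisson GLM with the model's own
design matrix, so covariate-driven structure (cluster, donor, concentration
links) is not absorbed into α, and applies an n/(n−p) residual-df
correction. The estimate is then refined by maximizing the Cox–Reid
adjusted profile likelihood (NB likelihood minus ½ log det X′WX) at the
fitted means. The adjustment is a bias correction, not shrinkage: no
information is shared across genes, which keeps estimates honest but
noisier than shrinkage-based DE tools. The dispersion floor is 1e-8;
all-zero genes are flagged at the floor.

Designs:

* **Cluster contrast** — `~ study + cell_type`, Wald z on the cell-type
  coefficient, two-sided normal p, effect reported as log2 fold change.
  Rank-deficient designs fail fast and name the collinear columns.
* **Concentration LRT** — full `~ donor + z(time) + z(HMO)` versus reduced
  `~ donor + z(time)`, statistic 2(ℓ_full − ℓ_reduced) clipped at 0 on 1
  df, sign and log2-per-SD effect from the full-model coefficient. Donors
  enter as fixed indicators. Because the nuisance covariates are projected
  out, only the within-donor, detrended component of the concentration is
  testable; an HMO whose variation is mostly trajectory-driven will
  legitimately show little association even for truly linked genes.

Convergence uses deviance tolerance 1e-8 with at most 100 iterations;
non-converged genes are flagged and excluded from the BH family. The
per-sample log2 fold change between two cell types is
log2((CPM_A + 1)/(CPM_B + 1)) — CPM with pseudocount 1 defines "normalized
expression" here, a convention chosen for scale-freeness at pseudobulk
depths. Calibration measured under the reference conditions below: Wald
null rejection ≈ 0.05 at 48+ samples; the LRT statistic is ≈ χ²₁ (KS
distance ≈ 0.05 at 40 samples) but runs anti-conservative when the
residual df after donor indicators drops below ~10 — at 10 donors × 2
samples expect null rates near 0.1 and read adjusted p-values accordingly.

## Enrichment

Ranking: score = sign(log2FC)·(−log10 max(p, 1e-300)); the floor prevents
infinite scores from underflowed p-values. Ties break by |log2FC| then gene
name. The running sum increments |score|^w / Σ_set|score|^w at set members
(w = 1 by default) and decrements 1/(N − N_set) elsewhere; ES is the signed
maximum deviation. With w = 0 the statistic reduces to the two-sample
Kolmogorov–Smirnov distance between member and non-member rank positions,
which serves as an independent cross-check. The permutation null draws
random member positions of the same size (a gene-label permutation);
p-values are computed within the sign-matched tail, doubled, and capped at
1. Sets with no overlap with the ranked universe, or covering it entirely
(decrement denominator zero), are skipped with a log entry. The leading
edge is the member genes at or before the extremum for positive ES, at or
after it for negative ES.

MeanRank TF aggregation: per library, every set is scored against the input
list by the one-sided Fisher exact test (the same hypergeometric kernel as
the co-occurrence screen), BH-adjusted within the library; each TF keeps
only its lowest-raw-p set; integer ranks 1..k follow ascending adjusted p
with ties broken by raw p then TF name (a deterministic convention — the
aggregation scheme itself does not define tie handling); a TF's score is
the mean of its ranks over the libraries containing it. TF identity is the
first space- or underscore-delimited token of the set name.

## Synthetic data generator

The generator emulates the structure of a longitudinal milk single-cell
study with matched HMO quantitation:

* **Cohort** — default 10 donors × 3 samples over days 4–272 postpartum
  with 300–600 cells per sample, matching a cohort of tens of samples
  from ten donors; one synthetic study label (real multi-study structure is
  emulated separately by the DE calibration generator with 2–3 study
  blocks).
* **Counts** — NB(μ, α) via gamma–Poisson with α = 0.3 and per-cell-type
  gene means drawn log-normally (σ = 1) around a baseline mean of 0.5
  UMI/cell, a shallow-coverage regime typical of milk single-cell data.
  Specific genes' means can be pinned (`mean_overrides`) to place planted
  effects in an informative detection regime.
* **Planted co-expression** — a latent per-cell Bernoulli program (on with
  probability 0.5) multiplies both genes' means by the configured factor,
  so joint detection exceeds independence; the factor, not a literal odds
  ratio, is the knob.
* **HMO trajectories** — y = intercept + slope·t + u_donor + ε in nmol/mL,
  truncated at zero by resampling ε (clipping would put a point mass at 0
  and distort mixed-model recovery); configs whose implied mean is negative
  anywhere in the time range are rejected. Default panel: ten HMOs covering
  the declared type-I members (LNT, LNFPI, LNFPII, LSTb, DSLNT) and type-II
  members (LNnT, LNFPIII, LSTc), with intercepts and declines on the scale
  of published absolute concentrations and 3FL rising over lactation;
  aggregate columns are the member sums.
* **Gene–HMO links** — a linked gene's cell-level mean in the configured
  cell type scales as 2^(lfc · z(conc)) with z taken across samples.

All randomness flows from one root seed through named substreams per stage,
so the HMO panel of a full run equals the panel-only fast path
(`simulate_hmo_panel`) under the same config.

What the generator does **not** emulate: real library-size and gene-count
distributions, ambient RNA, doublets, batch effects beyond a study-level
mean shift, gene–gene correlation beyond the planted programs, secretor
polymorphism (all simulated donors are secretors), or real gene catalogs
(names are placeholders with an optional alias list). Passing tests
therefore demonstrate correctness of the statistical machinery under the
declared model, not robustness to the full messiness of real milk
single-cell data.

## Calibration studies (`lactolink.calibration`)

Each study regenerates data and measures an operating characteristic; the
reproduction script reports exactly these numbers. Conditions were chosen
once to match either the stated study sizes or the asymptotic regime a
calibration check requires:

* **Kernel** — exhaustive agreement with exact integer enumeration over all
  ~46k valid configurations with N ≤ 30 (tolerance 1e-12) and margin
  symmetry over 10,000 random tuples.
* **Co-occurrence null** — 8 donors × 3 samples, ~40k cells/sample, ~50%
  detection, 30 disjoint pairs → 720 eligible records; the large margins
  make the exact test's discreteness negligible, and disjoint pairs keep
  records independent so the binomial band applies.
* **Planted pair** — 20 samples, mean multiplier 8 at baseline mean 0.3
  (detection ~0.25 off-program vs ~0.84 on-program).
* **Mixed model** — 200 recovery replicates and 500 null replicates at 10
  donors × 3 samples, donor SD 0.3, residual SD 0.2, slope −0.5 per SD of
  time; the standardized truth is b·sd_t/√(b²sd_t² + σ_d² + σ_e²) ≈ −0.81.
* **NB-GLM** — Wald null over 2000 genes at 3 studies × 24 samples
  (≈ the integrated resource's 71 samples); LFC-2 recovery over 20
  single-planted-gene cohorts at 20 samples/group; LRT power for a
  1 log2-per-SD effect at 10 donors × 2 samples with dispersion 0.1 and
  within-donor-dominated concentration variance; Poisson-limit agreement
  at α = 1e-10.
* **Enrichment** — the 5-gene worked instance (ES = 0.75) against a
  step-by-step walk, and the weight-0 KS reduction over 100 random
  instances.
* **Determinism** — the full pipeline run twice on one seed must produce
  byte-identical outputs (SHA-256 comparison over every written file).

## Known limitations

* Per-gene dispersion estimation without shrinkage needs ~10+ residual df
  for calibrated LRT p-values; below that the test is anti-conservative.
* Mixed-model inference uses a between-within t approximation, not
  Satterthwaite/Kenward–Roger degrees of freedom.
* The preranked permutation null permutes gene labels, not phenotypes, and
  no cross-set NES normalization is applied, so ES values are not
  comparable across very different set sizes.
* The co-occurrence screen cannot rank pairs involving near-ubiquitously
  detected genes (p → 1 by construction).
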