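# Methods

This note documents the statistical models, the defaults and their
rationale, the numerical choices, and the limits of what the synthetic-data
tests demonstrate.

## Phenotype reduction

Each trait is fitted by REML (statsmodels `MixedLM`) as

    y ~ line * treatment + (1 | replicate:treatment:tray)

with line, treatment and their interaction fixed and a single random
intercept per treatment-by-tray cell nested within replicate. The LS mean of
a line × treatment cell is the fixed-effects prediction for that cell —
random tray effects average out. On a complete-block balanced design this is
exactly the arithmetic cell mean (tested to 1e-10); on unbalanced data it is
the GLS estimate at the fitted variance components (tested against an
explicit dense-GLS oracle).

Residual normality is screened per trait with a Shapiro–Wilk test at
α = 0.05 (the decision is per trait, no multiplicity — a one-off transform
choice, not an inference). Rejection with strictly positive values triggers a
log transform and refit; non-positive values keep the identity scale with a
warning; constant residuals make the test inapplicable. Residuals longer than
5000 observations are thinned for the test's validity range.

The REML optimizer occasionally stops before its gradient tolerance on
saturated line×treatment designs; finite estimates are retained (flag
logged) because the GLS fixed effects at a near-optimal variance ratio are
numerically indistinguishable for LS-mean purposes. Only an exception or a
non-finite fit downgrades the model to OLS on the same fixed effects (the
"singular random term" path). `trait_matrix(engine="cell_mean")` bypasses
the model entirely; it is exact for balanced designs and is what the large
simulation studies use.

Trait–trait correlations are Pearson on pairwise-complete LS means over all
trait × treatment column pairs, within and across treatments; the Bonferroni
level divides α = 0.05 by the number of pairs actually tested. Trait PCA
standardizes each trait over line × treatment rows (each genotype appears
once per treatment), drops constant traits, and reports variance fractions
over all components (they sum to 1).

## Genotypes, kinship and structure

Dosages count copies of the **minor** allele (0/1/2, NaN missing); the
association layer negates the coefficient to report major-allele effects, so
there is exactly one internal sign convention. Minor/major assignment is by
non-missing frequency with ties keeping ALT — deterministic, and re-applied
after filtering.

Marker filters remove boundaries inclusively: missing fraction ≥ 0.30 or
MAF ≤ 0.05 drops the marker. Both boundaries matter for marker counts, so
they are pinned by tests.

IBS kinship is K[i,j] = mean over markers non-missing in both lines of
1 − |gᵢ − gⱼ|/2, diagonal forced to 1. Pairwise-complete averaging is the
documented choice for missing calls; a pair with zero overlap is a hard
error. Eigenvalues below −1e-8 are a hard error; tiny negatives are clipped
to zero (logged).

Structure covariates are principal components of the genotype matrix after
per-marker mean imputation, centering, and scaling by √(2p(1−p)); the
line × line covariance is divided by the marker count so duplicating markers
leaves the model unchanged, and the sign convention (largest-magnitude score
positive) makes runs reproducible. The default of 4 components in the scan is
a configurable choice: structure corrections in panels of a few hundred lines
typically need only the leading components, and kinship absorbs finer
relatedness.

## Association (EMMAX approximation)

Variance components are estimated once per trait/treatment under the null:
the restricted likelihood is profiled over δ = σ²_e/σ²_g using the
eigendecomposition of the null-projected kinship, on a 100-point grid over
log₁₀δ ∈ [−5, 5] with bounded local refinement to |Δlog₁₀δ| < 1e-6. A flat
profile (no identifiable genetic variance, e.g. K = I) returns σ²_g = 0 with
a boundary flag; scans then reduce exactly to OLS. Per-marker tests are GLS
in the eigen-rotated basis with V = σ²_g K + σ²_e I fixed — the defining
EMMAX shortcut — vectorized over markers through the Schur complement of the
covariate block. Missing dosages are mean-imputed per marker (the EMMAX
convention); collinear dosages yield missing P-values, logged. The test is a
two-sided F(1, n−q−1): better calibrated than a Wald χ² at panel sizes of a
few hundred.

δ is well identified only when the kinship spectrum is dispersed. Raw IBS on
a structured panel is dominated by one large eigenvalue plus a flat bulk, so
δ estimates on such K are broad; the parameter-recovery test therefore uses a
standardized genomic-relationship matrix with m ≈ n markers, where the
eigenvalue dispersion makes the REML optimum sharp. This affects only what
the recovery test can demonstrate — the pipeline itself uses IBS kinship, as
is standard for this analysis.

## Multiple testing and regions

The effective number of tests is the count of markers surviving windowed LD
pruning: per chromosome, a 100-kbp physical window anchored at the current
kept marker; while any kept pair inside exceeds r² = 0.8 (strictly), the
lower-MAF member of the most-correlated pair is removed (MAF tie → later
position); the anchor then advances by 10 kept SNPs. Removal preference and
tie-breaks are pinned for determinism. The genome-wide threshold is
α/m_eff. r² is the squared Pearson correlation of dosages over
pairwise-complete lines; zero-variance pairs count as 0 (logged).

Regions collapse significant markers (P ≤ threshold, boundary included) and
suggestive markers (smallest ⌈0.05·M⌉ P-values genome-wide per scan, ties at
the cutoff included) into greedy tag-SNP bins at r² ≥ 0.80: repeatedly pick
the marker with the most unbinned companions (tie → leftmost), bin it with
them, repeat. Bins with at least one significant member become regions; the
boundaries are the outermost member positions (nothing is interpolated), the
focal marker is the member with the lowest P, and lengths in Mbp are rounded
half-up to two decimals — the rounding that reproduces printed region
tables. Unique regions merge same-chromosome intervals that overlap
inclusively, carrying all contributing trait/treatment labels.

Note the two distinct r² conventions: pruning removes at r² **>** 0.8,
binning joins at r² **≥** 0.80. They live in separate configurations because
they serve different steps.

## Downstream

Relative effect size is |2β/range| × 100 with range = max − min of the LS
means of that trait/treatment, reported to one decimal (half-up). The
pleiotropy percentile counts markers with **strictly** greater P, so the best
of M markers ranks 100(M−1)/M, never 100; tiers are ≥99 (top1), ≥95 (top5),
≥90 (top10). Self-comparisons are excluded; direction agreement compares
major-allele effect signs between contexts. Candidate genes are all genes
whose [start, end] intersects the region interval (1-based inclusive, any
strand) plus the b nearest genes strictly before the start and after the
stop; chromosome edges yield fewer flanks, logged.

## Synthetic data

The generator emulates what the analysis assumes about a real diversity
panel, not the panel itself:

- **Structure** — Balding–Nichols: ancestral frequencies uniform on
  (maf_floor, 1−maf_floor), subpopulation frequencies Beta-diverged at Fst
  (default 0.15, 3 subpopulations — moderate crop-panel structure).
- **LD** — one latent haplotype per line per chromosome from a first-order
  copying chain (state copied from the previous marker with probability
  `ld_persist`, default 0.9 → geometric blocks of ~10 markers). Dosage is
  twice the haplotype state (fully inbred); residual heterozygous calls
  (default 2%) and missing calls (default 5%) are injected afterwards as
  mutually exclusive noise, matching panels where het calls are treated as
  noise and converted to missing.
- **Density** — default chromosomes are 10 Mb with ~10 kb marker spacing:
  the SNP density of a large shotgun marker set, scaled down in chromosome
  count and length so physical pruning windows contain whole LD blocks at
  desk scale.
- **Phenotypes** — y = μ_t + Σ β_qt·x_q + u_i + γ_it + tray(rep,trt) + ε
  with u ~ N(0, σ²_line·K_true) drawn against the IBS kinship of the
  noise-free panel, and independent normal line×treatment, tray and residual
  effects (defaults 1.0 / 0.2 / 0.1 / 1.0 in squared trait units — GxE and
  tray effects present but subordinate to line variance, as in replicated
  growth-room designs). The default design is 3 replicates × 2 treatments ×
  4 trays. Truth tables record each QTL's effects and its true relative
  effect size against the realized range of true line means, so recovery
  tests never reverse-engineer the generator.

What the copying chain does **not** emulate: coalescent genealogies, mutation
/ recombination-rate heterogeneity, allele-frequency–LD coupling, selection,
or realistic long-range admixture LD. Adjacent-marker r² under the chain is
roughly `ld_persist`-bounded, so blocks have soft edges rather than
haplotype-sharp ones; passing tests show the pipeline recovers planted
signals under honest LD and structure, not that it reproduces any particular
real panel's region count.

## Problem sizes and determinism

A single seed drives every stochastic stage through named substreams
(CRC32-keyed `SeedSequence`), so stages can be regenerated independently and
reruns are byte-identical. Simulation studies in the test suite use panels of
200–500 lines and 1200–5000 markers with 20–50 replicates per claim — sizes
chosen so each Monte-Carlo claim has comfortable margins at its stated
success fraction. The planted-QTL recovery study (250 lines, 5000 markers,
20 seeds, QTL at 0.5 trait SD per allele copy) reduces phenotypes via the
balanced-design cell-mean identity rather than per-seed REML fits; the two
paths agree exactly on balanced data by construction.

## Known limitations

- Exact per-marker REML (full EMMA) is out of scope; the single null-fit
  approximation slightly misstates variance components at strongly
  associated markers, as is inherent to the method.
- LS means assume the package default estimable-function weighting (equal
  treatment weights through the saturated fixed model); other weightings
  would shift unbalanced-cell estimates.
- The pruning step's window/step semantics (physical window, step in kept
  SNPs) and tie rules are pinned choices among several defensible readings
  of the `indep-pairwise` convention.
- Gene lists depend entirely on the supplied GFF3; genes absent from the
  annotation, and regulatory variants between genes beyond the b-gene
  buffer, are invisible to the rule.
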