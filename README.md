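# seedgwas

Mixed-model genome-wide association for inbred diversity panels phenotyped
under **two treatments** (e.g. well-watered vs. water-limited seedlings), with
the full downstream chain used in plant stress-physiology GWAS: LD-aware
multiple-testing correction, LD-delimited associated regions, relative effect
sizes, a percentile-rank pleiotropy screen, and buffered candidate-gene lists.

## Who it is for

Quantitative geneticists mapping seedling growth or root-architecture traits
in structured panels of homozygous lines (association-mapping panels of crop
cultivars or inbred accessions), where per-marker tests must be corrected for
both population structure and kinship, and where single-marker hits are more
usefully reported as LD-coherent genomic regions with candidate genes.

## The model

Phenotypes are first reduced to least-squares means per line × treatment from
a linear mixed model

> y = line + treatment + line×treatment + (treatment:tray | replicate) + ε

fitted by REML (traits with Shapiro–Wilk-rejected residual normality are
log-transformed and refitted). Association then uses the EMMAX approximation:
for each trait/treatment, variance components of

> y = X₀b + g + e,  g ~ N(0, σ²_g K),  e ~ N(0, σ²_e I)

are estimated **once** under the null by REML (profiled over
δ = σ²_e/σ²_g via eigendecomposition), with K the identity-by-state kinship
and X₀ an intercept plus principal-component structure covariates (Q). Every
marker is then scored by generalized least squares with V = σ²_g K + σ²_e I
held fixed, an F(1, n−q−1) test on the dosage coefficient, and the effect
reported per copy of the **major** allele.

Downstream:

- **Effective tests** — PLINK-style `indep-pairwise` pruning (100 kbp window,
  step of 10 kept SNPs, r² > 0.8 removal) sets the genome-wide level
  α/m_eff.
- **Regions** — significant markers (P ≤ threshold) plus suggestive markers
  (best 5% of the scan) are collapsed into LDSelect-style greedy bins at
  r² ≥ 0.80; bins holding a significant marker become regions spanning their
  outermost members. Overlapping regions across traits/treatments merge into
  unique regions.
- **Relative effect size** — |2β / (max−min of LS means)| × 100, the percent
  of a trait's observed range covered by the homozygote contrast.
- **Pleiotropy screen** — each region's focal (lowest-P) marker is ranked as
  a percentile among all markers for every other trait in the same treatment
  and the same trait in the other treatment (tiers at the 99th/95th/90th
  percentile), with direction-of-effect agreement.
- **Candidate genes** — all annotated genes intersecting a region plus `b`
  flanking genes each side (default b = 1), so a single marker lists 2b genes
  between genes and 1 + 2b genes inside a gene.

A first-class simulator (`seedgwas.simdata`) generates structured inbred
panels (Balding–Nichols subpopulation divergence, copying-chain LD blocks,
residual heterozygosity and missing calls) and replicated two-treatment
phenotypes with planted QTLs plus truth tables, so every stage is testable
with known answers.

## Worked example

```bash
seedgwas demo --seed 1 --out demo_run
```

simulates a 150-line, 2000-marker panel on three 10-Mb chromosomes with two
planted QTLs (root biomass, both treatments, β = 0.9; taproot length,
water-limited only, β = 1.0), runs every stage, and prints:

```json
{
  "seed": 1,
  "stages": ["genio", "covariance", "phenostats", "mma",
             "multiplicity", "regions", "downstream"],
  "markers_after_filter": 2000,
  "threshold": 3.282994090610637e-05,
  "n_regions": 10
}
```

The threshold is 0.05 / 1523 effective tests (m_eff from pruning 2000
markers). `demo_run/run/effect_sizes.tsv` then shows, e.g.:

```
region_id              trait         treatment      focal_marker   beta_major  trait_range  effect_size_pct
root_biomass.Chr01.1   root_biomass  water-limited  Chr01:7664320  -0.917      7.506        24.4
taproot_length.Chr02.3 taproot_length water-limited Chr02:9993835  -0.951      6.347        30.0
```

i.e. the planted root-biomass QTL is recovered at its true position
(Chr01:7664320) with a major-allele effect of −0.92 trait units covering
24.4% of the observed trait range (the planted truth, recorded in
`demo_run/fixture/truth.tsv`, is 25.8%). `pleiotropy.tsv` shows the focal
marker in the alternate treatment in the top-1% tier with the same effect
direction — the planted cross-treatment consistency.

Library use mirrors the CLI:

```python
from seedgwas import genio, phenostats, mma, multiplicity, regions, downstream

panel = genio.filter_markers(genio.read_vcf("genotypes.vcf"))
K = genio.ibs_kinship(panel)
Q = genio.structure_pca(panel, 4)
tm = phenostats.trait_matrix(raw_phenotypes)          # REML LS means
scan = mma.gwa_scan(tm, panel, K, Q, "root_biomass", "water-limited")
kept = multiplicity.prune_indep_pairwise(panel)
thr = multiplicity.adjusted_threshold(0.05, len(kept), panel.n_markers)
regs = regions.delineate_regions(scan, panel, thr.threshold)
```

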