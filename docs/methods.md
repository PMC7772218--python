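# Methods

`bogdiv` analyses a diversity panel of a recently domesticated, clonally
propagated fruit crop whose accessions fall into four breeding stages:
wild clones (WLD), first-generation native selections (NS),
first-generation hybrid cultivars (CLT1), and advanced third-generation
selections (CLT2). The package quantifies how few cycles of selection
reshaped genome-wide variation — per-subgroup diversity, pairwise
differentiation, locus-level diversity loss along the breeding path,
linkage disequilibrium, ancestry structure — and maps trait variation
with structure-aware mixed models. Every statistic is validated against
a simulator with full ground truth.

## Marker filtering (`genotype_io`)

Genotypes are biallelic SNP dosages (0/1/2 copies of the ALT allele)
with an explicit missing sentinel; missing is never coded 0, and all
downstream statistics use pairwise-complete observations. Filtering
removes markers with > 30% missing calls, then markers with panel-wide
MAF < 0.05 (MAF computed on non-missing calls among markers that
survived the missingness step). The order affects only the attribution
of removals, not the retained set. Duplicate (chrom, pos) records and
non-biallelic VCF records are dropped with logged counts. Thresholds are
the defaults of `filter_markers` and the `bogdiv filter` CLI.

## Diversity (`diversity`)

Per (subgroup, marker): ALT-allele frequency p on non-missing calls,
MAF = min(p, 1−p), and expected heterozygosity He = 2p(1−p) — the
diversity measure that ROD is built on. A marker with no calls in a
subgroup is *undefined* there and excluded from numerator and
denominator of the defined-fraction; because the choice of denominator
is genuinely open, polymorphic fractions are reported against both the
defined-marker count and the full filtered set. Joint-MAF contingency
tables use half-open bins of width 0.05 on [0, 0.5] (final bin closed);
the scalar summary is the diagonal mass — the fraction of markers
falling in identical bins — which is higher for adjacent breeding
stages than for stages separated by a bottleneck.

## F_ST scans (`selection_scan`)

Per-locus differentiation uses the Weir & Cockerham (1984)
two-population moment estimator θ̂ = a / (a + b + c) with
among-population (a), among-individual (b) and within-individual (c)
variance components; heterozygote frequencies enter the components
directly, so no Hardy–Weinberg assumption is made. Loci are undefined
when either subgroup has fewer than two genotyped individuals or when
both groups are fixed for the same allele. Negative estimates are
retained. Nei's G_ST is available as a sensitivity switch
(`estimator="gst"`).

Two genome-wide summaries are emitted: the arithmetic mean of defined
per-locus θ̂ (the headline number) and the ratio-of-sums
Σa / Σ(a+b+c). The distinction matters: averaging per-locus ratios
carries a downward Jensen-type bias of order 10% at moderate
differentiation, whereas the ratio-of-sums combination is consistent
for the parametric divergence; calibration checks against
Balding–Nichols simulations therefore use the ratio-of-sums value.

Significance thresholds come from membership permutations: each of R
iterations (default 1000) reshuffles the pooled labels of the two
subgroups preserving group sizes and recomputes every per-locus θ̂. By
default all defined permuted values across iterations are pooled and
the empirical 95th percentile is the threshold (`null_mode="pooled"`);
a per-iteration-maximum mode gives family-wise control instead. The
pooled null answers "how large can a single-locus estimate get by
labelling noise alone", and its threshold scales inversely with group
size, which is why small-subgroup comparisons have much larger
thresholds than large ones.

## ROD (`selection_scan`)

The breeding path defines four ancestral→derived steps:
step1 WLD→NS, step2 NS→CLT1, step3a CLT1→CLT2, step3b NS→CLT2.
Per locus, ROD = 1 − He_derived / He_ancestral: 1 means total loss of
diversity at a locus still segregating in the ancestor (exactly
equivalent, on integer counts, to derived-fixed & ancestral-polymorphic),
0 means no reduction, negative means the derived group is more diverse
(never clamped). Loci with He_ancestral = 0 are undefined. Counts are
reported in six disjoint categories — the four headline bins
{ROD = 0, 0 < ROD ≤ 0.2, 0.8 ≤ ROD < 1, ROD = 1} plus the mid-range
(0.2, 0.8) and negatives — so that every defined locus is accounted for.

## LD decay (`ld`)

LD between two loci is the squared Pearson correlation of genotype
dosages (unphased composite LD) on pairwise-complete observations,
requiring ≥ 3 complete pairs and polymorphism on the complete subset.
All intra-chromosomal pairs with distance ≤ 500 kb are pooled across
chromosomes into non-overlapping 10-kb bins (per-chromosome curves are
kept as well). The half-decay distance is the upper edge of the first
bin whose mean r² falls to half the first-bin mean; no asymptote is
subtracted. A curve that never reaches half its starting value within
the maximum distance has no resolvable decay scale and reports the
first bin edge as a sentinel — this is the behaviour for unlinked loci,
whose flat curve sits at the finite-sample floor E[r̂²] ≈ 1/n.

## Structure (`structure`)

PCA recodes dosages 0/1/2 to −1/0/+1, mean-imputes missing entries per
marker, centers columns and takes the SVD; explained fractions are
λ_c / Σλ. Ward clustering (minimum-variance agglomeration, scipy
linkage) runs on the same coded matrix and exports newick.

Ancestry is a Structure-like factorization of the individual
allele-frequency matrix X = dosage/2 into Q (n×K, rows on the simplex)
and F (K×L frequencies) by alternating nonnegative least squares. Each
sweep EM-fills unobserved entries (missing or held out) with the
current prediction QF, solves the batched NNLS for F (clipped to
[0, 1]) and for Q (rows renormalized to sum 1). Missing genotypes never
enter any loss. Model choice holds out a random 5% of observed entries
per replicate and scores them with the binomial cross-entropy
CE = −(1/2|M|) Σ [g log f̂ + (2−g) log(1−f̂)], f̂ clipped to
[1e-6, 1−1e-6]; five replicates per K by default, best replicate =
lowest held-out CE, K* = argmin of mean CE with ties going to the
smallest K. Because the squared-error ANLS steps with row
renormalization do not monotonically decrease the cross-entropy, the
fit records the full training-CE path and the package guarantees (and
tests) improvement over the run rather than per-iteration monotonicity.
Ancestry labels are identifiable only up to permutation; all
comparisons use best-permutation alignment (`align_q`).

## GBLUP (`phenotype_blup`)

Plot-level records (accession, trait, value, year, row, col) are fit
per trait with

y = Xτ + Z_g u_g + Z_y u_y + Z_s u_s + e,

u_g ~ N(0, σ²_g K) the accession genetic values with K the VanRaden
relationship matrix, u_y iid year effects, u_s the penalized part of a
tensor-product B-spline surface over the field grid (8×8 cubic basis,
second-order difference penalty on each axis). The spline enters in its
mixed-model reparameterization: the penalty is eigendecomposed, the
penalized directions are rescaled to iid random effects, and the
penalty null space — the bilinear trend, which cannot carry a
finite-variance prior — forms the fixed effects. Variance components
come from EM-REML (the classical update
σ² ← σ² + σ⁴ (y'PH Py − tr(PH))/q), which never decreases the
restricted likelihood; the likelihood path is recorded and tested for
monotonicity. BLUPs are û_g = σ̂²_g K Z'_g P y. Degenerate designs
(single year, constant coordinates) drop the corresponding component.
Subgroup comparisons use one-way ANOVA plus Tukey HSD on accession
values, with p-values floored at the smallest positive double rather
than reported as literal zero. Trait correlations are signed Pearson r
with tests on pairwise-complete observations.

## GWAS (`gwas`)

Kinship: A = W W′ / (2 Σ p_j(1−p_j)), W the mean-imputed, 2p-centered
dosage matrix with in-sample frequencies. Scans follow EMMAX/P3D: K is
eigendecomposed once on the analysis subset, δ = σ²_e/σ²_g is
REML-estimated under the covariates-only null model, and each marker is
tested by generalized least squares with a Wald t-test in the whitened
space. Variance components are not refit per marker; at these sample
sizes the approximation is standard and keeps the scan O(nL).
Covariates are PC1–10 plus K−1 columns of the ancestry Q matrix (one
dropped to avoid the sum-to-one collinearity). Markers collinear with
the covariates are flagged and not tested, as are markers below 5% MAF
within a per-subgroup subset. Discoveries use Benjamini–Hochberg FDR at
0.1 with monotone q-values.

Because the breeding stages are strongly stratified for yield-type
traits, `stratification_audit` breaks any association down by
(subgroup × genotype class) and flags it as confounded when no subgroup
shows a nominally significant within-subgroup effect — the situation
where an association is carried entirely by between-stage differences
that the covariates failed to absorb.

## Simulator (`synthetic_data`)

The generator reproduces the statistical structure the analyses assume,
not any specific demographic history:

- **Wild stage.** Accessions sample from 4 demes whose allele
  frequencies follow the Balding–Nichols distribution around an
  ancestral frequency (Beta(0.4, 0.4) clipped to [0.02, 0.98], giving
  the observed excess of rare alleles) at divergence F = 0.05.
- **LD.** Haplotypes are first-order Markov chains along each
  chromosome: adjacent alleles have Pearson correlation exp(−gap/d₀)
  with d₀ = 30 kb, so any two intra-chromosomal loci correlate as
  exp(−distance/d₀) — a closed-form decay target. Marker maps use 12
  chromosomes with exponential gaps of mean 22 kb. This Markov
  construction gives desk-scale speed and exact calibration targets at
  the price of not modelling coalescent variance in LD.
- **Breeding.** NS = truncation selection of wild candidates (3× pool)
  on a two-trait index observed with accuracy² = 0.5; CLT1 = two
  generations of crosses from the top 7 NS founders with Poisson(1)
  crossovers per chromosome per meiosis; CLT2 = crosses of CLT1×CLT1
  and CLT1×(8th-grandparent × founder) offspring, constraining ancestry
  to 8 grandparents; each crossing stage selects the top fraction of a
  3× candidate pool. Clonal duplication of top selections is available
  but off by default.
- **Phenotypes.** Per trait: true breeding value (100 causal loci plus
  any configured major QTL) + year effect + a smooth spatial field
  (Gaussian-filtered noise on the trial grid, σ = 2 cells) + residual,
  with variance shares set so plot-level heritabilities are 0.3–0.5 per
  trait, year 15% and spatial 10% of total. Defaults use the panel's
  subgroup sizes (121/111/26/104) and seven trial years.
- **Missingness.** Completely at random at 15% (configurable within
  0–30%).

All randomness derives from one master seed via `numpy.SeedSequence`
spawning, one child stream per simulation stage in a fixed order; the
same seed reproduces every emitted file byte-for-byte. Ground truth
(ancestral and per-stage frequencies, founder identities, QTL effects,
breeding values, the spatial field) is returned alongside the data.

What the simulator does *not* emulate: real linkage maps and
recombination hotspots, non-random missingness of reduced-representation
sequencing, genotyping error, selfing/inbreeding depression dynamics,
and historical population-size changes. Passing recovery tests
therefore demonstrates correctness of the estimators under their
stated models, not robustness to those real-data artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical checks have adequate power:
L = 200–2400 markers, panels of 40–362 accessions, 200 permutations,
5 seeds for across-seed properties, 50 seeds for GWAS power.
Numerical conventions: missing sentinel −1; cross-entropy clipping
ε = 1e-6; kinship ridged by 1e-6 before REML; variance components
floored at 1e-10; EM-REML stops at relative log-likelihood change
1e-7 (≤ 200 iterations); ancestry ANLS stops at relative training-CE
change 1e-5 (≤ 100 iterations); K-selection ties break to the smallest
K; Ward ties to the lowest index pair; collinearity threshold for
tested markers is residual variance ≤ 1e-8 of the whitened marker
variance.

## Known limitations

- The ancestry factorization is a least-squares analogue of
  sparse-NMF ancestry methods; it shares their criterion (held-out
  cross-entropy) but not their exact regularization, so Q matrices are
  comparable only up to column permutation and mild shrinkage
  differences.
- The permutation null pools loci; under strong LD the effective
  number of independent loci is smaller than L and the pooled
  percentile is slightly anti-conservative per locus (family-wise mode
  available).
- EM-REML converges slowly near variance-component boundaries; the
  iteration cap can stop short of the optimum, which matters for
  variance-component interpretation but little for BLUP ranking.
- GWAS assumes a single variance-component background; interactions
  between stage stratification and trait architecture are only
  diagnosed (via the audit), not modelled.
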