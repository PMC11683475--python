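# Methods

This note documents the models, estimators and design choices behind the
package, and what the synthetic scenario does and does not demonstrate.

## Chromatin-state model

Mark tracks are summarized as counts in fixed 200-bp bins. Binarization is
Poisson-background thresholding: with λ̂ the genome-wide mean bin count of a
track, a bin is "on" iff P(X ≥ c | Poisson(λ̂)) < 10⁻⁴. Both the bin size
and the tail probability are the documented defaults of the standard
segmentation tool for this data type; an all-zero track degenerates to
all-off with a warning.

The segmentation model is a K-state HMM (default K = 6) whose emissions are
per-mark independent Bernoullis, so a state is a probability vector over
(ATAC, H3K4me3, H3K27ac). One model is trained on the concatenation of all
tissues' binarized sequences — each chromosome of each tissue is an
independent sequence — and decoded per tissue, so state definitions are
shared across tissues. Training is Baum–Welch with scaled forward–backward
(per-position normalization constants; the forward likelihood is verified
against exhaustive path enumeration in the tests), best of `n_restarts`
seeded random initializations, stopping when the log-likelihood gain drops
below 10⁻⁴ or after 500 sweeps. The log-likelihood is asserted
non-decreasing every sweep. Decoding is per-bin posterior maximum by
default (Viterbi behind a flag): posterior decoding matches the reference
tool's behavior and is what the recovery guarantees are stated for.

State labels are rule-based on the emission rows: H3K4me3 ≥ 0.5 with
H3K27ac ≥ 0.5 → TssA, H3K4me3 ≥ 0.5 alone → TssW, ATAC ≥ 0.5 with
H3K27ac ≥ 0.5 → EnhA, H3K27ac in [0.2, 0.5) → EnhAW, ATAC ≥ 0.5 alone →
ATAC_Is, else Quies. The 0.5/0.2 cut-offs are this package's convention
(labels are usually assigned by inspection); duplicate labels in a 6-state
model are resolved by a Hungarian assignment to label prototypes, with a
warning. Six states were chosen because they capture the informative
combinations of three marks; model selection over K is out of scope.

Tissue specificity of states: per-state intervals are merged across tissues
into non-redundant elements (bedtools-merge semantics: overlapping or
book-ended intervals collapse); an element is present in a tissue on ≥ 1 bp
of overlap, specific when present in exactly one tissue, common when in
all. The variability curve f(k) is the cumulative bp fraction of elements
present in ≤ k tissues, summarized as the smallest k with f(k) ≥ 0.75.
This cumulative-fraction reading is one defensible definition of state
variability; others exist.

## Expression specificity

TPM is the usual length-normalized rate scaled to 10⁶ per sample. The tau
index is computed on raw TPM with no log transform or expression floor —
the minimal published form of the index. Low-expressed genes therefore have
noisy tau; callers filtering by expression should do so upstream.
Specificity is strict: τ > 0.8, never ≥. Gene–enhancer grouping counts
enhancers overlapping the gene body (TSS–TES) by ≥ 1 bp; a promoter-window
alternative is available via the gene models. Group boundaries
(1 / 2–5 / ≥ 6) are configurable.

## Selection statistics

All scans share a sliding-window grid of full 150-kb windows stepped by
75 kb (windows that would overhang the chromosome end are dropped).

* **FST** is the Weir–Cockerham two-population variance-component
  estimator; windows aggregate as ratio of sums Σa / Σ(a+b+c) (the
  "weighted" estimator of the standard VCF tool), with mean-of-ratios
  behind a flag. Sites monomorphic across both samples or with fewer than
  two genotyped individuals in either population carry no information and
  are excluded; negative window values are reported as-is.
* **π** uses per-site unbiased heterozygosity 2j(n−j)/(n(n−1)) over
  non-missing allele counts, divided by the full window length (the
  windowed-π convention of the same tool), so uncalled and monomorphic
  positions dilute rather than truncate. The π ratio's orientation is
  explicit in the API; the end-to-end pipeline uses non-selected/selected
  so that diversity loss in the selected population raises the statistic.
* **XP-EHH** computes whole-sample EHH decay around each core SNP:
  EHH(x) = Σ_h C(c_h, 2)/C(n, 2) over distinct extended haplotypes, iHH is
  the trapezoidal integral over genetic distance truncated at the first
  crossing below 0.05 on each side, the raw score is ln(iHH_A/iHH_B), and
  scores are z-standardized genome-wide (no frequency binning) before
  window averaging. Genetic positions default to a uniform 1 cM/Mb map in
  the simulator. Scores are missing where either integral is zero.

Candidate sweep regions are windows at or above the (1−q) quantile of every
statistic (ties included), merged when overlapping or adjacent. The default
q = 0.005 (top 5‰); the looser top-5% variant is one argument away.

## Mixed-model GWAS

Site QC follows the standard VCF-tool semantics: per-genotype DP masking at
read time (minDP 5 by default in the CLI), then biallelic-SNP, call-rate
≥ 0.8 and MAF ≥ 0.05 filters with a per-rule removal report. Kinship is the
VanRaden GRM ZZᵀ/(2Σp(1−p)) on mean-imputed dosages. Population structure
covariates are the top 3 PCs of the LD-pruned (50-SNP window, step 5,
r² > 0.2), centered-scaled genotype matrix. Factor covariates are one-hot
coded against their first level; the design matrix is checked for rank and
collinear columns are named in the error.

Variance components come from REML on the null (no-SNP) model after one
eigendecomposition of K, profiling σ²_g and optimizing δ = σ²_e/σ²_g by a
grid-bracketed bounded scalar search on log δ ∈ [log 10⁻⁵, log 10⁵].
When K has no eigenvalue spread (identity-like), the split is
unidentifiable: the fit warns and returns the boundary, where the scan
reduces exactly to ordinary least squares (verified against OLS to 10⁻⁸ in
the tests). Per-SNP tests fix the components (P3D/EMMAX), whiten by
V^{-1/2}, project out the covariates once, and use a t test with n−p−1
degrees of freedom and a per-SNP residual variance — the per-SNP rescaling
keeps the null calibrated (genomic-control λ within [0.9, 1.1] and
KS-uniform p-values on two-population nulls at n = 500, M = 5000).
Monomorphic SNPs yield missing results with a warning. The reported
h² = σ²_g/(σ²_g+σ²_e) is a pseudo-heritability: when a large-effect variant
is itself represented in the GRM (as in the default scenario's LD block) it
absorbs that variance and can sit far above the simulated polygenic value,
occasionally at the boundary.

## Enrichment

Fold enrichment is base-pair based: (overlap/state_bp)/(feature_bp/genome_bp),
1 = random expectation, missing when either set is empty. The permutation
null circularly shifts the feature set per chromosome by one uniform
offset, preserving interval sizes and spacing (uniform re-placement would
destroy clustering); p = (1 + #{perm ≥ obs})/(n_perm + 1) is never zero.
Whether published folds of this kind use bp or element counts is often
ambiguous; bp matches the reference tool's default.

## Prioritization funnel

Stages are pure interval algebra on half-open coordinates: a SNP's 1-based
position converts to a 0-based point, and a point equal to an interval end
is outside. Peak membership means membership in the union of replicate peak
sets ("peak of at least one replicate/individual"); open chromatin AND
H3K27ac are both required. TAD annotation links a candidate to every gene
whose TSS (not body) lies in the same TAD; SNPs in no TAD are retained
without linked genes. The expression stage is one-way ANOVA of
per-individual expression across dosage classes (Kruskal–Wallis behind a
flag), dropping classes with < 3 individuals and returning missing with
fewer than two usable classes. Ranking is by minimum linked-gene expression
p ascending (candidates with no tested gene last), then GWAS −log₁₀p
descending, then coordinate — fully deterministic.

## Synthetic scenario

The generator's defaults are the package's study conditions, chosen once:
one 3-Mb chromosome, 5 000 SNPs, two populations of 250 (a "fat-tail" and a
"thin-tail" analog), Balding–Nichols differentiation F = 0.02 with
F_sweep = 0.5 inside one window-aligned 150-kb sweep, a causal enhancer
variant at 0.8/0.2 alt frequency, β = 1 phenotypic SD per allele,
polygenic h² = 0.4, covariates (birthplace, 7 batches, season) with fixed
effects, nine tissues with a planted 6-state architecture
(λ_bg = 1, λ_weak = 4, λ_fg = 10 Poisson rates), TADs of 400 kb, planted
tissue-specific genes at 20-fold contrast, and a target gene whose
per-individual expression shifts by 1 noise-SD per causal allele. Within
the sweep, one core haplotype is copied into 60 % of the selected
population's haplotypes — frequency models alone carry no
haplotype-homozygosity signal, and this is what gives XP-EHH power.
Because the frequency model has no recombination-based LD, GWAS-significant
decoy variants are planted explicitly as near-copies of the causal column
(2 % genotype flips) at ≥ 2 kb from every chromatin element, emulating the
strong-LD block around a real causal variant; one "bystander" near-copy
(10 % flips) sits inside the causal enhancer, so the funnel's last stage
genuinely has to discriminate by expression.

What passing tests show: the estimators agree with brute-force oracles; the
segmentation recovers a known architecture; the mixed model is calibrated
under two-population structure; and the funnel reliably isolates a planted
enhancer variant from LD decoys under these conditions. What they do not
show: robustness to realistic LD and demography, uneven marker density,
assay-specific read-level artifacts, phasing errors (haplotypes are known
exactly here), or peak-calling noise — peaks here are the planted truth.

## Problem sizes and numerical notes

Default analysis sizes (n = 500, M = 5 000, 15 000 bins/tissue, 39 windows,
20-seed recovery sweeps, HMM recovery at 10⁵ bins with 5 restarts) were
chosen so the full test suite and the acceptance script each run in minutes
on a single CPU while leaving every statistic comfortably estimable.
Emissions are clipped to [10⁻¹⁰, 1−10⁻¹⁰] inside the HMM to keep
log-likelihoods finite; the forward–backward recursions use per-position
scaling; kinship Cholesky adds a 10⁻⁶ jitter; quantile thresholds include
ties by using ≥. Known limitations: no multi-chromosome genetic map beyond
uniform cM/Mb, no dominance or epistasis in the phenotype model, no
frequency-binned XP-EHH standardization, and TAD calling itself is consumed
as input, never inferred.
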