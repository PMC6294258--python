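# Methods

## The model

The pipeline quantifies transcriptional metabolic dysregulation per
(cohort, pathway) cell from a genes × samples expression matrix of
non-negative RSEM-style values and a tumor/normal sample sheet.

**Differential expression.** Genes with zeros in strictly more than 80%
of a cohort's samples are removed first (the boundary is inclusive: a
gene zero in exactly 80% is kept). Values move to log2(x+1); the +1
guards zeros and the log brings count data close enough to Gaussian for
linear-model testing. Each sample column is then rescaled multiplicatively
about its median so its median absolute deviation (MAD) matches the
geometric mean of all columns' MADs — a scale normalization that equalizes
spread without touching location. Testing uses a moderated two-sample
*t*: gene-wise pooled variances s²_g on d = n_t + n_n − 2 degrees of
freedom are shrunk toward a prior (d₀, s₀²) estimated by method of
moments on log s²_g, using the digamma/trigamma closed forms for
log-scaled-χ² moments; the posterior variance is
s̃² = (d₀s₀² + d s²)/(d₀ + d) and the statistic has d₀ + d degrees of
freedom. When the empirical spread of log s² is no larger than its
sampling component the prior df is infinite and all genes share s̃² = s₀²
(with Gaussian reference distribution). `prior_df=0` recovers the
ordinary pooled *t* exactly — a tested classical limit. The design is a
plain two-group comparison: no pairing, covariates, trend or robust
options. BH step-up adjustment (via statsmodels) controls FDR; adjusted
p-values are floored at 1e−300 before any downstream log.

**Scores.** Gene score = |log2FC × −log10(adj p)| (the log base is
configurable; 10 is the volcano-plot convention, and since adj p ≤ 1 the
placement of the absolute value is immaterial). Pathway score = sum of
member-gene scores / √n, with n the total number of samples (tumor +
normal) entering that cohort's comparison — the most direct reading of
"sample size", recomputed for every comparison actually run, including
subtype partitions. Pathway genes absent from the cohort's DEG table are
dropped (intersection scoring): absent genes carry no evidence either
way. Pathways with fewer than `min_genes` (default 2) scored members get
NA rather than masquerading as evidence.

**Bootstrap null.** The resampling pool is the cohort's complete
gene-score vector — every gene that survived the expression filter. For a
pathway using k genes, each of B null scores (default B = 100,000) sums k
pool draws with replacement and divides by √n. The empirical p-value is
(1 + #{null ≥ observed})/(B + 1): one-sided upper tail (scores are
non-negative magnitudes), +1-corrected so p is never 0, ties counted into
the tail. k is the pathway's *scored* gene count, not its nominal size,
because the observed score summed exactly those genes. Significant means
boot p < α strictly (default α = 0.05); all other scores are replaced by
0 in the masked table. No multiple-testing correction is applied across
pathways by default — each pathway is tested against α on its own — and
each (cohort, pathway) cell gets an independent substream derived by
hashing the cell labels with SHA-256 into a seed sequence, so adding a
pathway never perturbs another's null.

**Direction and clustering.** A member gene counts as up (down) when
adj p < 0.05 and log2FC is positive (negative); the gene-level cutoff is
exposed as `--gene-alpha` since no canonical value is forced by the
method. Signed fold-change matrices keep log2FC where significant and NA
where tested-but-not-significant. Min–max scaling maps a vector through
(m − min)/(max − min); constant vectors map to 0 with a warning rather
than erroring, so whole-matrix row scaling never aborts. Heatmap orders
use Euclidean distance with complete linkage (the classical default of
the `hclust` family); NA cells are imputed as 0 for distances, mirroring
the zero-replacement of non-significant scores, and rows are pre-sorted
lexicographically so leaf orders are deterministic and invariant to input
permutation. Whether to cluster raw, min–max scaled or masked scores is
left to the caller — all three matrices are available.

**MMTR association.** Correlations are Pearson on log2(x+1) values
(Spearman available as a robustness option), regulator excluded from its
own profile, zero-variance genes NA with a warning. The pathway-restricted
correlations are compared against the genome-wide background with a
two-sample two-sided Kolmogorov–Smirnov test; pathway genes are removed
from the background first so the two samples do not overlap — the
conservative choice where the alternative (keeping them) would dilute the
test toward the null.

## Synthetic cohorts

The generator emulates RSEM-like overdispersed counts: per-gene baseline
means μ_g ~ LogNormal(5, 1) (median ≈ 150 counts), normal samples ~
NegBin(μ_g, dispersion 0.2), tumor samples ~ NegBin(μ_g·2^lfc_g, same
dispersion), with defaults of 2,000 genes, 20 + 20 samples, and 50
pathways of 20 genes partitioning the first 1,000 genes (background genes
belong to no pathway). A dropout mechanism silences 5% of genes in a
random sample subset (each sample zeroed with probability 0.85), so
silenced genes' zero fractions straddle the 80% filter boundary and both
sides of that rule are exercised. Planted truths assign a fixed log2 fold
change to round(fraction × size) uniformly chosen members of each planted
pathway; conflicting assignments from overlapping pathways are an error.
All stages draw from fixed-offset substreams of one seed, so cohorts are
bit-reproducible and each stage independently so.

What the generator does **not** emulate: batch effects, tumor purity,
paired-sample correlation, gene–gene co-expression within pathways (genes
are independent given the truth), library-size variation, or
mean-dependent dispersion. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under a clean
overdispersed-count model, not that real cohorts satisfy its assumptions.

The regulator-driver generator is separate and works directly on the
log2 scale: a latent factor z ~ N(0,1) per sample, the regulator tracking
z exactly, each of 15 pathway genes gaining `driver_strength`·z (default
1.0) over N(0, 0.5) gene noise, everything else independent — a minimal
co-expression module for exercising the KS shift test.

## Study conditions for the built-in checks

The calibration check uses complete-null cohorts at the default
configuration and pools 200 (cohort, pathway) cells from four independent
cohorts, since a 50-cell fraction is dominated by binomial noise; at
α = 0.05 the flagged fraction stays within [0.02, 0.09]. The recovery
check plants five pathways at log2FC = 2 on half their genes and asks for
perfect recovery at the top of the ranking with ≤ 10% false positives.
The robustness check draws two independent cohorts from one truth in
which half the pathways (25/50) carry graded effects, |log2FC| ranging
0.5–2.5 with alternating sign on half their genes — mirroring the
observation that roughly half of metabolic pathways are dysregulated in a
typical cancer cohort — and requires Spearman ≥ 0.8 between the two
pathway-score vectors. Bootstrap resample counts in tests are reduced
(2,000–10,000) where the quantity being checked does not need the
100,000-resample floor.

## Numerical choices

- Adjusted p-values floored at 1e−300; gene scores are finite always.
- Tables serialize floats with `%.17g` and NA as the literal token `NA`,
  and readers parse with round-trip float precision, so write→read→write
  is byte-identical.
- Zero-MAD (constant) sample columns are left unscaled with a warning;
  zero-variance genes get t = 0 and p = 1 when the fold change is 0.
- The trigamma inverse in the prior fit uses Newton iteration to 1e−10
  relative tolerance.
- Empirical p-values live in [1/(B+1), 1] by construction.

## Known limitations

- The moderated test assumes approximate log-scale normality;
  heavy-tailed real data may miscalibrate it where the synthetic model
  does not.
- The gene-score resampling null treats genes as exchangeable and
  independent; co-expressed gene sets in real data violate this, making
  the bootstrap anti-conservative for tightly correlated pathways.
- The KS p-value for the MMTR shift assumes independent samples; the
  correlations in a profile share the regulator's sampling noise and are
  weakly dependent, which simulation shows is negligible at the tested
  sizes but is not guaranteed in general.
- Identifier handling is case-sensitive with no alias resolution;
  mismatches surface as warnings in scoring, not silent fixes.
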