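# Methods

This note documents the statistical model behind `ervcoex`, the
conventions chosen where several are defensible, what the synthetic
generator does and does not emulate, and the package's known limits.

## Normalization

Size factors are raw median-of-ratios: for sample *j*,
`s_j = median_i( c_ij / g_i )` with `g_i` the geometric mean of gene
*i* across samples, taken over the reference set of genes with a
strictly positive count in every sample (a zero anywhere removes the
gene from the reference set, since its log is undefined). The median
of an even-length ratio vector is the midpoint of the two central
order statistics. Factors are **not** rescaled to unit geometric
mean. Consequence worth stating precisely: multiplying one sample's
counts by *c* multiplies its factor *relative to the others* by *c*
and the whole normalized matrix by the global constant `c^(1/n)`;
relative expression — everything the downstream correlations use — is
invariant, absolute normalized values are defined only up to that
global scale. If no gene is positive in every sample the operation
fails with a message advising prefiltering rather than silently
shrinking the reference set.

## Filtering

Two prefilters run on the normalized matrix, in order, with a shared
gene universe for both groups (means are pooled over all samples):
mean normalized count ≥ 50 (boundary inclusive: a published
post-filter quantile table whose minimum equals the threshold exactly
implies the boundary is kept), then membership in at least one
annotation gene set. The analysis target is exempt from both via a
keep-list — proviral features are often below any sensible expression
cut, and deleting the screen's own target is never intended. The
filter report carries both intermediate gene counts and five-number
summaries (linear-interpolation quantiles of per-gene means) because
the two filters are conflated in typical published summaries and the
intermediate counts make the reduction auditable.

## Correlation screen

Pearson product-moment correlation of each gene with the target,
within one group's samples only. Significance uses the exact
small-sample transform `t = r√(n−2)/√(1−r²)` against Student's t with
n−2 df, two-sided. With n = 7 per group this test leans on
near-normality of expression values; the package provides a normal
Q-Q diagnostic (order statistics of the standardized sample against
normal quantiles at plotting positions `(i−0.5)/n`) but deliberately
never gates the pipeline on it — normality is reported, not enforced.
Zero-variance genes get an undefined correlation (NaN) and are
excluded from ranking rather than assigned r = 0: an undefined
statistic must not occupy a rank. Screen p-values are not
multiplicity-adjusted; multiplicity is handled downstream at the
gene-set level, where inference actually happens. "Strong"
co-expression means |r| ≥ 0.7 by default, counting both signs; a
signed mode (r ≥ threshold) is exposed for sensitivity analyses.

## Preranked GSEA

Genes are ranked by signed r, descending, ties broken lexicographically
by gene id for bit-reproducibility. For a set with members M, walking
the ranked list adds `|score_i|^w / N_R` at members
(`N_R = Σ_{M} |score|^w`, weight `w = 1` by default — the classic
weighted statistic) and subtracts `1/(N − |M|)` elsewhere; the ES is
the running sum's maximal absolute deviation from zero, with an exact
positive/negative tie resolving positive. The leading edge is the
member prefix up to the peak (suffix from the trough for negative ES)
and `gene_ratio = |leading edge| / set size`.

**Null model.** The null is gene-label permutation: a set of size s is
compared with uniformly random size-s subsets of the ranked list. With
seven samples per group a phenotype permutation null cannot support
large permutation counts (7! = 5040 distinct relabelings), so the
gene-permutation null of preranked GSEA is the only consistent choice.
Implementation detail: null placements are generated by permuting the
gene labels of the whole list and reading off each set's member
positions, in memory-bounded chunks; under one permutation each set's
positions are exactly a uniform random subset, so the marginal null per
set is the stated one, and sharing permutations across sets (as
reference implementations do) only affects cross-set dependence, not
p-values.

**P-value conventions.** Two one-sided, add-one-smoothed conventions
are computed. The default, `pvalue`, refers the observed ES to the
*same-sign portion* of the null — the convention of the original GSEA
methodology — and is calibrated: under a fully null study it is
uniform, so ~5% of sets fall below 0.05. The second, `pvalue_pooled`,
divides the same exceedance count by the total permutation count; it
is the signed null's tail mass, roughly half the calibrated value, and
is reported because some tools print it. All downstream adjustment,
sorting and significance use the calibrated `pvalue`. NES divides ES
by the mean same-sign null ES (NaN, flagged, if that sign never
occurred). Defaults follow common GO-BP practice: restricted set size
in [25, 500] (bounds applied *after* restriction to the analyzed
universe), 100,000 permutations, significance at BH-adjusted p < 0.05.

**Multiplicity.** BH step-up adjustment across the tested sets, plus a
q-value `q_i = π̂₀ · BH_i` with the fixed-λ = 0.5 estimator
`π̂₀ = #{p > 0.5}/(0.5·m)` clamped to `[1/m, 1]`. The λ-grid spline
smoother of the full q-value estimator is intentionally out of scope;
the fixed-λ version is transparent and sufficient at the tested set
counts.

## Category over-representation ("meta" test)

Whether a designated category of terms is over-represented among the
top-k most significant GSEA terms: x = |top-k ∩ category| referred to
the exact hypergeometric distribution (scipy's log-space survival
function; no normal approximation). Both tail conventions are
first-class because upper-tail software defaults differ by one:
`p_inclusive = P(X ≥ x)` is the standard statistical report and the
default; `p_strict = P(X > x)` is labelled explicitly. Their
difference equals the point mass P(X = x) exactly, which the tests
assert. The universe size N is always an explicit caller input — using
the full term vocabulary (e.g. 29,698 GO BP terms) versus only the
tested sets changes the p-value by orders of magnitude, so the choice
must be visible in the call.

## Synthetic studies

`generate_study` emulates the target study design: two groups
("old"/"young") of 7 samples, 2,000 genes, 50 gene sets of 30–60
members, 2 planted sets. Counts are gamma-Poisson (negative binomial,
variance `μ + φμ²`, dispersion φ = 0.1 by default) around per-gene
baselines with log-means uniform on [4.2, 8.0] (means ≈ 67–3,000, so
the default expression filter retains most genes and set-size bounds
stay meaningful). The target feature is NB with mean 40 in the
reference group and 1.3× that in the other group. Co-expression is
planted through a shared latent: within the planted group, member
genes of planted sets have log-mean `base + β·z`, where z is the
standardized *realized* target value of each sample, so the induced
gene–target Pearson structure is exactly what the screen assumes;
β = 0 reduces to a fully null study. Planted sets draw disjoint member
pools; filler sets draw only non-planted genes, keeping ground truth
unambiguous. All randomness derives from one seed through numpy
`SeedSequence` spawning (target / baselines / set structure / counts
as separate streams).

The published study reports the provirus at sub-1 TPM medians
(0.357/0.478). On an integer-count scale a feature with mean below one
count is almost all zeros and can carry no correlation signal, so the
generator does not place the target at that absolute level; it keeps
the 1.3-fold group ratio — the property the analysis actually uses —
at a count level (mean ≈ 40) where the within-group variation that
drives the screen exists. Tests assert the fold ratio, never the
absolute medians.

What the generator does **not** emulate: realistic transcriptome-wide
correlation structure (non-planted genes are independent),
batch/library-size confounding beyond size factors, gene length or GC
effects, and annotation incompleteness. Passing recovery tests
therefore show the statistics behave as designed under the assumed
model, not that the pipeline is robust to those real-data phenomena.

## Numerical conventions and degenerate inputs

- Correlations are clipped to [−1, 1] against rounding; |r| = 1 maps
  to p = 0 exactly.
- Ranking ties: lexicographic by gene id, stable sorts throughout.
- ES ties (max deviation equal in both signs): positive wins, in both
  the scalar and the vectorized batch path (the two are tested to
  agree on exhaustive enumerations).
- Sets hitting none or all of the ranked list are hard errors (the
  decrement denominator degenerates).
- Empty filter results warn and return empty rather than raising;
  empty GSEA (no set within size bounds) returns an empty table with a
  warning.
- Result tables are written at six significant digits, rows ordered by
  ascending p then term id, which defines the round-trip contract.

## Problem sizes used in the test suite

End-to-end statistical tests run the generator defaults (2,000 genes,
2 × 7 samples, 50 sets) with 10,000 permutations and 20 replicate
seeds for the calibration and recovery checks, and 500–1,000
permutations for smoke-level checks. These sizes give the calibration
assertions comfortable binomial tolerance (e.g. ±3 percentage points
on a 5% rate over ~1,000 set-level tests) while keeping the whole
suite fast.

## Known limitations

- The screen's t-based p-values are exact only under bivariate
  normality; at n = 7 they are indicative, which is why inference is
  carried at the gene-set level.
- The fixed-λ q-value is coarser than the smoothed estimator for small
  m.
- Phenotype-permutation GSEA, partial correlations and cell-type
  deconvolution are out of scope.
- The pipeline starts from a count matrix containing the target as a
  feature row; alignment, quantification and annotation retrieval are
  upstream concerns.
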