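# Methods

`evintegra` re-implements, as a tested library, the computational arc of a
multiomic EV study: bulk EV proteomes are preprocessed and tested for
differential expression; cell-type signatures derived from labelled
single-cell data are used to deconvolve the cell-of-origin composition of EV
cargo; gene-set enrichment links miRNA target modules and receptor modules
to cell types; and qPCR/OpenArray Ct panels are filtered, normalized and fed
into the same moderated statistics, ending in a rule-based classifier that
decides whether a glial miRNA was produced in place or imported (e.g. as EV
cargo). Every stage is exercised against a synthetic-data generator with
known ground truth.

## Synthetic data

The generator produces the processed matrices the pipeline consumes, never
raw spectra or reads.

- **Signatures.** Genes share a log-normal baseline (Gaussian on the log2
  scale, mean 5, sd 1.5 — arbitrary but configurable); each cell type gets a
  disjoint block of `n_markers_per_type` genes elevated by `marker_log2fc`
  (default 3, i.e. 8-fold). Disjointness is by construction, so marker
  recovery can be scored exactly.
- **EV mixtures.** A sample is a convex combination of the signatures on the
  linear scale: `log2(sum_k p_k 2^sig_k)`, plus a per-feature group effect
  for spiked features and Gaussian log2 noise. Missingness is MNAR: dropout
  probability is logistic and decreasing in the noiseless log2 intensity,
  with midpoint at the matrix's lower quartile (width 1 log2 unit) and the
  curve *amplitude* tuned so the expected global missing rate equals
  `dropout_rate`. Amplitude rather than width is tuned because a pure width
  change cannot reach low global rates once the midpoint is fixed at the
  25th percentile.
- **Single-cell counts.** Negative-binomial (gamma–Poisson) counts with mean
  proportional to the signature column rescaled to a fixed library size;
  dispersion 0 falls back to Poisson.
- **Ct panels.** Gaussian Ct values around per-miRNA baselines
  (uniform 22–32, well sd 0.25), a per-sample loading offset (sd 0.5 Ct, the
  quantity normalization must remove), case-group shifts of `de_delta_ct`
  for planted miRNAs, and a stated fraction of wells flagged unreliable by a
  failing amplification score or a Ct above the ceiling. A stable reference
  assay (`U6`) is appended for comparative-Ct use.
- **Ligand–receptor tables.** A bipartite toy table whose distinct-receptor
  count is controlled by `shared_receptor_fraction`; with per-ligand slot
  counts (7,7,7,7,6,6) and sharing 0.2 it reproduces the 6-ligand /
  32-receptor / 40-interaction topology used as a fixture.

Every generator takes an explicit seed and owns a single RNG stream, so all
fixtures are bit-reproducible.

**What the generator does not emulate:** peptide-level effects and protein
rollup, batch structure, correlated noise across samples, realistic
signature collinearity between related cell types (planted markers are
disjoint and equally strong), library-size and cell-quality variation in the
single-cell counts, and probe-specific amplification chemistry. Passing
tests therefore demonstrate the correctness of the algorithms under the
stated models, not their field performance on real data.

## Proteomics preprocessing

Order is fixed and enforced through provenance flags: log2 → missingness
filter → imputation → variance stabilization.

- **Missingness filter.** A protein is kept only if it has at most
  `max_missing_per_group` (default 2) missing values in *every* group.
- **Imputation (MinProb-style).** Missing label-free intensities are
  left-censored, so each is replaced by an independent draw from
  Gaussian(mu, sigma) with mu = the minimum of all observed log2 intensities
  (the 0.0-th quantile, read literally) and sigma = the median of per-feature
  standard deviations among features observed in more than half of the
  samples. Draws are not truncated; values below mu are possible. If no
  feature is observed in >50% of samples, sigma is undefined and the
  operation raises.
- **Variance stabilization.** The algorithm behind the named transformation
  is not pinned by the upstream description, so this package's choice is:
  (1) a per-sample affine calibration (median-centering, MAD-scaling to the
  pooled reference) and (2) if the lowess-estimated SD-vs-mean trend still
  has |slope| ≥ 0.05, a monotone transform h(x) = ∫ du / sd_hat(u) evaluated
  along the trend, applied identically to every sample (so within-sample
  ranks are preserved), iterated up to three times. Constant samples are an
  error. The transform is exposed as its own function so an alternative
  strategy can be substituted.

## Moderated differential expression

A two-group linear model per feature: logFC = mean(case) − mean(control),
pooled within-group variance s² on d = n₁+n₂−2 df (per-feature d when the
NaN-aware fit is used, as for Ct panels). Empirical-Bayes moderation shrinks
s² toward a prior: s̃² = (d₀s₀² + d·s²)/(d₀+d), t = logFC /
(s̃·√(1/n₁+1/n₂)), referred to t with d₀+d df. The prior (d₀, s₀²) is
estimated by the method of moments on log s² (digamma/trigamma matching,
with a Newton trigamma inverse); d₀ = 0 reproduces the ordinary pooled t
exactly and d₀ = ∞ a z statistic (normal reference, the ∞-df limit).
Zero variances are excluded from moment estimation; features with zero
posterior variance are reported with infinite t and flagged. All tests are
two-sided; BH adjustment runs across all tested features. For Ct data the
matrix is sign-inverted before fitting so positive logFC means higher
abundance (lower Ct).

## Signatures and scaling

Markers are the top-n (default 100) genes per cell type by one-vs-rest log2
fold change of mean CPM with pseudocount 1, requiring detection in ≥10% of
the type's cells; ties break by detection fraction then gene id, making the
ranking deterministic and test-free. The signature matrix holds
log2(mean CPM + 1) per type, restricted to the marker union (or all genes).
`minmax_scale` implements the gene-wise [0,1] transformation
(x − min)/(max − min); constant rows map to zero and are flagged rather than
dropped. Protein–gene matching is by exact uppercase symbol.

## Deconvolution

Each sample is regressed on the signature columns with linear nu-SVR over
nu ∈ {0.25, 0.5, 0.75} (C = 1); the fit with the lowest reconstruction RMSE
is kept, negative coefficients are clamped to zero and the rest renormalized
to sum to one — the CIBERSORT-style recipe. Two design choices are this
package's own:

- **Shared gene-wise scaling on the linear scale.** Both matrices are mapped
  to [0,1] by the *signature's* per-gene min/max after exponentiation.
  Because the fractions sum to one, a shared per-gene affine transform
  preserves the convex-mixture identity exactly
  (`scaled_mixture = Σ p_k · scaled_signature_k`), which is what makes
  noise-free mixtures exactly invertible while still calibrating away
  per-gene unit differences between modalities. Scaling the mixture by its
  own min/max across samples instead reduces each gene to its rank across
  samples and destroys the mixture identity. Genes constant across cell
  types are scaled by the median positive gene span; their predictors are
  zero, and they anchor the regression intercept, which would otherwise be
  confounded with a uniform shift of all coefficients.
- **Deconvolution input.** The variance-stabilized matrix feeds model
  fitting/DE; deconvolution consumes the imputed matrix in original log2
  intensity units, because the VST's per-sample MAD scaling acts as a power
  transform on the linear scale and distorts mixture proportions.

Group shifts are tested per cell type with a two-sided Welch t on per-sample
proportions (the upstream description marks significance without naming a
test) and BH adjustment; group means are reported as percentages.

Known limitation: signatures derived from CPM-normalized counts carry each
cell type's unknown total-RNA content as a per-column scale factor plus
per-gene sampling noise; proportions recovered against such a signature are
normalized-expression fractions and can deviate substantially from
mass-fraction truth (an errors-in-variables effect that also binds the NNLS
oracle). Recovery benchmarks therefore use reference signatures, and the
derived-signature route is validated by marker and correlation recovery.

## Enrichment

The running-sum statistic over a ranked list: a set member at rank i adds
|metric_i|^weight (normalized to sum to one over the set) and every rank
carries a position penalty 1/N, so the running sum is a bridge ending at 0
and the ES — its signed maximum deviation — satisfies |ES| ≤ 1, with a
top-concentrated set approaching 1 − |S|/N. P-values come from gene-label
permutations with an add-one correction (p ≥ 1/(n_perm+1)), or from
exhaustive enumeration of all C(N,|S|) placements when requested (used by
the oracle tests). NES divides ES by the mean |ES| of same-signed
permutations and is NaN when none share the sign. The leading edge is the
set members at or before the extremum (at or after, for negative ES). Ties
in the ranking break by gene id.

For cell-type grids, genes are ranked per type by the z-score of that type's
expression across types. The grid default is the *unweighted* statistic
(weight 0): its permutation null is independent of the metric, so NES values
are comparable across cell types and "the type with maximal NES" is
well-defined; `gsea_preranked` itself defaults to weight 1, the cited tool's
default. Note that the two-sided statistic detects any non-uniform
placement, including central clumping — a set of deliberately non-specific
genes is only null when such genes scatter through the ranking as they do in
realistic profiles. Over-representation uses the exact hypergeometric upper
tail.

## Ligand–receptor modules

DE features (p < 0.05, |logFC| > 0.5 by default, strict inequalities) are
joined to a user-supplied curated interaction table (never downloaded);
receptors of up- and downregulated ligands form two modules, with
multi-subunit complexes (underscore-joined symbols) expanded to subunit
genes. Modules are scored across cell types by the enrichment grid; a
mean-z-score alternative with gene-label permutation p-values is provided
because the exact statistic behind the original module scores is not pinned.

## Ct processing and origin calls

Wells with Ct above `ct_max` or amplification score below `amp_min` are
unreliable; miRNAs with more than `max_unreliable` (default 3) unreliable
wells are removed, the rest keep those wells as missing. The defaults
ct_max = 35 and amp_min = 1.24 stand in for thresholds normally read off a
density scatter plot and are logged on every filter call. Three
normalizations: sample means (the geometric-mean equivalent, Ct being
log-scale), rank-invariant features (cross-sample rank SD ≤ 1), and
scale-invariant features (CV ≤ 2%); empty invariant sets fall back to the
mean method with a warning. Diagnostics report per-sample median relative
log expression before/after. ΔΔCt: per-sample ΔCt against a reference assay,
case-minus-control difference of group means, reported as 2^(−ΔΔCt)·100%.

Origin classification is a total function of the evidence: *endogenous* if
the miRNA drops significantly in the DICER-knockout contrast (the cell was
producing it) or its primary transcript is detected; *exogenous* if the
knockout shows a rise or no significant change and neither primary
transcript nor precursor change is seen; *indeterminate* otherwise.
"Precursor unchanged" defaults to |logFC| < 0.5 with p ≥ 0.05.

## Pipeline and reproducibility

A single config (YAML or `RunConfig`) drives the stages in dependency order
with fail-fast input validation; one top-level seed is expanded via
`SeedSequence` into per-stage seeds; the manifest records version, seeds,
thresholds, per-stage summaries and SHA-256 hashes of every output, and
re-running a config reproduces the hashes. All outputs are plain
TSV/CSV/JSON/GMT.

## Problem sizes

The packaged experiments use 500–600 genes, 5 cell types, 5–6 samples per
group, 40–100 cells per type, 100–200 miRNA assays, and 200–1000
permutations or 10–20 simulation replicates per check — sizes at which every
recovery experiment in `scripts/acceptance.py` completes in well under a
minute each while leaving the Monte-Carlo error comfortably inside the
asserted tolerances.
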