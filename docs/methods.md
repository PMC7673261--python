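# Methods

This note documents the statistical model behind `catmap`, the choices
made where the design was genuinely open, what the synthetic cohorts do
and do not emulate, and the numerical conventions.

## 1. Cross-species normalization

**Ortholog restriction.** The unit of cross-species identity is the
1:1 ortholog pair. Homology tables are reduced conservatively: any gene
participating in more than one pair is dropped together with all of its
pairs (one-to-many and many-to-many relations carry ambiguous identity,
and the reduction matches the semantics of a BioMart one-to-one
export). When chromosome annotations are available, pairs touching a
sex chromosome are removed so that donor sex cannot masquerade as
subtype signal. After restriction both matrices are re-keyed to the
pair ID (`geneA|geneB`), which makes every downstream gene-set
intersection well defined.

**Eligibility.** A gene is kept when it exceeds 1 count per million in
at least 3 samples, per species, with library size taken as the column
sum of the input matrix; in the paired pipeline a gene must pass in
*both* species to remain in the compendium. Defaults (`min_cpm=1`,
`min_samples=3`) are exposed.

**Variance stabilization.** Counts are transformed as
`log2(count / size_factor + 1)` with median-of-ratios size factors
(geometric-mean reference over genes observed in every sample; library-
size factors scaled to median 1 as fallback, with a warning). Every
downstream statistic — medians, ranks, linear contrasts — requires only
a monotone variance-stabilizing transform, so a dispersion-trend-fitted
VST would change nothing structurally; the transform is pluggable
(`transform=` argument) for users who want to feed in one. Note one
identity that does *not* hold: doubling every count of one of *n*
samples rescales the whole normalized matrix by `2^(1/n)` (the sample's
own factor absorbs only `2^((n-1)/n)` because the geometric reference
moves too). Between-sample structure is invariant; absolute values are
not.

**Subject regression.** Sorted populations from the same donor share
donor-level expression offsets. Per gene, an intercept-only linear
mixed model with a random intercept per donor is fitted and the
returned values are the fixed intercept plus residuals — the
observation minus its donor's predicted (BLUP) offset. When the
estimated donor variance is zero (*singular fit*, which includes every
constant gene and every design where donors contribute single samples)
the input values are kept and the gene is flagged; the flag travels
with the matrix. Because the donor offsets in this model are shrunken
BLUPs, the output differs from naive per-donor centering by the
shrinkage factor `σ²_d / (σ²_d + σ²_e / n_d)`; with strong donor
effects the two coincide, which is how the implementation is tested.

**Joint quantile normalization.** After subject regression, both
species' samples are quantile-normalized *together*: each sample's k-th
order statistic is replaced by the mean k-th order statistic over the
combined sample set. Ties within a sample receive the mean of the
reference values their rank block spans (the convention of the common
reference implementation; the tie rule is not statistically
identified, only a convention). Afterwards all samples share one
empirical distribution exactly — cross-species distributional
differences can no longer pose as biology — and within-sample ranks are
untouched up to ties.

**Highly variable genes.** Per species, genes are ranked by variance of
natural-log-scaled values and the top `n_top` (default 2000) sets are
intersected through the ortholog pairing. Real single-cell toolchains
use dispersion-binned selection dialects; since the shared-HVG set here
only feeds visualization-style downstream use, plain log-scale variance
is used and documented as such.

## 2. Marker scoring

For each species separately, on the eligible gene set:

* **Scaled median** `m(g, s)`: median of `g` over the samples of
  subtype `s`, divided by the median over all samples of the species
  (+ ε, ε = 1e−8). `m = 0` when the subtype median is ≤ 0; a gene
  silent overall but expressed in the subtype keeps its unscaled
  subtype median. The scaled median uses the quantile-normalized,
  subject-regressed values. An alternative denominator (median of the
  per-subtype medians) is available via `scale_by=`.
* **Mixed model**: `value ~ subtype (fixed) + donor (random intercept)`
  per gene, fitted by REML on the VST-stage values — the model owns the
  donor intercept, so feeding it pre-regressed values would double-count
  the correction. The **overall F gate** jointly tests all subtype
  coefficients; p-values are Benjamini–Hochberg adjusted across genes.
* **Directional Stouffer Z**: for subtype `s`, every pairwise contrast
  against another subtype yields a two-sided p and an effect sign.
  Positive contrasts enter as `pᵢ`, non-positive ones as
  `max(pᵢ, 1 − pᵢ)` — an exactly-tied contrast (sign 0) is treated as
  "lower", the conservative choice for markerhood. `Z = Σ Φ⁻¹(1 − p'ᵢ) / √m`
  with equal weights; p is clipped to `[1e−300, 1 − 1e−16]` before
  inversion so noise-free inputs stay finite.
* **Score and ranks**: `score = m · Z`; within a subtype, genes with
  BH-adjusted overall p ≤ α (default 0.05) *and* Z > 0 are ranked by
  decreasing score, ties broken by higher `m`, then lexicographic gene
  ID — rankings are fully deterministic.

The two-sided reading of the contrast p-values is the literal one for
t-test output; directionality enters only through the
`max(pᵢ, 1 − pᵢ)` substitution. One consequence worth knowing: a gene
elevated equally in two subtypes is dragged down in *both* by their
mutual null contrast, so shared "core" programs rank below genuinely
private markers of the same magnitude (tested noise-free).

## 3. Mixed-model machinery

All models have a single random intercept, so the REML criterion is
profiled to a 1-D search over the variance ratio λ = σ²_donor/σ²_resid
after one eigendecomposition of ZZ′ shared by every gene
(`catmap.lmm`). This is ~3 orders of magnitude faster than a generic
mixed-model optimizer and is cross-checked against `statsmodels.MixedLM`
in the test suite (fixed effects, variance components, Wald contrasts).
λ̂ at the boundary (0) is a singular fit → OLS fallback.

Degrees of freedom: the default reference is the large-sample Wald
normal/chi-square. The optional **Satterthwaite** mode estimates
denominator df from the curvature of the REML likelihood in
(σ²_donor, σ²_resid) — numerical gradient of the contrast variance and
numerical observed information, with multi-df F statistics combined
eigencontrast-wise. The modes agree asymptotically; at compendium-scale
designs (~30 samples) the chi-square reference is visibly
anticonservative, so calibration-sensitive analyses (and the null-
calibration acceptance test) use Satterthwaite. Singular fits use exact
OLS residual df. A noise-free gene gets its residual variance floored
at 1e−30 so that contrasts stay finite and directional: non-zero
effects → p ≈ 0, exact ties → p = 1; contrast estimates below 1e−9 of
the coefficient scale are snapped to zero so float dust cannot invent a
direction.

## 4. CAT homology

`overlap(k) = |top_k(ref) ∩ top_k(cand)|/k`, computed incrementally in
O(L); the mean over k = 1..L (default L = 1000) is the correspondence
statistic; the assignment is the row argmax, exact ties all reported in
lexicographic order. The statistic is symmetric in its two lists, but
the argmax is not required to be reciprocal — asymmetric assignments
are biologically meaningful (one subtype may be the best available
proxy for a partner that matches something else better). Lists shorter
than L — common in small simulations, where only a few hundred genes
are eligible — are averaged over their available length and a warning
records the effective L. For two independent random rankings of G
genes, E[overlap(k)] = k/G, hence E[mean CAT] = (L+1)/(2G): the random
baseline every observed overlap should be read against. The row-wise
min-max-scaled matrix (constant rows → zeros, warned) is provided for
heatmap display only; inference uses the raw means.

## 5. Signature comparison

External signature tables (gene, cluster, ranking statistic) are
reduced to top-N sets (default N = 20) after removing genes outside the
analysis universe and genes duplicated within a cluster; ties in the
ranking statistic break lexicographically. Per-gene cluster specificity
can be re-scored as EMD × AUC between in-cluster and out-of-cluster
expression values: AUC is the Mann–Whitney U/(n_in·n_out) with ties
counting ½ and in-cluster oriented high (AUC > 0.5 = higher inside),
EMD the 1-D Wasserstein-1 distance. The score is applied here to the
quantile-normalized compendium values rather than to single-cell counts
as in the method's original setting — a substitution users should keep
in mind. Profiles for heatmap-style comparison min-max scale each gene
to [0, 1] across samples before averaging over signature genes.

## 6. Synthetic cohorts

`simulate_cohort` generates: per-species gene baselines
log2 ~ N(5, 1.5) drawn *independently per species* (so absolute levels
carry no cross-species information and homology is only recoverable
through marker structure); per-subtype marker programs of
`markers_per_subtype` genes elevated by `marker_log2_effect` (default
4, i.e. 16-fold) in their subtype only; for each planted homolog pair a
fraction ρ (`conservation`) of markers conserved as the same ortholog,
the rest species-private, all marker blocks globally disjoint; donors
contributing one sample to every subtype (crossed, balanced design) with
a N(0, donor_sd) log-scale intercept shared across a donor's samples;
and NB counts with `Var = μ + α μ²` (α = `nb_dispersion`, default 0.05)
at library sizes uniform in 1–3 million. Default cohort shape (15 and 9
subtypes, 4 replicates, 5 donors, ~12k genes) mirrors a real sorted-
population compendium; acceptance-scale runs use 8 + 8 subtypes and
2000 genes for desk-time budgets.

What the generator does **not** emulate: batch effects beyond the donor
intercept, compositional library artifacts, correlated gene programs,
unequal replicate counts, or count-level donor effects that survive
normalization (a gene-independent donor offset is largely absorbed by
size factors — which is realistic, and why the subject-regression
oracle test feeds the regression continuous data with explicit
offsets). A green recovery test therefore establishes that the pipeline
recovers *planted rank structure under NB noise*, not that it is robust
to every real-data pathology.

## 7. Numerical conventions and edge cases

* All tables are TSV, UTF-8, deterministic column order, no index
  column; write → read round-trips are byte-identical.
* The full pipeline is RNG-free after simulation; reruns at a fixed
  config/seed are byte-identical.
* REML λ search: bounded Brent on log λ ∈ [−14, 16], xatol 1e−6;
  singular iff the boundary value is at least as good or λ̂ ≤ 1e−6.
* BH adjustment backs onto `scipy.stats.false_discovery_control`.
* Quantile normalization, min-max scaling and CAT curves warn rather
  than fail on degenerate inputs (constant rows, short lists), because
  small simulated cohorts hit these routinely.

## 8. Known limitations

* Satterthwaite df relies on finite-difference curvature; for variance
  estimates very near the boundary it falls back to residual df.
* The VST stand-in is not DESeq2's dispersion-trend VST; rank-based
  downstream statistics are insensitive to this, absolute values are
  not.
* CAT mean overlap has no attached significance measure here (none is
  established for it); judge assignments against the (L+1)/(2G) random
  baseline and the full matrix, not the argmax alone.
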