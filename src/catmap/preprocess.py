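"""Cross-species normalization chain.

Order of operations for the compendium: restrict both species to their
1:1 autosomal orthologs (re-keyed to shared pair IDs), drop genes that
fail the counts-per-million eligibility filter in either species,
variance-stabilize, regress out donor/subject random intercepts per
species, then quantile-normalize the two species' samples jointly so
that systematic distributional differences between species cannot
masquerade as biology.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, NormalizedMatrix, OrthologMap, ValidationError
from .lmm import MixedDesign, build_design

__all__ = [
    "restrict_to_orthologs",
    "cpm_filter",
    "vst",
    "regress_subject",
    "quantile_normalize",
    "select_hvg",
    "median_of_ratios_size_factors",
]

logger = logging.getLogger(__name__)


def restrict_to_orthologs(
    cm_a: CountMatrix, cm_b: CountMatrix, orthologs: OrthologMap
) -> tuple[CountMatrix, CountMatrix]:
    """Reduce both count matrices to the shared 1:1 ortholog set.

    Output rows are re-labelled with the cross-species pair ID
    (``geneA|geneB``) in identical order on both sides, which makes
    every downstream gene-set intersection well defined.
    """
    pairs = orthologs.pairs
    present = pairs["gene_a"].isin(cm_a.counts.index) & pairs["gene_b"].isin(cm_b.counts.index)
    kept = pairs[present.to_numpy()]
    if kept.empty:
        raise ValidationError("no ortholog pairs present in both count matrices")
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("restrict_to_orthologs: %d pairs absent from counts dropped", dropped)
    pair_ids = kept["gene_a"] + "|" + kept["gene_b"]
    out_a = cm_a.counts.loc[kept["gene_a"]].set_axis(pair_ids, axis=0)
    out_b = cm_b.counts.loc[kept["gene_b"]].set_axis(pair_ids, axis=0)
    return (
        CountMatrix(counts=out_a, species=cm_a.species),
        CountMatrix(counts=out_b, species=cm_b.species),
    )


def cpm_filter(cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> pd.Index:
    """Genes with more than ``min_cpm`` counts per million in at least
    ``min_samples`` samples.

    Library size is the column sum of the input matrix.
    """
    libsize = cm.library_sizes()
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValidationError(f"zero library size for samples: {list(zero.index)}")
    cpm = cm.counts.to_numpy() / libsize.to_numpy()[None, :] * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    logger.info("cpm_filter: %d of %d genes retained", int(keep.sum()), cm.shape[0])
    return cm.counts.index[keep]


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per sample, the median ratio of its
    counts to the geometric-mean reference gene, over genes observed in
    every sample. Falls back to library-size factors (scaled to median
    1) when no gene is all-positive.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        warnings.warn(
            "no gene with positive counts in every sample; "
            "falling back to library-size size factors"
        )
        lib = mat.sum(axis=0)
        return pd.Series(lib / np.median(lib), index=counts.columns)
    log_ref = np.mean(np.log(mat[all_positive]), axis=1)
    ratios = np.log(mat[all_positive]) - log_ref[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def vst(cm: CountMatrix, transform: str = "log2_mor") -> NormalizedMatrix:
    """Variance-stabilizing transform of counts to a continuous scale.

    The default ``log2_mor`` divides by median-of-ratios size factors
    and takes log2(x + 1); any monotone stabilizer suits the downstream
    statistics (medians, ranks, linear contrasts), so the transform is
    pluggable. ``log2_cpm`` is provided as an alternative.
    """
    if transform == "log2_mor":
        sf = median_of_ratios_size_factors(cm.counts)
        values = np.log2(cm.counts / sf + 1.0)
    elif transform == "log2_cpm":
        lib = cm.library_sizes()
        values = np.log2(cm.counts / lib * 1e6 + 1.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return NormalizedMatrix(values=values, stage="vst", species=cm.species)


def regress_subject(nm: NormalizedMatrix, meta: pd.DataFrame) -> NormalizedMatrix:
    """Remove per-subject random intercepts from each gene.

    Fits, per gene, an intercept-only mixed model with a random
    intercept per subject and returns the fixed intercept plus
    residuals (the observation minus its subject's predicted offset).
    Genes with a singular fit — zero estimated subject variance,
    including every constant gene — keep their input values and are
    flagged. Run one species at a time.
    """
    meta = meta.set_index("sample_id").loc[nm.sample_ids]
    if meta["species"].nunique() > 1:
        raise ValidationError("regress_subject must be run per species")
    X, _, _ = build_design(None, samples=nm.sample_ids)
    design = MixedDesign(X, meta["subject_id"].to_numpy(), ["(Intercept)"])
    mat = nm.values.to_numpy(dtype=float)
    out = np.empty_like(mat)
    flags = np.zeros(mat.shape[0], dtype=bool)
    for i in range(mat.shape[0]):
        out[i], flags[i] = design.remove_subject_effects(mat[i])
    n_fallback = int(flags.sum())
    if n_fallback:
        logger.info("regress_subject: %d genes kept original values (singular fit)", n_fallback)
    values = pd.DataFrame(out, index=nm.values.index, columns=nm.values.columns)
    return nm.advance(values, "subject_regressed", fallback=pd.Series(flags, index=nm.values.index))


def _quantile_normalize_values(mat: np.ndarray) -> np.ndarray:
    """Classic quantile normalization; ties get the mean of the
    reference values their rank block spans."""
    n_genes, n_samples = mat.shape
    order = np.argsort(mat, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(mat, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(mat, dtype=float)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # average the reference over each run of tied input values
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = reference[s:e].mean()
        out[order[:, j], j] = assigned
    return out


def quantile_normalize(
    nm_a: NormalizedMatrix, nm_b: NormalizedMatrix
) -> tuple[NormalizedMatrix, NormalizedMatrix]:
    """Quantile-normalize the two species' samples jointly.

    Every sample's k-th order statistic is replaced by the mean k-th
    order statistic across the combined sample set, forcing all samples
    onto one empirical distribution. Rows must already be aligned by
    ortholog pair.
    """
    if list(nm_a.values.index) != list(nm_b.values.index):
        raise ValidationError("matrices are not row-aligned by ortholog pair")
    combined = np.hstack([nm_a.values.to_numpy(float), nm_b.values.to_numpy(float)])
    normed = _quantile_normalize_values(combined)
    n_a = nm_a.values.shape[1]
    va = pd.DataFrame(normed[:, :n_a], index=nm_a.values.index, columns=nm_a.values.columns)
    vb = pd.DataFrame(normed[:, n_a:], index=nm_b.values.index, columns=nm_b.values.columns)
    return (
        nm_a.advance(va, "quantile_normalized"),
        nm_b.advance(vb, "quantile_normalized"),
    )


def select_hvg(nm_a: NormalizedMatrix, nm_b: NormalizedMatrix, n_top: int = 2000) -> pd.Index:
    """Highly variable genes shared between the species.

    Each species ranks genes by variance of natural-log-scaled values
    and keeps its ``n_top``; the result is the intersection through the
    ortholog pairing (rows are already keyed by pair ID).
    """
    sets = []
    for nm in (nm_a, nm_b):
        vals = nm.values.to_numpy(float) * np.log(2)  # log2 -> natural-log scale
        var = vals.var(axis=1, ddof=1)
        k = n_top
        if k > len(var):
            warnings.warn(f"n_top={n_top} exceeds gene count {len(var)}; using all genes")
            k = len(var)
        top = np.argsort(-var, kind="stable")[:k]
        sets.append(set(nm.values.index[top]))
    shared = sets[0] & sets[1]
    if not shared:
        warnings.warn("no highly variable genes shared between species")
    logger.info("select_hvg: %d shared of top %d per species", len(shared), n_top)
    return pd.Index(sorted(shared), name="gene_id")


def spearman_correspondence(nm_a: NormalizedMatrix, nm_b: NormalizedMatrix,
                            meta_a: pd.DataFrame, meta_b: pd.DataFrame) -> pd.DataFrame:
    """Optional baseline: Spearman correlation of per-subtype mean
    profiles across species (for comparison against CAT assignment)."""
    prof = []
    for nm, meta in ((nm_a, meta_a), (nm_b, meta_b)):
        m = meta.set_index("sample_id").loc[nm.sample_ids]
        prof.append(nm.values.T.groupby(m["subtype"].to_numpy()).mean().T)
    a, b = prof
    rho = np.zeros((a.shape[1], b.shape[1]))
    for i, ca in enumerate(a.columns):
        for j, cb in enumerate(b.columns):
            rho[i, j] = stats.spearmanr(a[ca], b[cb]).statistic
    return pd.DataFrame(rho, index=a.columns, columns=b.columns)
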