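"""Subtype-specific marker-gene scoring.

A marker gene for a cell subtype should be both *highly* expressed
there and *preferentially* expressed there. The score for gene g in
subtype s is the product of two ingredients:

* ``m`` — the median expression of g across the samples of s, scaled by
  the species-wide median of g. Scaling by the overall median separates
  genes high in a minority of subtypes from housekeeping-like genes
  high everywhere.
* ``Z`` — a meta-analytic (Stouffer) combination over all pairwise
  subtype contrasts from a per-gene mixed model (subtype fixed effect,
  random intercept per subject). A contrast where s is *higher* enters
  with its two-sided p-value p_i; one where s is lower (or exactly
  tied) enters with max(p_i, 1 - p_i), penalizing the combined Z. A
  gene equally elevated in two subtypes is dragged down by their mutual
  null contrast, so shared "core" programs score below truly private
  markers.

Genes are eligible for ranking in a subtype when the overall
mixed-model F-test is Benjamini-Hochberg significant (adjusted
p <= alpha) and Z > 0.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import NormalizedMatrix, ValidationError
from .lmm import MixedDesign, build_design

__all__ = [
    "scaled_median",
    "overall_f_test",
    "pairwise_contrast_p",
    "combine_z",
    "benjamini_hochberg",
    "marker_scores",
    "ranked_marker_list",
]

logger = logging.getLogger(__name__)

EPSILON = 1e-8
_P_LO, _P_HI = 1e-300, 1.0 - 1e-16

MARKER_COLUMNS = [
    "gene_id", "subtype", "scaled_median", "z", "p_overall", "p_adj",
    "score", "eligible", "rank",
]


def _aligned_meta(nm: NormalizedMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    m = meta.set_index("sample_id")
    missing = [s for s in nm.sample_ids if s not in m.index]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    return m.loc[nm.sample_ids]


def scaled_median(
    nm: NormalizedMatrix, meta: pd.DataFrame, subtype: str,
    scale_by: str = "all_samples",
) -> pd.Series:
    """Median expression in ``subtype`` scaled by the species-wide median.

    ``scale_by='all_samples'`` (default) divides by the median over all
    samples of the species; ``'subtype_medians'`` divides by the median
    of the per-subtype medians instead. A small epsilon guards the
    denominator; a gene whose subtype median is zero gets m = 0, and a
    gene silent overall but expressed in the subtype keeps its subtype
    median unscaled.
    """
    m = _aligned_meta(nm, meta)
    if subtype not in set(m["subtype"]):
        raise ValidationError(f"unknown subtype {subtype!r}")
    in_sub = (m["subtype"] == subtype).to_numpy()
    vals = nm.values.to_numpy(float)
    sub_med = np.median(vals[:, in_sub], axis=1)
    if scale_by == "all_samples":
        overall = np.median(vals, axis=1)
    elif scale_by == "subtype_medians":
        per_sub = np.stack(
            [np.median(vals[:, (m["subtype"] == s).to_numpy()], axis=1)
             for s in sorted(m["subtype"].unique())]
        )
        overall = np.median(per_sub, axis=0)
    else:
        raise ValueError(f"unknown scale_by {scale_by!r}")
    out = np.where(
        sub_med <= 0.0, 0.0,
        np.where(overall <= 0.0, sub_med, sub_med / (overall + EPSILON)),
    )
    return pd.Series(out, index=nm.values.index, name=subtype)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def combine_z(pairs) -> float:
    """Stouffer combination of directed pairwise contrast p-values.

    ``pairs`` is a sequence of ``(p_i, sign_i)``; a positive sign keeps
    p_i, any other sign substitutes max(p_i, 1 - p_i). Each directed
    p' maps to z = Phi^-1(1 - p'); Z is their unweighted Stouffer sum,
    sum(z) / sqrt(m).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("combine_z needs at least one contrast")
    p = np.array([pi for pi, _ in pairs], dtype=float)
    sign = np.array([si for _, si in pairs], dtype=float)
    p_dir = np.where(sign > 0, p, np.maximum(p, 1.0 - p))
    p_dir = np.clip(p_dir, _P_LO, _P_HI)
    z = stats.norm.isf(p_dir)
    return float(z.sum() / np.sqrt(len(pairs)))


class _FittedModels:
    """Per-gene mixed-model fits shared by the F-test and all contrasts."""

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame, df_method: str):
        subtype = meta["subtype"]
        if subtype.nunique() < 2:
            raise ValidationError("need at least 2 subtypes")
        X, coef_names, levels = build_design(subtype)
        self.levels = levels
        self.df_method = df_method
        self.design = MixedDesign(X, meta["subject_id"].to_numpy(), coef_names)
        self.values = values
        p = X.shape[1]
        self.L_overall = np.eye(p)[1:]
        self.pair_index = list(itertools.combinations(range(len(levels)), 2))
        C = np.zeros((len(self.pair_index), p))
        for r, (i, j) in enumerate(self.pair_index):
            if i > 0:
                C[r, i] = 1.0
            if j > 0:
                C[r, j] = -1.0
        self.C = C  # contrast rows: mean(level_i) - mean(level_j)
        self._fits = {}

    def fit_gene(self, gene: str):
        if gene not in self._fits:
            y = self.values.loc[gene].to_numpy(float)
            yt = self.design.rotate(y)
            fit = self.design.fit_rotated(yt)
            self._fits[gene] = (fit, yt)
        return self._fits[gene]

    def overall_p(self, gene: str) -> float:
        fit, yt = self.fit_gene(gene)
        if np.ptp(self.values.loc[gene].to_numpy(float)) == 0.0:
            return 1.0
        p = self.design.f_test(fit, self.L_overall, yt=yt, df_method=self.df_method)
        return 1.0 if not np.isfinite(p) else float(p)

    def pairwise(self, gene: str):
        """(est, p) for every unordered subtype pair, in self.pair_index order."""
        fit, yt = self.fit_gene(gene)
        est, pvals = self.design.contrast_tests(fit, self.C, yt=yt, df_method=self.df_method)
        return est, np.nan_to_num(pvals, nan=1.0)


def overall_f_test(
    nm: NormalizedMatrix, meta: pd.DataFrame, df_method: str = "wald"
) -> pd.DataFrame:
    """Per-gene joint test that any subtype differs, with BH adjustment.

    Fits the mixed model expression ~ subtype + (1 | subject) per gene
    and tests all subtype coefficients jointly (Wald chi-square by
    default, Satterthwaite-F optionally).
    """
    m = _aligned_meta(nm, meta)
    models = _FittedModels(nm.values, m, df_method)
    pvals = np.array([models.overall_p(g) for g in nm.values.index])
    return pd.DataFrame(
        {"p_overall": pvals, "p_adj": benjamini_hochberg(pvals)},
        index=nm.values.index,
    )


def pairwise_contrast_p(
    nm: NormalizedMatrix, meta: pd.DataFrame, subtype_of_interest: str,
    df_method: str = "wald",
) -> pd.DataFrame:
    """Two-sided contrast p-values (and effect signs) of the subtype of
    interest against every other subtype, per gene."""
    m = _aligned_meta(nm, meta)
    models = _FittedModels(nm.values, m, df_method)
    if subtype_of_interest not in models.levels:
        raise ValidationError(f"unknown subtype {subtype_of_interest!r}")
    s_idx = models.levels.index(subtype_of_interest)
    rows = []
    for gene in nm.values.index:
        est, pvals = models.pairwise(gene)
        for r, (i, j) in enumerate(models.pair_index):
            if s_idx == i:
                other, e = models.levels[j], est[r]
            elif s_idx == j:
                other, e = models.levels[i], -est[r]
            else:
                continue
            rows.append((gene, other, float(pvals[r]), int(np.sign(e))))
    return pd.DataFrame(rows, columns=["gene_id", "other_subtype", "p", "sign"])


def marker_scores(
    nm: NormalizedMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    df_method: str = "wald",
    model_values: NormalizedMatrix | pd.DataFrame | None = None,
    scale_by: str = "all_samples",
) -> pd.DataFrame:
    """Full marker table for one species.

    ``nm`` supplies the expression values for the scaled medians
    (normally the quantile-normalized stage); ``model_values`` supplies
    the values the mixed models are fitted on (normally the VST stage —
    the model owns the subject intercept, so pre-regressed values are
    not wanted there). When omitted, ``nm`` serves both roles.

    Returns a long-format table with one row per (gene, subtype):
    scaled median, combined Z, overall-F p and BH-adjusted p, score
    m * Z, eligibility, and the within-subtype rank of eligible genes
    (descending score; ties broken by higher m, then gene ID).
    """
    m = _aligned_meta(nm, meta)
    if model_values is None:
        model_df = nm.values
    elif isinstance(model_values, NormalizedMatrix):
        model_df = model_values.values
    else:
        model_df = model_values
    model_df = model_df.loc[nm.values.index, nm.sample_ids]
    models = _FittedModels(model_df, m, df_method)
    levels = models.levels
    genes = list(nm.values.index)

    medians = pd.DataFrame(
        {s: scaled_median(nm, meta, s, scale_by=scale_by) for s in levels}
    )
    p_overall = np.empty(len(genes))
    z_matrix = np.empty((len(genes), len(levels)))
    for gi, gene in enumerate(genes):
        p_overall[gi] = models.overall_p(gene)
        est, pvals = models.pairwise(gene)
        for si in range(len(levels)):
            contrib = []
            for r, (i, j) in enumerate(models.pair_index):
                if si == i:
                    contrib.append((pvals[r], int(np.sign(est[r]))))
                elif si == j:
                    contrib.append((pvals[r], int(np.sign(-est[r]))))
            z_matrix[gi, si] = combine_z(contrib)
    p_adj = benjamini_hochberg(p_overall)

    rows = []
    for si, s in enumerate(levels):
        med = medians[s].to_numpy()
        z = z_matrix[:, si]
        score = med * z
        eligible = (p_adj <= alpha) & (z > 0)
        rows.append(pd.DataFrame({
            "gene_id": genes, "subtype": s, "scaled_median": med, "z": z,
            "p_overall": p_overall, "p_adj": p_adj, "score": score,
            "eligible": eligible,
        }))
    table = pd.concat(rows, ignore_index=True)

    table["rank"] = pd.NA
    for s in levels:
        mask = (table["subtype"] == s) & table["eligible"]
        block = table.loc[mask].sort_values(
            ["score", "scaled_median", "gene_id"],
            ascending=[False, False, True], kind="stable",
        )
        table.loc[block.index, "rank"] = np.arange(1, len(block) + 1)
    table["rank"] = table["rank"].astype("Int64")
    n_elig = int(table["eligible"].sum())
    logger.info("marker_scores: %d eligible (gene, subtype) pairs of %d", n_elig, len(table))
    return table[MARKER_COLUMNS]


def ranked_marker_list(table: pd.DataFrame, subtype: str, max_len: int | None = None) -> list[str]:
    """Eligible genes of one subtype in decreasing marker-score order."""
    block = table[(table["subtype"] == subtype) & table["eligible"]]
    block = block.sort_values("rank")
    genes = block["gene_id"].tolist()
    return genes if max_len is None else genes[:max_len]
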