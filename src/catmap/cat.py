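"""Correspondence-at-the-top (CAT) homology assignment.

Given one ranked marker-gene list per subtype and species (in the
shared ortholog-pair ID space), the CAT curve between a reference and a
candidate list is the proportion of shared genes among their top-k
entries, traced over k. Averaging the curve over k = 1..L (default
L = 1000) yields the mean CAT overlap, a scale-free correspondence
statistic that rewards agreement at the very top of the lists; each
reference subtype's cross-species analog is the candidate maximizing
it. Note the argmax need not be reciprocal between species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "cat_curve",
    "mean_cat",
    "assign_homologs",
    "scale_rows_minmax",
    "homology_analysis",
    "HomologyResult",
]

logger = logging.getLogger(__name__)

DEFAULT_L = 1000


def cat_curve(ref: list[str], cand: list[str], L: int = DEFAULT_L) -> np.ndarray:
    """Proportion of shared genes among the top-k of both lists, k = 1..L.

    Computed incrementally: at step k the k-th gene of each list joins
    its side's top set and the running intersection count is updated,
    so the whole curve costs O(L) set operations. The curve stops at
    min(L, len(ref), len(cand)).
    """
    if not ref or not cand:
        raise ValueError("CAT curve needs two non-empty ranked lists")
    if len(set(ref)) != len(ref) or len(set(cand)) != len(cand):
        raise ValueError("ranked lists may not contain duplicate genes")
    kmax = min(L, len(ref), len(cand))
    in_ref: set[str] = set()
    in_cand: set[str] = set()
    overlap = np.empty(kmax)
    common = 0
    for k in range(kmax):
        g_r, g_c = ref[k], cand[k]
        if g_r == g_c:
            common += 1
        else:
            if g_r in in_cand:
                common += 1
            if g_c in in_ref:
                common += 1
        in_ref.add(g_r)
        in_cand.add(g_c)
        overlap[k] = common / (k + 1)
    return overlap


def mean_cat(overlap: np.ndarray, L: int = DEFAULT_L) -> float:
    """Arithmetic mean of the CAT curve over list sizes 1..L.

    A curve shorter than L (lists with fewer eligible genes) is
    averaged over its available length, with a warning.
    """
    overlap = np.asarray(overlap, dtype=float)
    if len(overlap) < L:
        warnings.warn(
            f"CAT curve has {len(overlap)} points < L={L}; averaging over available sizes"
        )
    return float(overlap[:L].mean())


def assign_homologs(mean_cat_matrix: pd.DataFrame) -> dict[str, list[str]]:
    """Per reference subtype (row), the candidate(s) with maximal mean
    CAT overlap. Exact ties are all reported, lexicographically ordered."""
    assignment: dict[str, list[str]] = {}
    for ref, row in mean_cat_matrix.iterrows():
        best = row.max()
        assignment[str(ref)] = sorted(str(c) for c in row.index[row == best])
    return assignment


def scale_rows_minmax(matrix: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each row to [0, 1] to emphasize, per reference
    subtype, which candidate corresponds best. Constant rows become
    all zeros, with a warning."""
    values = matrix.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows scaled to all zeros")
    span[flat] = 1.0
    out = (values - lo) / span
    out[flat] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


@dataclass
class HomologyResult:
    """CAT curves, mean-CAT matrices and assignments for both directions."""

    curves: pd.DataFrame  # long format: direction, reference, candidate, k, overlap
    mean_cat_ab: pd.DataFrame  # rows: species-A subtypes, cols: species-B subtypes
    mean_cat_ba: pd.DataFrame
    assignment_ab: dict[str, list[str]]
    assignment_ba: dict[str, list[str]]
    scaled_ab: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    scaled_ba: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scaled_ab is None:
            self.scaled_ab = scale_rows_minmax(self.mean_cat_ab)
        if self.scaled_ba is None:
            self.scaled_ba = scale_rows_minmax(self.mean_cat_ba)


def homology_analysis(
    lists_a: dict[str, list[str]],
    lists_b: dict[str, list[str]],
    L: int = DEFAULT_L,
) -> HomologyResult:
    """Full cross-species correspondence between two sets of ranked lists.

    ``lists_a`` / ``lists_b`` map subtype name to its ranked marker
    list (ortholog-pair IDs, decreasing marker score). Both assignment
    directions are computed; the pairwise mean CAT is symmetric in its
    two lists, so only the argmax direction differs.
    """
    for name, lists in (("A", lists_a), ("B", lists_b)):
        empty = [s for s, lst in lists.items() if not lst]
        if empty:
            raise ValueError(f"species {name} subtypes with empty marker lists: {empty}")
    subs_a = sorted(lists_a)
    subs_b = sorted(lists_b)
    mean_ab = pd.DataFrame(index=subs_a, columns=subs_b, dtype=float)
    curve_rows = []
    for sa in subs_a:
        for sb in subs_b:
            curve = cat_curve(lists_a[sa], lists_b[sb], L=L)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mean_ab.loc[sa, sb] = mean_cat(curve, L=L)
            curve_rows.append(pd.DataFrame({
                "reference": sa, "candidate": sb,
                "k": np.arange(1, len(curve) + 1), "overlap": curve,
            }))
    curves = pd.concat(curve_rows, ignore_index=True)
    mean_ba = mean_ab.T.copy()
    result = HomologyResult(
        curves=curves,
        mean_cat_ab=mean_ab,
        mean_cat_ba=mean_ba,
        assignment_ab=assign_homologs(mean_ab),
        assignment_ba=assign_homologs(mean_ba),
    )
    logger.info(
        "homology_analysis: %d x %d subtype pairs, L=%d", len(subs_a), len(subs_b), L
    )
    return result


def plot_cat_curves(result: HomologyResult, reference: str, path=None, L: int = DEFAULT_L):
    """One CAT panel for a reference subtype: every candidate's curve,
    the best match highlighted, vertical guide at k = L."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    best = set(result.assignment_ab.get(reference, []))
    sub = result.curves[result.curves["reference"] == reference]
    fig, ax = plt.subplots(figsize=(5, 4))
    for cand, grp in sub.groupby("candidate"):
        is_best = cand in best
        ax.plot(grp["k"], grp["overlap"] * 100,
                lw=2.0 if is_best else 0.8,
                color="crimson" if is_best else "grey",
                alpha=1.0 if is_best else 0.6,
                label=str(cand) if is_best else None)
    ax.axvline(L, ls="--", color="black", lw=0.8)
    ax.set_xlabel("list size k")
    ax.set_ylabel("% genes in common")
    ax.set_title(f"CAT curves — reference {reference}")
    if best:
        ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
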