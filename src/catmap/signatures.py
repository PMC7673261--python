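"""Scoring external signature gene sets against the compendium.

Published cell-subset signatures arrive as (gene, cluster, ranking
statistic) tables from heterogeneous sources. They are reduced to
comparable top-N sets after restriction to the analysis universe, and
per-gene cluster specificity can be re-scored as the product of the
earth mover's distance and the ROC AUC between in-cluster and
out-of-cluster expression values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import NormalizedMatrix, ValidationError

__all__ = ["top_n_signature", "emd_auc_score", "emd_auc_table", "signature_profile"]

logger = logging.getLogger(__name__)


def top_n_signature(
    table: pd.DataFrame, universe, n: int = 20
) -> dict[str, list[str]]:
    """Top-``n`` genes per cluster after universe filtering.

    Genes absent from the analysis universe are removed first, as are
    genes occurring more than once within a cluster; the survivors are
    sorted by decreasing ``rank_stat`` (ties broken lexicographically by
    gene ID) and truncated to ``n``.
    """
    if "rank_stat" not in table.columns:
        raise ValidationError("signature table needs a 'rank_stat' column (select one on read)")
    universe = set(universe)
    if not universe:
        raise ValidationError("empty analysis universe")
    out: dict[str, list[str]] = {}
    for cluster, block in table.groupby("cluster", sort=True):
        block = block[block["gene_id"].isin(universe)]
        block = block[~block["gene_id"].duplicated(keep=False)]
        if block.empty:
            warnings.warn(f"cluster {cluster!r}: no signature genes in the universe")
            out[str(cluster)] = []
            continue
        block = block.sort_values(
            ["rank_stat", "gene_id"], ascending=[False, True], kind="stable"
        )
        out[str(cluster)] = block["gene_id"].head(n).tolist()
    return out


def emd_auc_score(values_in, values_out) -> tuple[float, float, float]:
    """Earth mover's distance × ROC AUC between two expression samples.

    AUC is the Mann-Whitney U statistic divided by n_in * n_out, with
    in-cluster values as positives (ties count one half), so values
    above 0.5 mean the gene runs higher inside the cluster. EMD is the
    1-D Wasserstein-1 distance between the empirical distributions.
    Returns ``(emd, auc, emd * auc)``.
    """
    values_in = np.asarray(values_in, dtype=float)
    values_out = np.asarray(values_out, dtype=float)
    if values_in.size == 0 or values_out.size == 0:
        raise ValidationError("both groups must be non-empty")
    u = stats.mannwhitneyu(values_in, values_out, alternative="two-sided").statistic
    auc = float(u) / (values_in.size * values_out.size)
    emd = float(stats.wasserstein_distance(values_in, values_out))
    return emd, auc, emd * auc


def emd_auc_table(nm: NormalizedMatrix, meta: pd.DataFrame, cluster_col: str = "subtype") -> pd.DataFrame:
    """EMD×AUC score of every gene for every cluster (one-vs-rest)."""
    m = meta.set_index("sample_id").loc[nm.sample_ids]
    rows = []
    vals = nm.values
    for cluster in sorted(m[cluster_col].unique()):
        inside = (m[cluster_col] == cluster).to_numpy()
        if inside.all():
            raise ValidationError(f"cluster {cluster!r} contains every sample")
        vin = vals.loc[:, inside].to_numpy()
        vout = vals.loc[:, ~inside].to_numpy()
        for gi, gene in enumerate(vals.index):
            emd, auc, score = emd_auc_score(vin[gi], vout[gi])
            rows.append((gene, cluster, emd, auc, score))
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "emd", "auc", "rank_stat"])


def signature_profile(
    nm: NormalizedMatrix, meta: pd.DataFrame, signatures: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean min-max-scaled expression of each signature set per subtype.

    Each gene is min-max scaled to [0, 1] across samples before
    averaging, so the profile reflects where each signature peaks rather
    than absolute levels (heatmap-style comparison).
    """
    m = meta.set_index("sample_id").loc[nm.sample_ids]
    vals = nm.values.to_numpy(float)
    lo = vals.min(axis=1, keepdims=True)
    span = vals.max(axis=1, keepdims=True) - lo
    span[span == 0] = 1.0
    scaled = pd.DataFrame((vals - lo) / span, index=nm.values.index, columns=nm.values.columns)
    subtypes = sorted(m["subtype"].unique())
    rows = []
    for cluster, genes in signatures.items():
        genes = [g for g in genes if g in scaled.index]
        if not genes:
            warnings.warn(f"cluster {cluster!r}: no signature genes present in the matrix")
            rows.append([cluster] + [np.nan] * len(subtypes))
            continue
        block = scaled.loc[genes]
        rows.append(
            [cluster]
            + [float(block.loc[:, (m["subtype"] == s).to_numpy()].to_numpy().mean())
               for s in subtypes]
        )
    return pd.DataFrame(rows, columns=["cluster"] + subtypes)
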