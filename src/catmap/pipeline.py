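"""End-to-end orchestration: simulate/load → preprocess → markers →
homology → signatures, with full provenance in a run summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cat, markers, preprocess, signatures
from .io import (
    CountMatrix,
    NormalizedMatrix,
    OrthologMap,
    read_counts,
    read_metadata,
    read_ortholog_map,
    read_signature_table,
    write_counts,
    write_json,
    write_metadata,
    write_ortholog_map,
    write_table,
)
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "PreprocessResult", "preprocess_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters and paths for one pipeline run.

    When ``simulate`` is set, inputs are generated with that
    configuration instead of being read from the count/metadata paths.
    """

    out_dir: str = "catmap_run"
    counts_a: str | None = None
    counts_b: str | None = None
    meta_a: str | None = None
    meta_b: str | None = None
    orthologs: str | None = None
    signatures_path: str | None = None
    signature_rank_col: str | None = None
    simulate: SimulationConfig | None = None
    alpha: float = 0.05
    L: int = 1000
    min_cpm: float = 1.0
    min_samples: int = 3
    hvg_top: int = 2000
    signature_top_n: int = 20
    df_method: str = "wald"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha", "L", "min_cpm", "min_samples", "hvg_top", "signature_top_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        return cfg


@dataclass
class PreprocessResult:
    """All normalization stages for both species, plus filter provenance."""

    vst_a: NormalizedMatrix
    vst_b: NormalizedMatrix
    regressed_a: NormalizedMatrix
    regressed_b: NormalizedMatrix
    qn_a: NormalizedMatrix
    qn_b: NormalizedMatrix
    hvg: pd.Index
    counts: dict[str, int] = field(default_factory=dict)


def preprocess_cohort(
    cm_a: CountMatrix,
    cm_b: CountMatrix,
    meta_a: pd.DataFrame,
    meta_b: pd.DataFrame,
    orthologs: OrthologMap,
    min_cpm: float = 1.0,
    min_samples: int = 3,
    hvg_top: int = 2000,
) -> PreprocessResult:
    """Run the full normalization chain on a paired cohort.

    Ortholog restriction re-keys both species to shared pair IDs; the
    CPM eligibility filter is applied per species and a gene must pass
    in *both* to stay in the cross-species compendium; VST and subject
    regression run per species; quantile normalization runs jointly
    over the combined sample set.
    """
    ra, rb = preprocess.restrict_to_orthologs(cm_a, cm_b, orthologs)
    n_restricted = ra.shape[0]
    keep = preprocess.cpm_filter(ra, min_cpm, min_samples).intersection(
        preprocess.cpm_filter(rb, min_cpm, min_samples)
    )
    ra = CountMatrix(counts=ra.counts.loc[keep], species=ra.species)
    rb = CountMatrix(counts=rb.counts.loc[keep], species=rb.species)
    vst_a = preprocess.vst(ra)
    vst_b = preprocess.vst(rb)
    reg_a = preprocess.regress_subject(vst_a, meta_a)
    reg_b = preprocess.regress_subject(vst_b, meta_b)
    qn_a, qn_b = preprocess.quantile_normalize(reg_a, reg_b)
    hvg = preprocess.select_hvg(vst_a, vst_b, n_top=hvg_top)
    return PreprocessResult(
        vst_a=vst_a, vst_b=vst_b, regressed_a=reg_a, regressed_b=reg_b,
        qn_a=qn_a, qn_b=qn_b, hvg=hvg,
        counts={
            "ortholog_pairs": len(orthologs),
            "genes_after_restriction": n_restricted,
            "genes_after_cpm_filter": len(keep),
            "samples_a": ra.shape[1],
            "samples_b": rb.shape[1],
            "hvg_shared": len(hvg),
            "fallback_genes_a": int(reg_a.fallback.sum()),
            "fallback_genes_b": int(reg_b.fallback.sum()),
        },
    )


def _write_stage(nm: NormalizedMatrix, path: Path) -> None:
    write_table(nm.values, path, index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write every intermediate table under
    ``config.out_dir``, and return (and write) the run summary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "alpha": config.alpha, "L": config.L, "min_cpm": config.min_cpm,
        "min_samples": config.min_samples, "hvg_top": config.hvg_top,
        "df_method": config.df_method, "seed": config.seed,
    }}

    # ------------------------------------------------------------------ inputs
    if config.simulate is not None:
        cm_a, meta_a, cm_b, meta_b, omap, truth = simulate_cohort(config.simulate)
        write_counts(cm_a, out / "counts_a.tsv")
        write_counts(cm_b, out / "counts_b.tsv")
        write_metadata(meta_a, out / "meta_a.tsv")
        write_metadata(meta_b, out / "meta_b.tsv")
        write_ortholog_map(omap, out / "orthologs.tsv")
        write_json(truth, out / "truth.json")
    else:
        for name in ("counts_a", "counts_b", "meta_a", "meta_b", "orthologs"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name} missing: {p}")
        cm_a = read_counts(config.counts_a, species="A")
        cm_b = read_counts(config.counts_b, species="B")
        meta_a = read_metadata(config.meta_a)
        meta_b = read_metadata(config.meta_b)
        omap = read_ortholog_map(config.orthologs)

    # -------------------------------------------------------------- preprocess
    prep = preprocess_cohort(
        cm_a, cm_b, meta_a, meta_b, omap,
        min_cpm=config.min_cpm, min_samples=config.min_samples, hvg_top=config.hvg_top,
    )
    for name, nm in (
        ("vst_a", prep.vst_a), ("vst_b", prep.vst_b),
        ("subject_regressed_a", prep.regressed_a), ("subject_regressed_b", prep.regressed_b),
        ("quantile_normalized_a", prep.qn_a), ("quantile_normalized_b", prep.qn_b),
    ):
        _write_stage(nm, out / f"{name}.tsv")
    flags = pd.DataFrame({
        "gene_id": prep.qn_a.gene_ids,
        "fallback_a": prep.regressed_a.fallback.to_numpy(),
        "fallback_b": prep.regressed_b.fallback.to_numpy(),
    })
    write_table(flags, out / "subject_regression_flags.tsv")
    write_table(prep.hvg.to_frame(index=False), out / "hvg_shared.tsv")
    summary["preprocess"] = prep.counts

    # ----------------------------------------------------------------- markers
    tables = {}
    for label, qn, vst_nm, meta in (
        ("a", prep.qn_a, prep.vst_a, meta_a),
        ("b", prep.qn_b, prep.vst_b, meta_b),
    ):
        table = markers.marker_scores(
            qn, meta, alpha=config.alpha, df_method=config.df_method, model_values=vst_nm,
        )
        tables[label] = table
        write_table(table, out / f"markers_{label}.tsv")
    summary["markers"] = {
        lab: {
            "rows": len(tbl),
            "eligible": int(tbl["eligible"].sum()),
            "subtypes": int(tbl["subtype"].nunique()),
        } for lab, tbl in tables.items()
    }

    # ---------------------------------------------------------------- homology
    lists_a = {
        s: markers.ranked_marker_list(tables["a"], s)
        for s in tables["a"]["subtype"].unique()
    }
    lists_b = {
        s: markers.ranked_marker_list(tables["b"], s)
        for s in tables["b"]["subtype"].unique()
    }
    lists_a = {s: lst for s, lst in lists_a.items() if lst}
    lists_b = {s: lst for s, lst in lists_b.items() if lst}
    result = cat.homology_analysis(lists_a, lists_b, L=config.L)
    write_table(result.curves, out / "cat_curves.tsv")
    write_table(result.mean_cat_ab, out / "mean_cat_ab.tsv", index=True)
    write_table(result.mean_cat_ba, out / "mean_cat_ba.tsv", index=True)
    write_table(result.scaled_ab, out / "mean_cat_ab_scaled.tsv", index=True)
    write_table(result.scaled_ba, out / "mean_cat_ba_scaled.tsv", index=True)
    write_json(
        {"a_to_b": result.assignment_ab, "b_to_a": result.assignment_ba},
        out / "assignment.json",
    )
    summary["homology"] = {
        "assignment_a_to_b": result.assignment_ab,
        "assignment_b_to_a": result.assignment_ba,
        "n_curves": int(result.curves.groupby(["reference", "candidate"]).ngroups),
    }

    # -------------------------------------------------------------- signatures
    if config.signatures_path is not None:
        sig_table = read_signature_table(config.signatures_path, rank_col=config.signature_rank_col)
        universe = set(prep.qn_a.gene_ids)
        sets = signatures.top_n_signature(sig_table, universe, n=config.signature_top_n)
        profile = signatures.signature_profile(prep.qn_a, meta_a, sets)
        write_table(profile, out / "signature_profile.tsv")
        summary["signatures"] = {c: len(g) for c, g in sets.items()}

    write_json(summary, out / "summary.json")
    return summary
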