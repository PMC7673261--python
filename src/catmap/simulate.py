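"""Synthetic paired two-species cohorts with known homology ground truth.

The generator emulates the design of a sorted-cell-population bulk
RNA-seq compendium: two species whose genes are 1:1 orthologs by
construction, a handful of cell subtypes per species with a few
replicate samples each, donors that each contribute samples to several
subtypes (so a random intercept per donor is estimable), negative-
binomial counts with gene-specific baselines and library-size
variation, and per-subtype planted marker programs. For each planted
cross-species homolog pair a fraction ``conservation`` of the marker
genes is the *same ortholog* in both species; the remainder are
species-private, so downstream rank-overlap recovery can be dialled
from impossible (0) to perfect (1).

Species baselines are drawn independently, so absolute expression
levels carry no cross-species signal — homology is only recoverable
through marker rank structure, as in real cross-species compendia.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, OrthologMap, ValidationError

__all__ = ["SimulationConfig", "simulate_cohort"]

BASELINE_LOG2_MEAN = 5.0
BASELINE_LOG2_SD = 1.5


@dataclass
class SimulationConfig:
    """Stated world for one simulated cohort.

    Defaults mirror a two-species sorted-population compendium: 15 and 9
    subtypes, 4 replicate samples each (within the 3-6 range of real
    cohorts), 5 donors per species each sorted into every subtype, a
    ~12k-gene ortholog space, 100 planted markers per subtype with a
    16-fold (2^4) elevation, moderate donor effects and NB dispersion.
    """

    n_genes: int = 12000
    n_subtypes_a: int = 15
    n_subtypes_b: int = 9
    homolog_pairs: list[tuple[str, str]] | None = None
    n_donors: int = 5
    samples_per_subtype: int = 4
    markers_per_subtype: int = 100
    conservation: float = 0.75
    marker_log2_effect: float = 4.0
    donor_sd: float = 0.3
    nb_dispersion: float = 0.05
    library_size_range: tuple[int, int] = (1_000_000, 3_000_000)
    species_a: str = "human"
    species_b: str = "mouse"
    seed: int = 0

    subtypes_a: list[str] = field(init=False)
    subtypes_b: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.conservation <= 1.0):
            raise ValidationError("conservation must lie in [0, 1]")
        if self.marker_log2_effect < 0 or self.donor_sd < 0 or self.nb_dispersion < 0:
            raise ValidationError("effect sizes, donor_sd and dispersion must be >= 0")
        self.subtypes_a = [f"A{i + 1:02d}" for i in range(self.n_subtypes_a)]
        self.subtypes_b = [f"B{i + 1:02d}" for i in range(self.n_subtypes_b)]
        if self.homolog_pairs is None:
            k = min(self.n_subtypes_a, self.n_subtypes_b)
            self.homolog_pairs = list(zip(self.subtypes_a[:k], self.subtypes_b[:k]))
        self.homolog_pairs = [tuple(p) for p in self.homolog_pairs]
        for ta, tb in self.homolog_pairs:
            if ta not in self.subtypes_a or tb not in self.subtypes_b:
                raise ValidationError(f"homolog pair ({ta}, {tb}) names unknown subtypes")

    @property
    def n_conserved(self) -> int:
        return int(round(self.conservation * self.markers_per_subtype))


def _allocate_markers(cfg: SimulationConfig, rng: np.random.Generator):
    """Disjoint marker gene blocks: conserved per homolog pair, then
    species-private per subtype. All blocks are globally disjoint so no
    spurious cross-species marker sharing is planted."""
    paired_a = {ta for ta, _ in cfg.homolog_pairs}
    paired_b = {tb for _, tb in cfg.homolog_pairs}
    n_cons = cfg.n_conserved
    need = len(cfg.homolog_pairs) * n_cons
    need += sum(
        cfg.markers_per_subtype - (n_cons if t in paired_a else 0) for t in cfg.subtypes_a
    )
    need += sum(
        cfg.markers_per_subtype - (n_cons if t in paired_b else 0) for t in cfg.subtypes_b
    )
    if need > cfg.n_genes:
        raise ValidationError(
            f"marker allocation needs {need} genes but n_genes={cfg.n_genes}"
        )
    perm = rng.permutation(cfg.n_genes)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        block = perm[cursor:cursor + k]
        cursor += k
        return block

    markers_a = {t: np.array([], dtype=int) for t in cfg.subtypes_a}
    markers_b = {t: np.array([], dtype=int) for t in cfg.subtypes_b}
    conserved = {}
    for ta, tb in cfg.homolog_pairs:
        block = take(n_cons)
        conserved[(ta, tb)] = block
        markers_a[ta] = np.concatenate([markers_a[ta], block])
        markers_b[tb] = np.concatenate([markers_b[tb], block])
    for t in cfg.subtypes_a:
        extra = cfg.markers_per_subtype - len(markers_a[t])
        markers_a[t] = np.sort(np.concatenate([markers_a[t], take(extra)]))
    for t in cfg.subtypes_b:
        extra = cfg.markers_per_subtype - len(markers_b[t])
        markers_b[t] = np.sort(np.concatenate([markers_b[t], take(extra)]))
    conserved = {k: np.sort(v) for k, v in conserved.items()}
    return markers_a, markers_b, conserved


def _simulate_species(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    species: str,
    subtypes: list[str],
    markers: dict[str, np.ndarray],
    gene_ids: list[str],
):
    n_genes = cfg.n_genes
    baseline = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=n_genes)
    # expected within-subtype proportions: baseline plus planted elevation
    log2_mean = np.tile(baseline[:, None], (1, len(subtypes)))
    for j, t in enumerate(subtypes):
        log2_mean[markers[t], j] += cfg.marker_log2_effect
    rel = np.exp2(log2_mean)
    props = rel / rel.sum(axis=0, keepdims=True)

    donor_offsets = rng.normal(0.0, cfg.donor_sd, size=cfg.n_donors)
    sample_ids, meta_rows, mean_cols = [], [], []
    for j, t in enumerate(subtypes):
        for r in range(cfg.samples_per_subtype):
            donor = r % cfg.n_donors
            sid = f"{species}_{t}_s{r + 1}"
            libsize = rng.integers(cfg.library_size_range[0], cfg.library_size_range[1] + 1)
            mean_cols.append(libsize * props[:, j] * np.exp2(donor_offsets[donor]))
            sample_ids.append(sid)
            meta_rows.append({
                "sample_id": sid, "species": species, "tissue": "blood",
                "subtype": t, "subject_id": f"{species}_d{donor + 1}",
            })
    mu = np.column_stack(mean_cols)
    if cfg.nb_dispersion > 0:
        size = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids),
        species=species,
    )
    return cm, pd.DataFrame(meta_rows)


def simulate_cohort(cfg: SimulationConfig):
    """Generate one paired cohort.

    Returns ``(cm_a, meta_a, cm_b, meta_b, ortholog_map, truth)``.
    ``truth`` records the planted marker genes (as ortholog-pair IDs)
    per species and subtype, the conserved markers per homolog pair,
    the homolog pairs themselves, and the configuration. The same
    config and seed always reproduce identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    genes_a = [f"gA{i + 1:05d}" for i in range(cfg.n_genes)]
    genes_b = [f"gB{i + 1:05d}" for i in range(cfg.n_genes)]
    pair_ids = [f"{a}|{b}" for a, b in zip(genes_a, genes_b)]
    markers_a, markers_b, conserved = _allocate_markers(cfg, rng)
    cm_a, meta_a = _simulate_species(cfg, rng, cfg.species_a, cfg.subtypes_a, markers_a, genes_a)
    cm_b, meta_b = _simulate_species(cfg, rng, cfg.species_b, cfg.subtypes_b, markers_b, genes_b)
    omap = OrthologMap(pairs=pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b}))
    truth = {
        "homolog_pairs": [list(p) for p in cfg.homolog_pairs],
        "markers": {
            cfg.species_a: {t: [pair_ids[i] for i in idx] for t, idx in markers_a.items()},
            cfg.species_b: {t: [pair_ids[i] for i in idx] for t, idx in markers_b.items()},
        },
        "conserved_markers": {
            f"{ta}|{tb}": [pair_ids[i] for i in idx] for (ta, tb), idx in conserved.items()
        },
        "config": {k: v for k, v in asdict(cfg).items()},
    }
    return cm_a, meta_a, cm_b, meta_b, omap, truth
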