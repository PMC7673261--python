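import numpy as np
import pandas as pd
import pytest

import catmap


@pytest.fixture(scope="session")
def recovery_cohort():
    """Small strong-effect cohort with perfectly conserved markers.

    5 subtypes per species, 3 planted homolog pairs, 20 markers each at
    a 16-fold elevation: enough signal for parameter-recovery tests
    while staying fast. Returns the simulated inputs, preprocessing
    result, both marker tables and the truth record.
    """
    cfg = catmap.SimulationConfig(
        n_genes=600,
        n_subtypes_a=5,
        n_subtypes_b=5,
        homolog_pairs=[("A01", "B01"), ("A02", "B02"), ("A03", "B03")],
        n_donors=4,
        samples_per_subtype=4,
        markers_per_subtype=20,
        conservation=1.0,
        marker_log2_effect=4.0,
        donor_sd=0.3,
        nb_dispersion=0.05,
        seed=20240911,
    )
    cm_a, meta_a, cm_b, meta_b, omap, truth = catmap.simulate_cohort(cfg)
    prep = catmap.preprocess_cohort(cm_a, cm_b, meta_a, meta_b, omap, hvg_top=100)
    table_a = catmap.marker_scores(prep.qn_a, meta_a, model_values=prep.vst_a)
    table_b = catmap.marker_scores(prep.qn_b, meta_b, model_values=prep.vst_b)
    return {
        "config": cfg,
        "cm_a": cm_a, "meta_a": meta_a, "cm_b": cm_b, "meta_b": meta_b,
        "orthologs": omap, "truth": truth, "prep": prep,
        "markers_a": table_a, "markers_b": table_b,
    }


@pytest.fixture()
def toy_normalized():
    """6 samples in 3 subtypes of 2, two donors, hand-checkable values."""
    values = pd.DataFrame(
        {
            "s1": [4.0, 0.0, 1.0],
            "s2": [6.0, 0.0, 1.0],
            "s3": [1.0, 0.0, 1.0],
            "s4": [2.0, 0.0, 1.0],
            "s5": [0.0, 0.0, 1.0],
            "s6": [1.0, 0.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(1, 7)],
        "species": "human",
        "tissue": "blood",
        "subtype": ["t1", "t1", "t2", "t2", "t3", "t3"],
        "subject_id": ["d1", "d2", "d1", "d2", "d1", "d2"],
    })
    nm = catmap.NormalizedMatrix(values=values, stage="quantile_normalized")
    return nm, meta


def make_meta(sample_ids, subtypes, subjects, species="human"):
    return pd.DataFrame({
        "sample_id": sample_ids,
        "species": species,
        "tissue": "blood",
        "subtype": subtypes,
        "subject_id": subjects,
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
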