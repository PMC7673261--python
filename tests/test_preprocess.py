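import numpy as np
import pandas as pd
import pytest

import catmap
from catmap.io import CountMatrix, NormalizedMatrix, OrthologMap, ValidationError
from catmap.preprocess import (
    cpm_filter,
    median_of_ratios_size_factors,
    quantile_normalize,
    regress_subject,
    restrict_to_orthologs,
    select_hvg,
    vst,
)
from conftest import make_meta


def _cm(mat, genes, samples, species="human"):
    return CountMatrix(
        counts=pd.DataFrame(mat, index=genes, columns=samples), species=species
    )


class TestRestrict:
    def test_full_map_keeps_shapes_and_aligns_order(self):
        cm_a = _cm([[1, 2], [3, 4]], ["a1", "a2"], ["s1", "s2"])
        cm_b = _cm([[5, 6], [7, 8]], ["b2", "b1"], ["t1", "t2"])
        omap = OrthologMap(pairs=pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]}))
        ra, rb = restrict_to_orthologs(cm_a, cm_b, omap)
        assert ra.gene_ids == rb.gene_ids == ["a1|b1", "a2|b2"]
        assert rb.counts.loc["a1|b1"].tolist() == [7, 8]

    def test_partial_map_drops_missing(self):
        cm_a = _cm(np.arange(10).reshape(5, 2), [f"a{i}" for i in range(5)], ["s1", "s2"])
        cm_b = _cm(np.arange(10).reshape(5, 2), [f"b{i}" for i in range(5)], ["t1", "t2"])
        omap = OrthologMap(pairs=pd.DataFrame({"gene_a": ["a0", "a3"], "gene_b": ["b1", "b4"]}))
        ra, rb = restrict_to_orthologs(cm_a, cm_b, omap)
        assert ra.shape[0] == rb.shape[0] == 2

    def test_empty_intersection_is_error(self):
        cm_a = _cm([[1]], ["a1"], ["s1"])
        cm_b = _cm([[1]], ["b1"], ["t1"])
        omap = OrthologMap(pairs=pd.DataFrame({"gene_a": ["aX"], "gene_b": ["bX"]}))
        with pytest.raises(ValidationError):
            restrict_to_orthologs(cm_a, cm_b, omap)

    def test_simulated_cohort_matches_truth_pair_count(self, recovery_cohort):
        ra, _ = restrict_to_orthologs(
            recovery_cohort["cm_a"], recovery_cohort["cm_b"], recovery_cohort["orthologs"]
        )
        assert ra.shape[0] == len(recovery_cohort["orthologs"])


class TestCpmFilter:
    def test_spec_examples(self):
        # libsizes ~1e6; a gene needs CPM > 1 in at least 3 samples
        n = 6
        base = np.ones((4, n), dtype=int) * 250_000
        base[1] = [2, 2, 2, 0, 0, 0]
        base[2] = [2, 2, 0, 0, 0, 0]
        base[3] = 0
        cm = _cm(base, ["g_house", "g_keep", "g_drop", "g_zero"], [f"s{i}" for i in range(n)])
        kept = cpm_filter(cm, min_cpm=1.0, min_samples=3)
        assert "g_keep" in kept and "g_house" in kept
        assert "g_drop" not in kept and "g_zero" not in kept

    def test_zero_library_size_names_sample(self):
        cm = _cm([[0], [0]], ["g1", "g2"], ["bad_sample"])
        with pytest.raises(ValidationError, match="bad_sample"):
            cpm_filter(cm)


class TestVst:
    def test_zero_count_maps_to_zero_and_identical_columns_match(self):
        cm = _cm([[0, 0], [10, 10], [4, 4]], ["g1", "g2", "g3"], ["s1", "s2"])
        nm = vst(cm)
        assert nm.stage == "vst"
        assert nm.values.loc["g1"].tolist() == [0.0, 0.0]
        assert (nm.values["s1"] == nm.values["s2"]).all()

    def test_doubling_a_sample_is_absorbed_by_size_factors(self, rng):
        # doubling every count of one sample doubles the depth it shares
        # with the reference: its size factor grows by 2^((n-1)/n) and all
        # others shrink by 2^(-1/n), so the normalized matrix changes only
        # by one global factor 2^(1/n) — between-sample structure intact
        counts = rng.poisson(100, size=(50, 4)) + 1
        cm = _cm(counts, [f"g{i}" for i in range(50)], list("abcd"))
        doubled = counts.copy()
        doubled[:, 2] *= 2
        cm2 = _cm(doubled, [f"g{i}" for i in range(50)], list("abcd"))
        sf1 = median_of_ratios_size_factors(cm.counts)
        sf2 = median_of_ratios_size_factors(cm2.counts)
        np.testing.assert_allclose(sf2["c"] / sf1["c"], 2 ** (3 / 4), rtol=1e-12)
        norm1 = counts / sf1.to_numpy()
        norm2 = doubled / sf2.to_numpy()
        np.testing.assert_allclose(norm2, norm1 * 2 ** (1 / 4), rtol=1e-12)

    def test_size_factor_direct_formula(self):
        counts = pd.DataFrame([[4, 16], [1, 4], [9, 36]], index=list("xyz"), columns=["s1", "s2"])
        sf = median_of_ratios_size_factors(counts)
        # reference = geometric means (8, 2, 18); ratios are 0.5 and 2 for every gene
        np.testing.assert_allclose(sf.to_numpy(), [0.5, 2.0])

    def test_fallback_to_library_size_factors_warns(self):
        counts = pd.DataFrame([[0, 5], [3, 0]], index=["g1", "g2"], columns=["s1", "s2"])
        with pytest.warns(UserWarning, match="library-size"):
            sf = median_of_ratios_size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [3 / 4, 5 / 4])


class TestRegressSubject:
    def test_one_sample_per_subject_returns_input_flagged(self, rng):
        vals = pd.DataFrame(rng.normal(size=(3, 4)), index=list("abc"),
                            columns=[f"s{i}" for i in range(4)])
        nm = NormalizedMatrix(values=vals, stage="vst", species="human")
        meta = make_meta([f"s{i}" for i in range(4)], ["t1", "t1", "t2", "t2"],
                         [f"d{i}" for i in range(4)])
        out = regress_subject(nm, meta)
        assert out.stage == "subject_regressed"
        assert out.fallback.all()
        pd.testing.assert_frame_equal(out.values, vals)

    def test_constant_gene_unchanged_and_flagged(self, rng):
        samples = [f"s{i}" for i in range(8)]
        vals = pd.DataFrame(
            np.vstack([np.full(8, 3.0), rng.normal(size=8) + np.repeat([0.0, 5.0], 4)]),
            index=["flat", "vary"], columns=samples,
        )
        nm = NormalizedMatrix(values=vals, stage="vst")
        meta = make_meta(samples, ["t1"] * 4 + ["t2"] * 4, ["d1", "d2"] * 4)
        out = regress_subject(nm, meta)
        assert bool(out.fallback["flat"])
        assert (out.values.loc["flat"] == 3.0).all()

    def test_centering_oracle_on_strong_donor_effects(self, rng):
        n_donors, reps = 10, 6
        samples = [f"s{i}" for i in range(n_donors * reps)]
        donors = np.repeat([f"d{i}" for i in range(n_donors)], reps)
        offsets = np.repeat(rng.normal(0, 1.0, n_donors), reps)
        mat = np.stack([5.0 + offsets + rng.normal(0, 0.1, len(samples)) for _ in range(5)])
        nm = NormalizedMatrix(values=pd.DataFrame(mat, index=[f"g{i}" for i in range(5)],
                                                  columns=samples), stage="vst")
        meta = make_meta(samples, ["t1"] * len(samples), donors)
        out = regress_subject(nm, meta)
        assert not out.fallback.any()
        for g in out.values.index:
            y = nm.values.loc[g].to_numpy()
            centered = y - pd.Series(y).groupby(donors).transform("mean").to_numpy() + y.mean()
            rmse = np.sqrt(np.mean((out.values.loc[g].to_numpy() - centered) ** 2))
            assert rmse < 0.05

    def test_species_mixed_input_rejected(self, rng):
        samples = ["s1", "s2"]
        vals = pd.DataFrame(rng.normal(size=(2, 2)), index=["g1", "g2"], columns=samples)
        nm = NormalizedMatrix(values=vals, stage="vst")
        meta = make_meta(samples, ["t1", "t2"], ["d1", "d2"])
        meta.loc[1, "species"] = "mouse"
        with pytest.raises(ValidationError, match="per species"):
            regress_subject(nm, meta)


def _nm_pair(mat_a, mat_b, genes):
    samples_a = [f"sa{i}" for i in range(np.asarray(mat_a).shape[1])]
    samples_b = [f"sb{i}" for i in range(np.asarray(mat_b).shape[1])]
    return (
        NormalizedMatrix(values=pd.DataFrame(mat_a, index=genes, columns=samples_a),
                         stage="subject_regressed"),
        NormalizedMatrix(values=pd.DataFrame(mat_b, index=genes, columns=samples_b),
                         stage="subject_regressed"),
    )


class TestQuantileNormalize:
    def test_hand_computed_two_sample_case(self):
        nm_a, nm_b = _nm_pair([[1.0], [2.0], [3.0]], [[4.0], [5.0], [6.0]], list("xyz"))
        qa, qb = quantile_normalize(nm_a, nm_b)
        np.testing.assert_allclose(qa.values.iloc[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(qb.values.iloc[:, 0], [2.5, 3.5, 4.5])

    def test_permuted_identical_multisets_only_permute(self, rng):
        base = rng.normal(size=12)
        cols = np.stack([rng.permutation(base) for _ in range(5)], axis=1)
        nm_a, nm_b = _nm_pair(cols[:, :3], cols[:, 3:], [f"g{i}" for i in range(12)])
        qa, qb = quantile_normalize(nm_a, nm_b)
        np.testing.assert_allclose(qa.values.to_numpy(), cols[:, :3])
        np.testing.assert_allclose(qb.values.to_numpy(), cols[:, 3:])

    def test_all_samples_share_sorted_vector_and_ranks_survive(self, rng):
        mat = rng.normal(size=(40, 9))  # continuous, tie-free
        nm_a, nm_b = _nm_pair(mat[:, :4], mat[:, 4:], [f"g{i}" for i in range(40)])
        qa, qb = quantile_normalize(nm_a, nm_b)
        out = np.hstack([qa.values.to_numpy(), qb.values.to_numpy()])
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
            # within-sample order preserved up to ties
            src = mat[:, j]
            order = np.argsort(src, kind="stable")
            assert np.all(np.diff(out[order, j]) >= -1e-12)

    def test_tied_values_get_mean_of_spanned_reference(self):
        nm_a, nm_b = _nm_pair([[1.0], [1.0], [5.0]], [[10.0], [20.0], [30.0]], list("xyz"))
        qa, _ = quantile_normalize(nm_a, nm_b)
        ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])
        np.testing.assert_allclose(
            qa.values.iloc[:, 0], [ref[:2].mean(), ref[:2].mean(), ref[2]]
        )

    def test_row_misalignment_rejected(self, rng):
        nm_a, nm_b = _nm_pair(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)), list("xyz"))
        nm_b.values.index = list("xzy")
        with pytest.raises(ValidationError, match="row-aligned"):
            quantile_normalize(nm_a, nm_b)


class TestSelectHvg:
    def test_identical_matrices_give_top_set(self, rng):
        mat = rng.normal(size=(30, 6)) * np.linspace(0.1, 3.0, 30)[:, None]
        nm_a, nm_b = _nm_pair(mat, mat.copy(), [f"g{i}" for i in range(30)])
        hvg = select_hvg(nm_a, nm_b, n_top=5)
        var = mat.var(axis=1, ddof=1)
        expected = {f"g{i}" for i in np.argsort(-var)[:5]}
        assert set(hvg) == expected

    def test_disjoint_top_sets_warn_empty(self):
        mat_a = np.zeros((4, 4))
        mat_a[0] = [0, 9, 0, 9]
        mat_b = np.zeros((4, 4))
        mat_b[3] = [0, 9, 0, 9]
        nm_a, nm_b = _nm_pair(mat_a, mat_b, list("wxyz"))
        with pytest.warns(UserWarning, match="no highly variable"):
            hvg = select_hvg(nm_a, nm_b, n_top=1)
        assert len(hvg) == 0

    def test_n_top_above_gene_count_warns_and_uses_all(self, rng):
        mat = rng.normal(size=(5, 4))
        nm_a, nm_b = _nm_pair(mat, mat, list("abcde"))
        with pytest.warns(UserWarning, match="exceeds gene count"):
            hvg = select_hvg(nm_a, nm_b, n_top=50)
        assert len(hvg) == 5

    def test_planted_marker_recall(self, recovery_cohort):
        # planted markers dominate cross-subtype variance at strong effect
        prep = recovery_cohort["prep"]
        truth = recovery_cohort["truth"]
        cfg = recovery_cohort["config"]
        planted = {g for sub in truth["markers"][cfg.species_a].values() for g in sub}
        hvg = select_hvg(prep.vst_a, prep.vst_a, n_top=len(planted))
        recall = len(planted & set(hvg)) / len(planted)
        assert recall >= 0.9
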