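"""Normalization, k-means phenotypes, PCA, phases, Ward cross-check."""

import numpy as np
import pandas as pd
import pytest

import emstem as es
from emstem.clustering import (
    NormalizationError,
    PHENOTYPE_ORDER,
    corner_geometry,
    label_agreement,
    phase_label,
)

CORE = list(es.CORE_NODES)


def _blob_table(seed=0, n_per=120, sep=20.0, sd=1.0):
    """Four well-separated synthetic blobs at pairwise distance >= sep*sd,
    placed so median-ZEB ordering is unambiguous."""
    rng = np.random.default_rng(seed)
    centers = np.array([
        # miR200, ZEB, LIN28, let7
        [sep, -1.5 * sep, -sep, sep],     # e
        [sep, -0.5 * sep, sep, -sep],     # he
        [-sep, 0.5 * sep, -sep, -sep],    # hm
        [-sep, 1.5 * sep, sep, sep],      # m
    ]) * sd
    rows, truth = [], []
    for name, c in zip(PHENOTYPE_ORDER, centers):
        pts = rng.normal(c, sd, size=(n_per, 4))
        rows.append(pts)
        truth += [name] * n_per
    X = np.vstack(rows)
    tbl = pd.DataFrame(X, columns=CORE)
    tbl.insert(0, "replicate", 0)
    tbl.insert(1, "param_set", range(len(tbl)))
    tbl.insert(2, "n_states", 1)
    return tbl, np.array(truth)


class TestNormalize:
    def test_reference_geometric_mean_maps_to_zero(self):
        rng = np.random.default_rng(1)
        ref = pd.DataFrame({"A": np.exp(rng.normal(2.0, 0.7, 500))})
        stats = es.reference_stats(ref, ["A"])
        gm = 2 ** stats.loc["A", "mean"]
        sol = pd.DataFrame({"A": [gm, gm * 2 ** stats.loc["A", "sd"]]})
        z = es.normalize(sol, stats, ["A"])
        assert z["A"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert z["A"].iloc[1] == pytest.approx(1.0, abs=1e-12)

    def test_self_normalization_is_standard(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame({n: np.exp(rng.normal(1.0, 0.5, 400)) for n in CORE})
        z = es.normalize(raw, raw, CORE)
        for n in CORE:
            assert abs(z[n].mean()) < 1e-6
            assert abs(np.std(z[n]) - 1) < 1e-6

    def test_external_reference_used_not_self(self):
        """A perturbed table is scored on the reference scale, not its own."""
        ref = pd.DataFrame({"A": [1.0, 2.0, 4.0, 8.0]})
        pert = pd.DataFrame({"A": [16.0, 32.0]})
        z = es.normalize(pert, ref, ["A"])
        assert (z["A"] > 1.5).all()  # far above the reference mean

    def test_zero_variance_names_node(self):
        ref = pd.DataFrame({"A": [2.0, 2.0, 2.0], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(NormalizationError, match="'A'"):
            es.reference_stats(ref, ["A", "B"])


class TestKmeansPhenotypes:
    def test_blobs_perfectly_recovered(self):
        tbl, truth = _blob_table()
        assign = es.kmeans_phenotypes(tbl, k=4, restarts=10, seed=0)
        assert (assign.labels.to_numpy() == truth).all()

    def test_labels_ordered_by_median_zeb(self):
        tbl, _ = _blob_table(seed=3)
        assign = es.kmeans_phenotypes(tbl, k=4, seed=1)
        medians = [tbl.loc[(assign.labels == c).to_numpy(), "ZEB"].median()
                   for c in PHENOTYPE_ORDER]
        assert medians == sorted(medians)

    def test_deterministic(self):
        tbl, _ = _blob_table(seed=4)
        a1 = es.kmeans_phenotypes(tbl, k=4, seed=7)
        a2 = es.kmeans_phenotypes(tbl, k=4, seed=7)
        assert (a1.labels == a2.labels).all()

    def test_label_order_invariant_to_row_permutation(self):
        tbl, truth = _blob_table(seed=5)
        perm = np.random.default_rng(0).permutation(len(tbl))
        shuffled = tbl.iloc[perm].reset_index(drop=True)
        a = es.kmeans_phenotypes(shuffled, k=4, seed=0)
        assert (a.labels.to_numpy() == truth[perm]).all()

    def test_k_exceeding_rows_raises(self):
        tbl, _ = _blob_table(n_per=1)
        with pytest.raises(ValueError):
            es.kmeans_phenotypes(tbl, k=10)


class TestQualitySweep:
    def test_metrics_on_blobs(self):
        tbl, _ = _blob_table()
        q = es.cluster_quality_sweep(tbl, k_range=range(2, 7), restarts=5, seed=0)
        assert q["inertia"].is_monotonic_decreasing
        assert ((q["silhouette"] >= -1) & (q["silhouette"] <= 1)).all()
        assert q["silhouette"].idxmax() == 4  # blobs are 4 true clusters


class TestPCA:
    def test_one_dimensional_data(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=6)
        X = np.outer(rng.normal(size=300), direction)
        tbl = pd.DataFrame(X, columns=list(es.BASE_NODES))
        pca = es.pca_summary(tbl)
        assert pca.pc1_fraction == pytest.approx(1.0)

    def test_orthonormal_loadings_and_orientation(self):
        rng = np.random.default_rng(1)
        tbl = pd.DataFrame(rng.normal(size=(500, 6)), columns=list(es.BASE_NODES))
        pca = es.pca_summary(tbl)
        L = pca.loadings.to_numpy()
        np.testing.assert_allclose(L @ L.T, np.eye(6), atol=1e-8)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert pca.loadings.loc["PC1", "ZEB"] <= 0


class TestPhases:
    def test_phase_label_canonical_order(self):
        assert phase_label(["m", "e"]) == "{e,m}"
        assert phase_label(["hm", "he", "e"]) == "{e,he,hm}"
        assert phase_label(["e", "e"]) == "{e,e}"

    def test_toy_phase_frequencies(self):
        tbl = pd.DataFrame({
            "replicate": 0,
            "param_set": [0, 1, 1, 2, 2],
            "n_states": [1, 2, 2, 2, 2],
            "phenotype": ["e", "e", "m", "e", "m"],
        })
        freq = es.label_phases(tbl)
        bist = freq[freq["stability"] == "bistable"]
        assert bist["frequency"].sum() == pytest.approx(1.0)
        assert bist.set_index("phase")["frequency"]["{e,m}"] == pytest.approx(1.0)

    def test_incomplete_parameter_set_raises(self):
        tbl = pd.DataFrame({
            "replicate": 0, "param_set": [0], "n_states": [2], "phenotype": ["e"],
        })
        with pytest.raises(ValueError, match="missing"):
            es.label_phases(tbl)

    def test_unlabeled_solution_raises(self):
        tbl = pd.DataFrame({
            "replicate": 0, "param_set": [0], "n_states": [1], "phenotype": [None],
        })
        with pytest.raises(ValueError):
            es.label_phases(tbl)


class TestWard:
    def test_blobs_recovered_and_agreeing_with_kmeans(self):
        tbl, truth = _blob_table()
        ward = es.ward_dendrogram(tbl, max_rows=10_000, seed=0)
        assert label_agreement(ward.four_group_labels, truth) == pytest.approx(1.0)
        km = es.kmeans_phenotypes(tbl, k=4, seed=0)
        assert label_agreement(ward.four_group_labels, km.labels.to_numpy()) > 0.8

    def test_duplicated_points_merge_at_zero_height(self):
        tbl = pd.DataFrame(np.ones((6, 4)), columns=CORE)
        ward = es.ward_dendrogram(tbl)
        assert np.allclose(ward.linkage[:, 2], 0.0)


class TestCornerGeometry:
    def test_perfect_rectangle_has_zero_misfit(self):
        centers = pd.DataFrame(
            {"ZEB": [-1, -1, 1, 1], "LIN28": [-1, 1, -1, 1]},
            index=pd.Index(["e", "he", "hm", "m"], name="phenotype"),
        )
        geom = corner_geometry(centers)
        assert geom["misfit"].dropna().max() == pytest.approx(0.0)

    def test_requires_distinct_quadrants(self):
        centers = pd.DataFrame(
            {"ZEB": [-1, -1, -1, 1], "LIN28": [-1, -1.2, -0.8, 1]},
            index=pd.Index(list("abcd"), name="phenotype"),
        )
        with pytest.raises(ValueError):
            corner_geometry(centers)
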