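"""QC filtering, germ selection, scaling, clustering and annotation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nestkin.simulate import ContinuumSimConfig, simulate_counts
from nestkin.transcriptome import (
    LibraryFilterSpec,
    ResolutionSelectionError,
    annotate_clusters,
    cluster_graph,
    cluster_overlap,
    marker_stats,
    modified_rv,
    normalize_log,
    passes_marker_criteria,
    qc_filter,
    qc_metrics,
    read_counts_mtx,
    select_germ_cells,
    select_resolution,
    variable_genes,
    write_counts_mtx,
    zscore_genes,
)


def make_adata(counts, genes=None, library="lib1"):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    obs = pd.DataFrame({"library": library}, index=[f"c{i}" for i in range(len(counts))])
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class TestQCFilter:
    def test_printed_style_gene_threshold_keeps_three_of_five(self):
        # Cells detect 1200/1400/2000/900/1350 genes; ">1300 genes" keeps 3.
        n_genes_per_cell = [1200, 1400, 2000, 900, 1350]
        counts = np.zeros((5, 2000), dtype=int)
        for i, n in enumerate(n_genes_per_cell):
            counts[i, :n] = 1
        adata = make_adata(counts)
        filtered, report = qc_filter(adata, {"lib1": LibraryFilterSpec(
            min_genes=1300, max_mito_fraction=None)})
        assert filtered.n_obs == 3
        assert report.loc[0, "n_pass"] == 3 and report.loc[0, "n_fail"] == 2

    def test_mito_boundary_is_strict(self):
        genes = ["mt-Nd1", "Actb", "Gapdh", "Dazl"]
        counts = np.array([[25, 25, 25, 25],   # exactly 0.25 -> fails
                           [24, 26, 25, 25]])  # 0.24 -> passes
        adata = make_adata(counts, genes=genes)
        filtered, _ = qc_filter(adata, {"lib1": LibraryFilterSpec()})
        assert list(filtered.obs_names) == ["c1"]

    def test_unknown_library_rejected(self):
        adata = make_adata(np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError, match="lib1"):
            qc_filter(adata, {"other": LibraryFilterSpec()})

    def test_agrees_with_per_cell_brute_force(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            counts = rng.integers(0, 5, size=(30, 25))
            genes = [f"mt-g{i}" if i < 3 else f"g{i}" for i in range(25)]
            adata = make_adata(counts, genes=genes)
            spec = LibraryFilterSpec(
                min_genes=int(rng.integers(5, 15)),
                max_umi=int(rng.integers(30, 80)),
                max_mito_fraction=float(rng.uniform(0.1, 0.4)),
            )
            filtered, _ = qc_filter(adata, {"lib1": spec})
            expected = []
            for i in range(30):
                row = counts[i]
                n_genes = int((row > 0).sum())
                total = int(row.sum())
                mito = row[:3].sum() / total if total else 0.0
                if (n_genes > spec.min_genes and total < spec.max_umi
                        and mito < spec.max_mito_fraction):
                    expected.append(f"c{i}")
            assert list(filtered.obs_names) == expected

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            LibraryFilterSpec(min_genes=2000, max_genes=1000)


class TestGermSelection:
    def test_marker_count_threshold(self):
        counts = np.array([[0, 0, 9], [2, 0, 0], [0, 3, 0]])
        adata = make_adata(counts, genes=["Dazl", "Ddx4", "Actb"])
        kept = select_germ_cells(adata, min_count=1)
        assert list(kept.obs_names) == ["c1", "c2"]

    def test_zero_threshold_is_identity(self):
        adata = make_adata(np.zeros((3, 3), dtype=int), genes=["Dazl", "Ddx4", "x"])
        assert select_germ_cells(adata, min_count=0).n_obs == 3

    def test_missing_markers_listed(self):
        adata = make_adata(np.ones((2, 2), dtype=int), genes=["a", "b"])
        with pytest.raises(ValueError, match="Dazl"):
            select_germ_cells(adata)

    def test_soma_without_markers_fully_separated(self):
        config = ContinuumSimConfig(n_cells={"P6": 400}, soma_fraction=0.1)
        adata = simulate_counts(config, 1)
        kept = select_germ_cells(adata)
        truth_germ = set(adata.obs_names[adata.obs["is_germ"]])
        assert set(kept.obs_names) <= truth_germ  # precision 1: no soma kept
        # Recall: germ cells express Dazl/Ddx4 highly, so essentially all kept.
        assert len(kept) >= 0.99 * len(truth_germ)


class TestNormalizeScale:
    def test_normalized_columns_sum_to_scale_factor(self):
        adata = make_adata(np.random.default_rng(0).integers(0, 20, (10, 8)))
        norm = normalize_log(adata, scale_factor=1e4)
        sums = np.asarray(norm.layers["normalized_linear"].sum(axis=1)).ravel()
        assert sums == pytest.approx(np.full(10, 1e4))

    def test_single_cell_with_own_library_size_gives_log1p_counts(self):
        counts = np.array([[3, 7, 0]])
        adata = make_adata(counts)
        norm = normalize_log(adata, scale_factor=10)
        np.testing.assert_allclose(np.asarray(norm.X.todense()),
                                   np.log1p(counts), rtol=1e-6)

    def test_constant_gene_scaled_to_zeros_and_flagged(self):
        # Equal library sizes keep the first gene constant after
        # normalisation; it must be flagged and zeroed, not NaN.
        counts = np.array([[5, 1, 4], [5, 3, 2], [5, 5, 0]])
        scaled = zscore_genes(normalize_log(make_adata(counts)))
        assert scaled.var["zero_variance"].tolist() == [True, False, False]
        np.testing.assert_allclose(scaled.X[:, 0], 0.0)
        assert scaled.X[:, 1].mean() == pytest.approx(0.0, abs=1e-12)
        assert scaled.X[:, 1].std() == pytest.approx(1.0)


class TestVariableGenes:
    def test_uniform_dispersion_selects_nothing(self):
        rng = np.random.default_rng(0)
        perm = rng.permutation(24)
        counts = np.tile(np.arange(1, 25)[perm], (30, 1))
        adata = make_adata(counts)
        adata.X = sp.csr_matrix(counts.astype(float))
        assert variable_genes(adata, n_bins=4, z_cutoff=0.5) == []

    def test_inflated_dispersion_gene_selected(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5, size=(200, 30)).astype(float)
        base[:, 7] = rng.poisson(5, 200) * rng.integers(0, 2, 200) * 4
        adata = make_adata(base.astype(int))
        adata.X = sp.csr_matrix(base)
        selected = variable_genes(adata, n_bins=5, z_cutoff=1.0)
        assert "g7" in selected

    def test_selection_invariant_to_gene_order(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(5, 0.3, size=(100, 40))
        adata = make_adata(counts)
        perm = rng.permutation(40)
        adata_p = make_adata(counts[:, perm], genes=[f"g{i}" for i in perm])
        assert set(variable_genes(adata, 5, 1.0)) == set(variable_genes(adata_p, 5, 1.0))

    def test_fewer_genes_than_bins_rejected(self):
        adata = make_adata(np.ones((5, 3), dtype=int))
        with pytest.raises(ValueError):
            variable_genes(adata, n_bins=10)


def two_blob_adata(n=200, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n // 2, 30))
    b = rng.normal(6, 1, (n // 2, 30))
    X = np.vstack([a, b])
    obs = pd.DataFrame({"truth": ["a"] * (n // 2) + ["b"] * (n // 2)},
                       index=[f"c{i}" for i in range(n)])
    return ad.AnnData(X=X, obs=obs)


class TestClustering:
    def test_two_separated_blobs_fully_recovered(self):
        adata = two_blob_adata()
        result = cluster_graph(adata, n_pcs=5, k=10, resolution=0.5, seed=0)
        table = pd.crosstab(result.labels, adata.obs["truth"])
        assert (table.max(axis=1) == table.sum(axis=1)).all()  # pure clusters
        assert result.labels.nunique() == 2

    def test_low_resolution_limit_gives_one_cluster(self):
        # On connected data (a single Gaussian blob) the modularity limit
        # at vanishing resolution is one community.
        rng = np.random.default_rng(0)
        adata = ad.AnnData(X=rng.normal(0, 1, (120, 20)))
        result = cluster_graph(adata, n_pcs=5, k=15, resolution=1e-4, seed=0)
        assert result.labels.nunique() == 1

    def test_same_seed_same_labels(self):
        adata = two_blob_adata(seed=3)
        r1 = cluster_graph(adata, n_pcs=5, k=10, resolution=1.0, seed=7)
        r2 = cluster_graph(adata, n_pcs=5, k=10, resolution=1.0, seed=7)
        assert (r1.labels == r2.labels).all()

    def test_k_must_be_below_cell_count(self):
        adata = two_blob_adata(n=20)
        with pytest.raises(ValueError):
            cluster_graph(adata, n_pcs=5, k=25)


class TestResolutionSelection:
    def _scaled_rare(self, seed):
        config = ContinuumSimConfig(n_cells={"P6": 600})
        adata = simulate_counts(config, seed)
        return zscore_genes(normalize_log(adata))

    def test_reference_of_all_cells_selects_smallest_resolution(self):
        scaled = self._scaled_rare(0)
        res, _, _ = select_resolution(scaled, scaled.obs_names,
                                      resolution_grid=(0.4, 0.8), seed=0)
        assert res == 0.4

    def test_planted_rare_population_isolated(self):
        scaled = self._scaled_rare(1)
        ref = scaled.obs_names[scaled.obs["rare"].to_numpy(dtype=bool)]
        res, result, table = select_resolution(scaled, ref, seed=1)
        row = table[table["resolution"] == res].iloc[0]
        assert row["containment"] >= 0.8 and row["purity"] >= 0.5

    def test_unreachable_criteria_error_carries_table(self):
        config = ContinuumSimConfig(n_cells={"P6": 300}, program_effect_log2=0.0,
                                    rare_marker_effect_log2=0.0)
        adata = simulate_counts(config, 2)
        scaled = zscore_genes(normalize_log(adata))
        ref = scaled.obs_names[scaled.obs["rare"].to_numpy(dtype=bool)]
        with pytest.raises(ResolutionSelectionError) as err:
            select_resolution(scaled, ref, resolution_grid=(0.2, 0.4), seed=0,
                              containment_min=0.95, enrichment_min=0.95)
        assert {"resolution", "containment", "purity"} <= set(err.value.table.columns)


class TestMarkerStats:
    def _stats(self):
        counts = np.array([
            [9, 0, 1], [8, 0, 1], [7, 0, 0],   # cluster 0: gene0 on
            [0, 5, 1], [0, 6, 1], [0, 4, 0],   # cluster 1: gene1 on
        ])
        adata = make_adata(counts, genes=["a", "b", "hk"])
        norm = normalize_log(adata)
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=adata.obs_names)
        return marker_stats(norm, labels)

    def test_scaled_values_sum_to_zero_per_gene(self):
        stats = self._stats()
        np.testing.assert_allclose(stats.scaled.sum(axis=1), 0.0, atol=1e-12)

    def test_detection_fraction_bounds_and_values(self):
        stats = self._stats()
        assert ((stats.detection >= 0) & (stats.detection <= 1)).all().all()
        assert stats.detection.loc["a", 0] == 1.0
        assert stats.detection.loc["a", 1] == 0.0
        assert stats.detection.loc["hk", 1] == pytest.approx(2 / 3)

    def test_cluster_restricted_gene_passes_criterion(self):
        stats = self._stats()
        assert passes_marker_criteria(stats, "a")
        assert passes_marker_criteria(stats, "b")

    def test_low_detection_gene_fails_criterion(self):
        counts = np.zeros((40, 2), dtype=int)
        counts[:, 1] = 5
        counts[0, 0] = 1  # detected in 5% of cluster 0
        adata = make_adata(counts)
        norm = normalize_log(adata)
        labels = pd.Series([0] * 20 + [1] * 20, index=adata.obs_names)
        stats = marker_stats(norm, labels)
        assert not passes_marker_criteria(stats, "g0", detect_min=0.10)


class TestAnnotation:
    def _stats_two_clusters(self):
        counts = np.array([
            [9, 9, 0, 0, 3], [8, 9, 0, 1, 3],
            [0, 0, 9, 9, 3], [1, 0, 8, 9, 3],
        ])
        adata = make_adata(counts, genes=["s1", "s2", "d1", "d2", "hk"])
        labels = pd.Series([0, 0, 1, 1], index=adata.obs_names)
        return marker_stats(normalize_log(adata), labels)

    def test_ssc_like_cluster_has_stem_program(self):
        stats = self._stats_two_clusters()
        scores, ident = annotate_clusters(
            stats, {"ssc": ["s1", "s2"], "diff": ["d1", "d2"]})
        assert ident["ssc_like"] == 0

    def test_swapping_panels_swaps_the_label(self):
        stats = self._stats_two_clusters()
        _, ident = annotate_clusters(stats, {"ssc": ["d1", "d2"], "diff": ["s1", "s2"]})
        assert ident["ssc_like"] == 1

    def test_lowest_continuum_cluster_wins_on_simulated_data(self):
        config = ContinuumSimConfig(n_cells={"P6": 500})
        adata = simulate_counts(config, 4)
        norm = normalize_log(adata)
        labels = pd.Series((adata.obs["u"] > 0.5).astype(int).to_numpy(),
                           index=adata.obs_names)
        stats = marker_stats(norm, labels)
        _, ident = annotate_clusters(stats, {
            "ssc": list(config.ssc_genes), "diff": list(config.diff_genes)})
        u_by_cluster = adata.obs.groupby(labels)["u"].mean()
        assert ident["ssc_like"] == u_by_cluster.idxmin()

    def test_empty_panel_rejected(self):
        stats = self._stats_two_clusters()
        with pytest.raises(ValueError, match="empty"):
            annotate_clusters(stats, {"ssc": [], "diff": ["d1"]})


class TestClusterOverlap:
    def test_identical_labelings_have_diagonal_100(self):
        labels = pd.Series([0, 0, 1, 1, 2], index=list("abcde"))
        table = cluster_overlap(labels, labels)
        np.testing.assert_allclose(np.diag(table), 100.0)

    def test_even_split_gives_50_50(self):
        a = pd.Series([0, 0, 0, 0], index=list("abcd"))
        b = pd.Series([0, 0, 1, 1], index=list("abcd"))
        table = cluster_overlap(a, b)
        assert table.loc[0].tolist() == pytest.approx([50.0, 50.0])

    def test_matches_contingency_table_oracle(self):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(200)]
        a = pd.Series(rng.integers(0, 4, 200), index=idx)
        b = pd.Series(rng.integers(0, 3, 200), index=idx)
        table = cluster_overlap(a, b)
        for ca in range(4):
            for cb in range(3):
                expected = 100 * np.sum((a == ca) & (b == cb)) / np.sum(a == ca)
                assert table.loc[ca, cb] == pytest.approx(expected)
        np.testing.assert_allclose(table.sum(axis=1), 100.0)

    def test_disjoint_universes_rejected(self):
        a = pd.Series([0], index=["x"])
        b = pd.Series([0], index=["y"])
        with pytest.raises(ValueError):
            cluster_overlap(a, b)


class TestModifiedRV:
    def test_self_correlation_is_one(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        assert modified_rv(X, X) == pytest.approx(1.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(size=(40, 3)), rng.normal(size=(40, 5))
        v = modified_rv(X, Y)
        assert v == pytest.approx(modified_rv(Y, X))
        assert -1.0 <= v <= 1.0

    def test_invariant_to_column_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        assert modified_rv(X, X[:, ::-1]) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(3)
        vals = [modified_rv(rng.normal(size=(100, 5)), rng.normal(size=(100, 5)))
                for _ in range(10)]
        assert max(abs(v) for v in vals) < 0.2

    def test_constant_matrix_flagged_nan(self):
        X = np.ones((10, 2))
        Y = np.random.default_rng(0).normal(size=(10, 2))
        assert np.isnan(modified_rv(X, Y))

    def test_mismatched_features_rejected(self):
        with pytest.raises(ValueError):
            modified_rv(np.zeros((5, 2)), np.zeros((6, 2)))


class TestMTXRoundTrip:
    def test_counts_metadata_and_genes_preserved(self, tmp_path):
        config = ContinuumSimConfig(n_cells={"P6": 50})
        adata = simulate_counts(config, 0)
        write_counts_mtx(adata, tmp_path / "counts")
        back = read_counts_mtx(tmp_path / "counts")
        assert (back.X != adata.X).nnz == 0
        assert list(back.var_names) == list(adata.var_names)
        assert back.obs["library"].tolist() == adata.obs["library"].tolist()


class TestQCMetrics:
    def test_metrics_match_hand_computation(self):
        counts = np.array([[2, 0, 3], [0, 0, 1]])
        adata = make_adata(counts, genes=["mt-Nd1", "a", "b"])
        m = qc_metrics(adata)
        assert m["n_genes"].tolist() == [2, 1]
        assert m["total_umi"].tolist() == [5, 1]
        assert m["mito_fraction"].tolist() == pytest.approx([0.4, 0.0])
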