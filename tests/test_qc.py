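"""Cell/gene filtering rules, normalization formula, similarity measures."""

import numpy as np
import pandas as pd
import pytest

from crosstalk import (
    CountMatrix,
    cell_similarity,
    cluster_correlation_matrix,
    filter_cells,
    filter_genes,
    normalize,
    select_variable_genes,
)

from conftest import make_norm


def make_counts(values, genes=None, cells=None, is_mito=None, condition=None, cluster=None):
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["donor"] = "d0"
    meta["condition"] = condition if condition is not None else ["nonAD"] * n_cells
    if cluster is not None:
        meta["cluster"] = cluster
    flags = pd.DataFrame(
        {"is_mito": is_mito if is_mito is not None else [False] * n_genes},
        index=pd.Index(genes, name="gene_id"),
    )
    return CountMatrix(values, genes, cells, meta, flags)


class TestFilterCells:
    def test_two_sd_log10_window_drops_low_depth_cell(self):
        # totals (10000, 9500, 10500, 100, 9800, 10200): the 100-UMI cell's
        # log10 (2.0) falls below mean - 2 s.d. = 2.033 of the log10 totals
        totals = [10000, 9500, 10500, 100, 9800, 10200]
        m = make_counts(np.array([totals]))
        kept, report = filter_cells(m, sd_window=2.0, min_genes=0)
        assert report.removed_cell_ids == ["c3"]
        assert kept.n_cells == 5
        lo, hi = report.umi_bounds
        logs = np.log10(totals)
        assert lo == pytest.approx(logs.mean() - 2 * logs.std(ddof=1), abs=1e-12)
        assert hi == pytest.approx(logs.mean() + 2 * logs.std(ddof=1), abs=1e-12)
        assert lo == pytest.approx(2.033, abs=5e-4)

    def test_gene_floor_is_inclusive(self):
        # a cell detecting exactly min_genes genes is retained
        values = np.zeros((4, 2), dtype=int)
        values[:3, 0] = 1  # 3 detected genes
        values[:2, 1] = 1  # 2 detected genes
        m = make_counts(values)
        kept, _ = filter_cells(m, sd_window=10.0, min_genes=3)
        assert list(kept.cell_ids) == ["c0"]

    def test_identical_cells_all_retained(self):
        m = make_counts(np.full((3, 5), 7))
        kept, report = filter_cells(m, sd_window=2.0, min_genes=0)
        assert kept.n_cells == 5
        lo, hi = report.umi_bounds
        assert lo == hi  # zero s.d.: the window degenerates to a point

    def test_zero_total_cell_rejected(self):
        m = make_counts([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero total UMI"):
            filter_cells(m)

    def test_retained_cells_satisfy_recorded_bounds(self, ref_data):
        counts, _, _, _ = ref_data
        kept, report = filter_cells(counts, sd_window=2.0, min_genes=100)
        logs = np.log10(kept.total_umis())
        lo, hi = report.umi_bounds
        assert np.all((logs >= lo) & (logs <= hi))
        assert np.all(kept.detected_genes_per_cell() >= 100)


class TestFilterGenes:
    def test_prevalence_threshold_is_inclusive(self):
        values = np.zeros((2, 12), dtype=int)
        values[0, :10] = 1  # detected in exactly 10 cells
        values[1, :9] = 1  # detected in 9 cells
        m = make_counts(values)
        kept, report = filter_genes(m, min_cells=10, drop_mito=False)
        assert list(kept.gene_ids) == ["g0"]
        assert report.removed_gene_ids == ["g1"]

    def test_mito_dropped_regardless_of_prevalence(self):
        values = np.ones((2, 20), dtype=int)
        m = make_counts(values, genes=["MT-1", "g1"], is_mito=[True, False])
        kept, _ = filter_genes(m, min_cells=1, drop_mito=True)
        assert list(kept.gene_ids) == ["g1"]

    def test_noop_configuration_is_identity(self):
        values = np.array([[0, 1], [2, 0], [0, 0]])
        m = make_counts(values, is_mito=[True, False, False])
        kept, _ = filter_genes(m, min_cells=0, drop_mito=False)
        assert np.array_equal(kept.values, m.values)
        assert list(kept.gene_ids) == list(m.gene_ids)


class TestNormalize:
    def test_formula_on_known_count(self):
        # count 4 of a 2000-total cell: ln(4/2000*10000 + 1) = ln(21)
        values = np.array([[4], [1996]])
        nm = normalize(make_counts(values))
        assert nm.values[0, 0] == pytest.approx(np.log(21.0), abs=1e-12)

    def test_zero_count_maps_to_zero(self):
        nm = normalize(make_counts([[0, 3], [5, 2]]))
        assert nm.values[0, 0] == 0.0

    def test_per_cell_conservation(self, ref_nm):
        back = np.expm1(ref_nm.values).sum(axis=0)
        assert np.allclose(back, 10_000.0, rtol=1e-6)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero total UMI"):
            normalize(make_counts([[1, 0]]))


class TestVariableGenes:
    def test_membership_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(30, 40)) + (rng.random((30, 40)) < 0.2) * rng.poisson(
            20, size=(30, 40)
        )
        counts[:, counts.sum(axis=0) == 0] += 1
        nm = normalize(make_counts(counts))
        got = set(select_variable_genes(nm, 0.01, 3.0, 1.0))
        expected = set()
        for i, gene in enumerate(nm.gene_ids):
            v = nm.values[i]
            x = np.expm1(v)
            mean_log = sum(v) / len(v)
            mean_nat = sum(x) / len(x)
            var_nat = sum((xi - mean_nat) ** 2 for xi in x) / (len(x) - 1)
            disp = var_nat / mean_nat if mean_nat > 0 else 0.0
            if 0.01 <= mean_log <= 3.0 and disp > 1.0:
                expected.add(str(gene))
        assert got == expected

    def test_bounds_exclude_high_and_silent_genes(self):
        high = np.full(10, 3.5)
        silent = np.zeros(10)
        mid = np.array([0.0, 1.0] * 5)
        nm = make_norm(np.vstack([high, silent, mid]))
        kept = select_variable_genes(nm)
        assert "g0" not in kept  # mean log 3.5 > 3
        assert "g1" not in kept  # mean 0 < 0.01


class TestSimilarity:
    def test_identical_cells_have_unit_similarity(self):
        nm = make_norm(np.tile([[1.0], [2.0], [3.0]], (1, 4)), cluster=["a"] * 4)
        sim = cell_similarity(nm)
        assert np.allclose(sim, 1.0)

    def test_anticorrelated_cell_against_centroid(self):
        # cell (1,0) against a leave-one-out centroid (0,1) gives r = -1
        nm = make_norm(
            np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 1.0, 1.0]]), cluster=["a"] * 4
        )
        sim = cell_similarity(nm, include_self=False)
        assert sim["c0"] == pytest.approx(-1.0)

    def test_values_bounded_and_within_exceeds_between(self, ref_nm):
        sim = cell_similarity(ref_nm)
        assert sim.between(-1.0, 1.0).all()
        # own-centroid similarity should beat similarity to another cluster
        labels = ref_nm.cell_meta["cluster"].to_numpy()
        centroids = {
            cl: ref_nm.values[:, labels == cl].mean(axis=1) for cl in np.unique(labels)
        }
        own, other = [], []
        for ci in range(0, ref_nm.n_cells, 7):
            cl = labels[ci]
            v = ref_nm.values[:, ci]
            for cl2, cen in centroids.items():
                r = np.corrcoef(v, cen)[0, 1]
                (own if cl2 == cl else other).append(r)
        assert np.mean(own) > np.mean(other)

    def test_constant_cell_raises_with_cell_name(self):
        # both cells have constant expression vectors -> undefined correlation
        nm = make_norm(np.array([[1.0, 2.0], [1.0, 2.0]]), cluster=["a", "a"])
        with pytest.raises(ValueError, match="c0"):
            cell_similarity(nm)


class TestClusterCorrelation:
    def test_symmetric_with_unit_diagonal(self, ref_nm):
        corr = cluster_correlation_matrix(ref_nm)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert np.array_equal(corr.to_numpy(), corr.to_numpy().T)

    def test_condition_halves_correlate_higher_than_shifted_cluster(self, ref_nm):
        corr = cluster_correlation_matrix(ref_nm)
        # C1's two condition halves share all planted parameters; FB2 carries
        # different 4x markers, so it should sit farther away
        assert corr.loc["nonAD:C1", "AD:C1"] > corr.loc["nonAD:C1", "nonAD:FB2"]
        assert corr.loc["nonAD:C1", "AD:C1"] > corr.loc["nonAD:C1", "AD:SMC"]
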