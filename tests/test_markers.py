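"""Rank-sum test, BH adjustment, and marker detection against oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosstalk import (
    SimulationConfig,
    bh_adjust,
    count_degs,
    filter_cells,
    filter_genes,
    find_all_markers,
    find_markers_between,
    generate_counts,
    normalize,
    rank_sum_test,
)
from crosstalk.markers import _rank_sum_exact, _rank_sum_normal


def permutation_p(x, y):
    """Independent enumeration oracle with its own midrank computation."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    observed = sum(ranks[:nx])
    lo = hi = total = 0
    for combo in combinations(range(n), nx):
        w = sum(ranks[i] for i in combo)
        total += 1
        if w <= observed + 1e-9:
            lo += 1
        if w >= observed - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestRankSum:
    def test_separated_triples_give_exact_p(self):
        # all 3 low vs all 3 high: 2 * (1/20) over the C(6,3) labelings
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_symmetry_in_group_order(self, x, y):
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(y, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_enumeration_for_all_small_sizes(self):
        rng = np.random.default_rng(1)
        for nx in range(1, 8):
            for ny in range(1, 9 - nx):
                for _ in range(3):
                    x = rng.integers(0, 4, nx).astype(float)
                    y = rng.integers(0, 4, ny).astype(float)
                    _, p = rank_sum_test(x, y)
                    assert p == permutation_p(x, y)

    def test_normal_approximation_close_to_exact_for_moderate_n(self):
        # groups of >= 3 observations are the regime the marker functions
        # accept; there the approximate path tracks the exact one closely
        rng = np.random.default_rng(2)
        for n in range(9, 15):
            for _ in range(20):
                nx = int(rng.integers(3, n - 2))
                x = rng.normal(0, 1, nx)
                y = rng.normal(0.5, 1, n - nx)
                _, exact = _rank_sum_exact(x, y)
                _, approx = _rank_sum_normal(x, y)
                if exact >= 0.05:
                    assert approx == pytest.approx(exact, rel=0.10)

    def test_large_sample_path_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0.3, 1.2, 45)
            u, p = rank_sum_test(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBHAdjust:
    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_matches_statsmodels_and_dominates_p(self, p):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, 25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestFindAllMarkers:
    def test_recovers_planted_markers(self, ref_nm, ref_data, ref_cluster_markers):
        _, truth, _, _ = ref_data
        present = set(map(str, ref_nm.gene_ids))
        hits = misses = 0
        for cluster, genes in truth.planted_markers.items():
            found = set(
                ref_cluster_markers.loc[ref_cluster_markers["group"] == cluster, "gene"]
            )
            for g in genes & present:
                hits += g in found
                misses += g not in found
        assert hits / (hits + misses) >= 0.9

    def test_flat_gene_is_never_a_marker(self):
        rng = np.random.default_rng(0)
        values = rng.normal(1, 0.2, size=(5, 60)).clip(0)
        values[0] = 1.0  # identical in all clusters
        from conftest import make_norm

        nm = make_norm(values, cluster=["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        table = find_all_markers(nm)
        assert "g0" not in set(table["gene"])

    def test_undersized_cluster_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        from conftest import make_norm

        nm = make_norm(rng.normal(1, 0.3, (5, 23)).clip(0), cluster=["a"] * 20 + ["b"] * 2 + ["c"])
        with caplog.at_level("WARNING", logger="crosstalk"):
            find_all_markers(nm)
        assert "skipped" in caplog.text

    def test_sensitivity_monotone_in_fold_change(self):
        small = dict(
            n_clusters=3, cells_per_cluster_per_condition=50, n_genes=300,
            n_mito_genes=4, n_secreted=10, n_receptors=10, n_planted_pairs=2,
            markers_per_cluster=8, n_program_genes=12, state_genes_per_state=4,
            seed=5,
        )
        sens = []
        for fold in (1.5, 2.0, 4.0):
            counts, truth = generate_counts(SimulationConfig(**{**small, "marker_fold_change": fold}))
            kept, _ = filter_cells(counts, 2.0, 50)
            kept, _ = filter_genes(kept, 5, True)
            nm = normalize(kept)
            table = find_all_markers(nm)
            hit = tot = 0
            for cluster, genes in truth.planted_markers.items():
                found = set(table.loc[table["group"] == cluster, "gene"])
                for g in genes:
                    tot += 1
                    hit += g in found
            sens.append(hit / tot)
        assert sens[0] <= sens[1] <= sens[2]


class TestFindMarkersBetween:
    def test_overlapping_groups_rejected(self, ref_nm):
        cells = list(ref_nm.cell_ids[:10])
        with pytest.raises(ValueError, match="overlap"):
            find_markers_between(ref_nm, cells, cells[5:] + list(ref_nm.cell_ids[10:15]))

    def test_planted_condition_ligand_detected_up_in_ad(self, ref_nm, ref_data):
        _, truth, _, _ = ref_data
        meta = ref_nm.cell_meta
        sender = truth.sender_cluster
        ad = list(meta.index[(meta["cluster"] == sender) & (meta["condition"] == "AD")])
        non = list(meta.index[(meta["cluster"] == sender) & (meta["condition"] == "nonAD")])
        table = find_markers_between(ref_nm, ad, non)
        up = set(table.loc[table["log_fc"] > 0, "gene"])
        for ligand in truth.ligands:
            assert ligand in up

    def test_null_groups_rarely_significant(self, ref_nm):
        meta = ref_nm.cell_meta
        cells = list(meta.index[meta["cluster"] == "C1"])
        # split one homogeneous cluster arbitrarily in two
        table = find_markers_between(ref_nm, cells[::2], cells[1::2])
        assert len(table) / ref_nm.n_genes <= 0.05

    def test_up_down_bookkeeping(self):
        t = pd.DataFrame(
            {"gene": list("abcde"), "group": "x", "log_fc": [1, 2, 3, -1, -2],
             "p": [0.01] * 5, "q": [0.02] * 5, "mean_in": 0.0, "mean_out": 0.0}
        )
        counts = count_degs({"x": t})
        row = counts.iloc[0]
        assert (row["n_up"], row["n_down"], row["n_total"]) == (3, 2, 5)
        shuffled = count_degs({"x": t.sample(frac=1, random_state=0)})
        assert shuffled.equals(counts)

    def test_empty_table_counts_zero(self):
        empty = pd.DataFrame(columns=["gene", "group", "log_fc", "p", "q"])
        assert count_degs({"x": empty}).iloc[0]["n_total"] == 0
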