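"""scRNA-seq QC, normalization, DEG and gene-set overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from escapekit import synth
from escapekit.scqc import (
    MAD_SCALE,
    CountMatrix,
    downsample_to_match,
    intersect_signatures,
    log_normalize,
    overlap_test,
    read_gmt,
    remove_invalid_genes,
    remove_outlier_cells,
    wilcoxon_deg,
)


def small_matrix(counts, conds=None, symbols=None, ids=None):
    counts = np.asarray(counts)
    g, c = counts.shape
    return CountMatrix(
        counts,
        ids or [f"id{i}" for i in range(g)],
        symbols or [f"sym{i}" for i in range(g)],
        [f"c{i}" for i in range(c)],
        np.asarray(conds if conds is not None else ["a"] * (c // 2) + ["b"] * (c - c // 2)),
    )


class TestDownsampling:
    def test_equal_totals_is_identity(self):
        cm = small_matrix([[5, 5], [3, 3]], conds=["a", "b"])
        out = downsample_to_match(cm, 0)
        assert np.array_equal(out.counts, cm.counts)

    def test_deeper_condition_total_matches_exactly(self):
        rng = np.random.default_rng(0)
        counts = np.hstack([rng.poisson(20, (50, 30)), rng.poisson(5, (50, 30))])
        cm = small_matrix(counts, conds=["deep"] * 30 + ["shallow"] * 30)
        out = downsample_to_match(cm, 1)
        t_deep = out.counts[:, np.asarray(out.condition) == "deep"].sum()
        t_sh = out.counts[:, np.asarray(out.condition) == "shallow"].sum()
        assert t_deep == t_sh == cm.counts[:, 30:].sum()
        # shallower condition untouched
        assert np.array_equal(out.counts[:, 30:], cm.counts[:, 30:])
        # subsampling only removes counts
        assert (out.counts <= cm.counts).all()

    def test_retained_counts_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(5)
        counts = np.hstack([rng.poisson(30, (20, 10)), rng.poisson(10, (20, 10))])
        cm = small_matrix(counts, conds=["deep"] * 10 + ["shallow"] * 10)
        total = counts[:, :10].sum()
        target = counts[:, 10:].sum()
        reps = np.stack([
            downsample_to_match(cm, seed).counts[:, :10].sum(axis=1)
            for seed in range(100)
        ])
        # per-gene retained totals follow a hypergeometric draw of
        # target-out-of-total units; compare empirical means over 100 seeds
        n = counts[:, :10].sum(axis=1).astype(float)
        f = target / total
        expected = n * f
        var = n * f * (1 - f) * (total - n) / (total - 1)
        se = np.sqrt(var / 100)
        assert (np.abs(reps.mean(axis=0) - expected) <= 2.5 * se).all()

    def test_empty_condition_rejected(self):
        cm = small_matrix([[0, 5], [0, 3]], conds=["a", "b"])
        with pytest.raises(ValueError):
            downsample_to_match(cm, 0)

    def test_seeded_reproducibility(self):
        cm, _ = synth.simulate_counts(synth.CountsSimConfig(
            n_cells=(40, 40), n_background_genes=60, rng_seed=2))
        a = downsample_to_match(cm, 7)
        b = downsample_to_match(cm, 7)
        assert np.array_equal(a.counts, b.counts)


class TestInvalidGenes:
    def test_gene_detected_in_both_conditions_retained(self):
        cm = small_matrix([[1, 2], [3, 4]], conds=["a", "b"])
        out, report = remove_invalid_genes(cm)
        assert out.shape[0] == 2 and report.removed_genes.empty

    def test_gene_absent_in_one_condition_removed(self):
        cm = small_matrix([[1, 0], [3, 4]], conds=["a", "b"])
        out, report = remove_invalid_genes(cm)
        assert out.gene_ids == ["id1"]
        assert report.removed_genes.reason.tolist() == ["undetected-in-a-condition"]

    def test_shared_symbol_removes_all_rows(self):
        cm = small_matrix([[1, 2], [3, 4], [5, 6]], conds=["a", "b"],
                          symbols=["dup", "dup", "ok"],
                          ids=["id0", "id1", "id2"])
        out, report = remove_invalid_genes(cm)
        assert out.gene_ids == ["id2"]
        assert set(report.removed_genes.gene_id) == {"id0", "id1"}
        assert (report.removed_genes.reason == "multi-ID-symbol").all()


def brute_force_outliers(counts, mito_rows, n_mads=5.0):
    """Independent plain-loop reimplementation of the three MAD rules."""
    lib = counts.sum(axis=0).astype(float)
    removed = set()
    metrics = {
        "lib": np.log(lib),
        "genes": np.log((counts > 0).sum(axis=0)),
        "mito": 100.0 * counts[mito_rows, :].sum(axis=0) / lib,
    }
    for name, vals in metrics.items():
        med = float(np.median(vals))
        mad = MAD_SCALE * float(np.median([abs(v - med) for v in vals]))
        for j, v in enumerate(vals):
            if name == "mito":
                if v >= med + n_mads * mad and v > med:
                    removed.add(j)
            elif v <= med - n_mads * mad and v < med:
                removed.add(j)
    return removed


class TestOutlierCells:
    def test_homogeneous_matrix_keeps_everything(self):
        rng = np.random.default_rng(1)
        cm = small_matrix(rng.poisson(10, (40, 30)))
        out, report = remove_outlier_cells(cm, [])
        assert out.shape[1] == 30 and report.removed_cells.empty

    def test_planted_low_library_cell_removed(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(50, (60, 40))
        counts[:, 0] = rng.binomial(counts[:, 0], 0.01)  # ~e^-4.6 library
        cm = small_matrix(counts)
        out, report = remove_outlier_cells(cm, [])
        assert "c0" in set(report.removed_cells.cell_id)
        row = report.removed_cells.set_index("cell_id").loc["c0", "reason"]
        assert "low-library" in row

    def test_planted_high_mito_cell_removed(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(20, (50, 40))
        counts[:2, :] = rng.poisson(1, (2, 40))   # ~2% mito baseline
        counts[:2, 5] = 500                        # 90%-mito cell
        cm = small_matrix(counts)
        out, report = remove_outlier_cells(cm, ["id0", "id1"])
        row = report.removed_cells.set_index("cell_id").loc["c5", "reason"]
        assert "high-mito" in row

    def test_agrees_with_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            g, c = rng.integers(10, 30), rng.integers(8, 25)
            counts = rng.poisson(rng.uniform(2, 30), (g, c))
            counts[:, rng.integers(0, c)] += rng.poisson(100)  # heterogeneity
            if rng.random() < 0.5:
                counts[:, rng.integers(0, c)] //= rng.integers(5, 60)
            counts[:, counts.sum(axis=0) == 0] += 1  # avoid empty cells
            n_mito = int(rng.integers(0, 4))
            cm = small_matrix(counts)
            mito_ids = [f"id{i}" for i in range(n_mito)]
            expected = brute_force_outliers(counts, np.arange(n_mito))
            _, report = remove_outlier_cells(cm, mito_ids)
            got = {int(cid[1:]) for cid in report.removed_cells.cell_id}
            assert got == expected

    def test_degenerate_equal_cells_keep_everything(self):
        # identical cells give zero MAD on every metric; the strict-
        # deviation guard means nobody is flagged
        cm = small_matrix(np.ones((4, 3), dtype=int))
        out, report = remove_outlier_cells(cm, ["id0"])
        assert out.shape[1] == 3 and report.removed_cells.empty

    def test_fewer_than_three_cells_rejected(self):
        cm = small_matrix([[1, 2], [3, 4]], conds=["a", "b"])
        with pytest.raises(ValueError):
            remove_outlier_cells(cm, [])


class TestNormalization:
    def test_zero_count_maps_to_zero(self):
        cm = small_matrix([[0, 1], [5, 3]])
        norm = log_normalize(cm)
        assert norm[0, 0] == 0.0

    def test_formula_value(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 10
        counts[1, 0] = 9990
        cm = small_matrix(counts, conds=["a"])
        norm = log_normalize(cm)
        assert norm[0, 0] == pytest.approx(math.log(11.0))

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (30, 4)) + 1
        cm = small_matrix(counts)
        doubled = small_matrix(counts * 2)
        np.testing.assert_allclose(log_normalize(cm), log_normalize(doubled))

    def test_zero_total_cell_rejected(self):
        cm = small_matrix([[0, 1], [0, 2]])
        with pytest.raises(ValueError):
            log_normalize(cm)


def permutation_pvalue(a, b):
    """Exhaustive two-sided rank-sum permutation test (oracle)."""
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    n = len(a)
    obs = ranks[:n].sum()
    stats = [sum(ranks[list(comb)]) for comb in
             itertools.combinations(range(len(pooled)), n)]
    mu = np.mean(stats)
    return np.mean([abs(s - mu) >= abs(obs - mu) - 1e-9 for s in stats])


class TestWilcoxonDEG:
    def norm_from(self, counts, conds):
        return log_normalize(small_matrix(counts, conds=conds))

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        counts = np.tile(rng.poisson(10, (30, 1)), (1, 12))
        norm = self.norm_from(counts, ["a"] * 6 + ["b"] * 6)
        table = wilcoxon_deg(norm, [f"g{i}" for i in range(30)],
                            np.arange(6), np.arange(6, 12))
        assert not table.significant.any()

    def test_planted_fold_change_recovered_with_sign(self):
        cm, truth = synth.simulate_counts(synth.CountsSimConfig(
            n_cells=(200, 200), n_background_genes=300, rng_seed=8))
        cm, _ = remove_invalid_genes(downsample_to_match(cm, 8))
        norm = log_normalize(cm)
        cond = np.asarray(cm.condition)
        table = wilcoxon_deg(norm, cm.gene_ids, cond == "treated",
                            cond == "untreated")
        sig_up = set(table.loc[table.significant & (table.direction == "up"),
                               "gene"])
        planted = set(truth["de_gene_ids"]) & set(cm.gene_ids)
        assert planted and planted <= sig_up

    def test_pvalue_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(12):
            a = rng.normal(0.5, 0.4, 5).clip(0)
            b = rng.normal(1.2, 0.4, 5).clip(0)
            norm = np.vstack([np.concatenate([a, b])])
            table = wilcoxon_deg(norm, ["g"], np.arange(5), np.arange(5, 10),
                                 logfc_threshold=0.0, min_pct=0.0)
            assert table.p_val[0] == pytest.approx(
                permutation_pvalue(a, b), abs=0.06)

    def test_min_pct_filter_excludes_rare_genes(self):
        norm = np.zeros((1, 20))
        norm[0, 0] = 3.0  # detected in 1/10 of group A only
        table = wilcoxon_deg(norm, ["g"], np.arange(10), np.arange(10, 20),
                             min_pct=0.5)
        assert np.isnan(table.p_val[0])

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_deg(np.zeros((1, 10)), ["g"], np.arange(5), np.arange(4, 10))

    def test_bonferroni_uses_full_matrix_size(self):
        rng = np.random.default_rng(2)
        norm = rng.uniform(0, 2, (40, 16))
        table = wilcoxon_deg(norm, [f"g{i}" for i in range(40)],
                             np.arange(8), np.arange(8, 16),
                             logfc_threshold=0.0, min_pct=0.0)
        tested = table.p_val.notna()
        np.testing.assert_allclose(
            table.p_val_adj[tested], np.minimum(table.p_val[tested] * 40, 1.0))


class TestSignaturesAndOverlap:
    def deg_table(self, genes, sig_up=(), sig_down=()):
        df = pd.DataFrame({"gene": genes})
        df["significant"] = df.gene.isin(set(sig_up) | set(sig_down))
        df["direction"] = np.where(df.gene.isin(set(sig_up)), "up",
                                   np.where(df.gene.isin(set(sig_down)), "down", "none"))
        return df

    def test_intersection_of_up_and_down_sets(self):
        genes = [f"g{i}" for i in range(10)]
        a = self.deg_table(genes, sig_up=["g1", "g2", "g3"], sig_down=["g7"])
        b = self.deg_table(genes, sig_up=["g2", "g3", "g4"], sig_down=["g7", "g8"])
        up, down = intersect_signatures(a, b)
        assert up == ["g2", "g3"] and down == ["g7"]

    def test_disjoint_significant_sets_empty(self):
        genes = [f"g{i}" for i in range(6)]
        up, down = intersect_signatures(
            self.deg_table(genes, sig_up=["g1"]),
            self.deg_table(genes, sig_up=["g2"]))
        assert up == [] and down == []

    def test_no_overlap_large_universe_p_near_one(self):
        _, p = overlap_test([f"a{i}" for i in range(10)],
                            [f"b{i}" for i in range(10)], 1000)
        assert p > 0.6

    def test_matches_hand_enumerated_hypergeometric_tail(self):
        # universe 20, |A| = 6, |B| = 5, overlap 3:
        # p = sum_{j>=3} C(6,j) C(14,5-j) / C(20,5)
        tail = sum(math.comb(6, j) * math.comb(14, 5 - j) for j in range(3, 6))
        expected = tail / math.comb(20, 5)
        _, p = overlap_test([f"g{i}" for i in range(6)],
                            [f"g{i}" for i in range(3)] + ["x1", "x2"], 20)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(["a", "b"], ["c"], 2)


class TestIO:
    def test_mtx_round_trip(self, tmp_path):
        cm, _ = synth.simulate_counts(synth.CountsSimConfig(
            n_cells=(15, 15), n_background_genes=40, rng_seed=3))
        cm.to_mtx_dir(tmp_path / "mtx")
        back = CountMatrix.from_mtx_dir(tmp_path / "mtx")
        assert np.array_equal(back.counts, cm.counts)
        assert back.gene_ids == cm.gene_ids
        assert list(back.condition) == list(cm.condition)

    def test_gmt_parsing(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\t-\tg9\n")
        sets = read_gmt(path)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
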