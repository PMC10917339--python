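"""Pipeline operations against construction oracles and exact enumeration."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nanobiopsy.sicm_model import InvalidParameterError
from nanobiopsy.transcriptomics import (
    QC_THRESHOLDS,
    CountsMatrix,
    classify_phenotype,
    compute_qc_metrics,
    enrichment_score,
    filter_cells,
    filter_genes,
    fisher_exact_two_sided,
    lognormalize,
    regress_out,
    run_pca,
    scale_clip,
    score_change_summary,
    select_hvg,
    tabulate_switches,
)


def fisher_enumeration_oracle(table):
    """Exact two-sided Fisher p by full enumeration in rational arithmetic."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = sum(p for x in range(0, c1 + 1) if (p := prob(x)) <= p_obs)
    return float(total)


def toy_matrix(counts, pc=None, mito=None, ribo=None, cells_df=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = pd.DataFrame(
        {
            "protein_coding": pc if pc is not None else [True] * n_genes,
            "mito": mito if mito is not None else [False] * n_genes,
            "ribo": ribo if ribo is not None else [False] * n_genes,
        },
        index=pd.Index([f"g{i:03d}" for i in range(n_genes)]),
    )
    if cells_df is None:
        cells_df = pd.DataFrame(index=pd.Index([f"c{i:03d}" for i in range(n_cells)]))
    return CountsMatrix(sp.csr_matrix(counts), genes, cells_df)


class TestQcMetricsAndFilters:
    def test_basic_metric_definitions(self):
        counts = np.zeros((4, 1), dtype=int)
        counts[0, 0] = 6  # protein-coding
        counts[1, 0] = 2  # mito
        counts[2, 0] = 2  # ribo
        m = toy_matrix(counts, pc=[True, True, True, False], mito=[False, True, False, False],
                       ribo=[False, False, True, False])
        qc = compute_qc_metrics(m)
        assert qc["n_expressed_pc_genes"].iloc[0] == 3
        assert qc["pct_mito"].iloc[0] == pytest.approx(20.0)
        assert qc["pct_ribo"].iloc[0] == pytest.approx(20.0)

    def test_all_mito_cell(self):
        counts = np.array([[5], [0]])
        m = toy_matrix(counts, mito=[True, False])
        assert compute_qc_metrics(m)["pct_mito"].iloc[0] == pytest.approx(100.0)

    def test_strict_boundaries(self):
        metrics = pd.DataFrame(
            {
                "n_expressed_pc_genes": [150, 151, 151, 151],
                "pct_ribo": [5.0, 9.9, 10.0, 5.0],
                "pct_mito": [5.0, 29.9, 5.0, 30.0],
            }
        )
        mask = filter_cells(metrics, QC_THRESHOLDS)
        assert list(mask) == [False, True, False, False]

    def test_gene_filter_examples(self):
        counts = np.array(
            [
                [4, 4, 0],  # kept: >3 in two cells
                [4, 3, 3],  # dropped: only one cell exceeds 3
                [9, 9, 9],  # non-coding, dropped by flag
            ]
        )
        m = toy_matrix(counts, pc=[True, True, False])
        assert list(filter_genes(m)) == [True, False, False]

    def test_gene_filter_matches_brute_force(self, rng):
        counts = rng.integers(0, 8, size=(50, 20))
        pc = rng.uniform(size=50) > 0.2
        m = toy_matrix(counts, pc=list(pc))
        mask = filter_genes(m)
        brute = [
            sum(c > 3 for c in counts[g]) >= 2 and pc[g] for g in range(50)
        ]
        assert list(mask) == brute

    def test_filters_idempotent_and_permutation_equivariant(self, rng):
        counts = rng.integers(0, 10, size=(30, 12))
        m = toy_matrix(counts)
        qc = compute_qc_metrics(m)
        mask = filter_cells(qc, {"min_genes": 5, "max_ribo_pct": 10, "max_mito_pct": 30})
        once = m.subset_cells(mask.to_numpy())
        twice = once.subset_cells(
            filter_cells(compute_qc_metrics(once),
                         {"min_genes": 5, "max_ribo_pct": 10, "max_mito_pct": 30}).to_numpy()
        )
        assert once.n_cells == twice.n_cells
        perm = rng.permutation(12)
        permuted = toy_matrix(counts[:, perm])
        mask_p = filter_cells(compute_qc_metrics(permuted),
                              {"min_genes": 5, "max_ribo_pct": 10, "max_mito_pct": 30})
        assert list(mask_p.to_numpy()) == list(mask.to_numpy()[perm])


class TestNormalisation:
    def test_single_gene_cell(self):
        norm = lognormalize(np.array([[7], [0]]))
        assert norm[0, 0] == pytest.approx(np.log1p(1e4))

    def test_depth_invariance(self, rng):
        counts = rng.integers(0, 20, size=(30, 1))
        assert np.allclose(lognormalize(counts), lognormalize(counts * 2))

    def test_column_sums_hit_target(self, rng):
        counts = rng.integers(0, 30, size=(40, 6)) + 1
        norm = lognormalize(counts)
        assert np.allclose(np.expm1(norm).sum(axis=0), 1e4)

    def test_matches_scanpy(self, rng):
        import scanpy as sc
        from anndata import AnnData

        counts = rng.integers(0, 30, size=(25, 8)).astype(float)
        adata = AnnData(counts.T.copy())
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        assert np.allclose(lognormalize(counts), adata.X.T, atol=1e-6)

    def test_zero_cell_warns(self):
        counts = np.zeros((5, 2), dtype=int)
        counts[0, 0] = 3
        with pytest.warns(UserWarning, match="zero-total"):
            norm = lognormalize(counts)
        assert np.all(norm[:, 1] == 0)


class TestRegressOut:
    def test_residuals_orthogonal_to_covariates(self, rng):
        y = rng.normal(size=(40, 30))
        cov = rng.normal(size=(30, 2))
        res = regress_out(y, cov)
        for g in range(0, 40, 7):
            for j in range(2):
                assert abs(np.corrcoef(res[g], cov[:, j])[0, 1]) < 1e-8

    def test_pure_confound_removed(self, rng):
        cov = rng.normal(size=30)
        y = np.outer(np.ones(5), 2.0 * cov)
        res = regress_out(y, cov)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_uncorrelated_covariate_leaves_centered_values(self):
        y = np.array([[1.0, 2.0, 3.0, 4.0]])
        cov = np.array([1.0, -1.0, -1.0, 1.0])  # exactly orthogonal to the trend
        res = regress_out(y, cov)
        assert np.allclose(res, y - y.mean())

    def test_collinear_covariates_dropped_with_warning(self, rng):
        y = rng.normal(size=(5, 20))
        cov = rng.normal(size=20)
        with pytest.warns(UserWarning, match="collinear"):
            regress_out(y, np.column_stack([cov, 2 * cov]))


class TestScaleClip:
    def test_constant_gene_scales_to_zero(self):
        assert np.all(scale_clip(np.full((3, 10), 4.2)) == 0.0)

    def test_outlier_clipped_at_cap(self):
        x = np.zeros((1, 200))
        x[0, 0] = 100.0  # z ~ 14 before clipping
        assert scale_clip(x).max() == pytest.approx(5.0)

    def test_mean_zero_unit_sd_when_unclipped(self, rng):
        x = rng.normal(size=(10, 200))
        z = scale_clip(x, cap=50.0)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestSelectHvg:
    def test_planted_high_dispersion_genes_selected(self, rng):
        # planted genes sit at spread-out baseline levels (so they fall in
        # different mean bins) and are strongly bimodal across cells
        n_genes, n_cells = 1000, 60
        x = rng.poisson(5.0, size=(n_genes, n_cells)).astype(float)
        planted = rng.choice(n_genes, 10, replace=False)
        for k, g in enumerate(planted):
            x[g] = 0.0  # on/off bimodal: huge variance at its mean level
            x[g, n_cells // 2:] = rng.poisson(20.0 + 10.0 * k, size=n_cells // 2)
        norm = lognormalize(x)
        ids = [f"g{i:04d}" for i in range(n_genes)]
        selected = select_hvg(norm, ids, n=50)
        assert set(planted).issubset(set(selected))

    def test_requesting_more_than_available_returns_all(self, rng):
        x = rng.poisson(5.0, size=(20, 10)).astype(float)
        with pytest.warns(UserWarning):
            sel = select_hvg(lognormalize(x), [f"g{i}" for i in range(20)], n=600)
        assert len(sel) <= 20

    def test_deterministic(self, rng):
        x = rng.poisson(3.0, size=(300, 30)).astype(float)
        norm = lognormalize(x)
        ids = [f"g{i:03d}" for i in range(300)]
        assert np.array_equal(select_hvg(norm, ids, n=40), select_hvg(norm, ids, n=40))


class TestRunPca:
    def test_recovers_planted_direction(self, rng):
        direction = rng.normal(size=100)
        direction /= np.linalg.norm(direction)
        scores = rng.normal(size=50) * 10
        x = np.outer(direction, scores) + rng.normal(size=(100, 50)) * 0.1
        emb, var, loadings = run_pca(x, k=3)
        assert abs(np.dot(loadings[0], direction)) > 0.99
        assert np.all(np.diff(var) <= 1e-9)

    def test_rotation_invariant_spectrum(self, rng):
        x = rng.normal(size=(30, 40))
        q, _ = np.linalg.qr(rng.normal(size=(30, 30)))
        _, var1, _ = run_pca(x, k=5)
        _, var2, _ = run_pca(q @ x, k=5)
        assert np.allclose(var1, var2, rtol=1e-8)

    def test_sign_convention(self, rng):
        x = rng.normal(size=(30, 40))
        _, _, loadings = run_pca(x, k=4)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_deficit_reduces_with_warning(self, rng):
        x = rng.normal(size=(5, 4))
        with pytest.warns(UserWarning, match="rank"):
            emb, _, _ = run_pca(x, k=8)
        assert emb.shape[1] <= 3


class TestEnrichmentScore:
    def test_maximal_enrichment_at_top_ranks(self):
        v = np.concatenate([np.full(10, 5.0), np.zeros(90)])
        mask = np.concatenate([np.ones(10, bool), np.zeros(90, bool)])
        assert enrichment_score(v, mask) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            v = rng.normal(size=200)
            mask = rng.uniform(size=200) < 0.1
            if not mask.any() or mask.all():
                continue
            assert -1.0 <= enrichment_score(v, mask) <= 1.0

    def test_permutation_null_is_centred(self, rng):
        v = rng.normal(size=300)
        scores = []
        for _ in range(1000):
            mask = np.zeros(300, bool)
            mask[rng.choice(300, 20, replace=False)] = True
            scores.append(enrichment_score(v, mask))
        assert abs(np.mean(scores)) < 0.03

    def test_scale_invariance_of_rank_statistic(self, rng):
        v = rng.normal(size=150)
        mask = np.zeros(150, bool)
        mask[:12] = True
        assert enrichment_score(3.0 * v, mask) == pytest.approx(enrichment_score(v, mask))

    def test_empty_overlap_rejected(self):
        with pytest.raises(InvalidParameterError):
            enrichment_score(np.ones(10), np.zeros(10, bool))


class TestClassifyAndSwitches:
    def test_classification_rules(self):
        assert classify_phenotype(0.4, 0.1) == "PN"
        assert classify_phenotype(0.1, 0.4) == "MES"
        assert classify_phenotype(0.3, 0.3) == "unclassified"

    def _labels(self, rows):
        return pd.DataFrame(rows, columns=["pair_id", "timepoint", "treated", "label"])

    def test_printed_switch_counts(self):
        rows = []
        for i in range(7):
            rows += [(f"u{i}", "day1", False, "PN"), (f"u{i}", "day4", False, "MES")]
        for i in range(3):
            rows += [(f"v{i}", "day1", False, "PN"), (f"v{i}", "day4", False, "PN")]
        for i in range(8):
            rows += [(f"t{i}", "day1", True, "MES"), (f"t{i}", "day4", True, "MES")]
        rows += [("t9", "day1", True, "MES"), ("t9", "day4", True, "PN")]
        result = tabulate_switches(self._labels(rows))
        assert result.table.tolist() == [[7, 3], [1, 8]]

    def test_no_switches_zero_column(self):
        rows = [("a", "day1", False, "PN"), ("a", "day4", False, "PN")]
        assert tabulate_switches(self._labels(rows)).table[:, 0].sum() == 0

    def test_unclassified_pairs_excluded_and_counted(self):
        rows = [
            ("a", "day1", False, "PN"),
            ("a", "day4", False, "unclassified"),
            ("b", "day1", True, "PN"),
            ("b", "day4", True, "MES"),
        ]
        result = tabulate_switches(self._labels(rows))
        assert result.n_excluded_unclassified == 1
        assert result.table.sum() == 1

    def test_unpaired_samples_reported(self):
        rows = [("a", "day1", False, "PN")]
        result = tabulate_switches(self._labels(rows))
        assert result.unpaired == ["a"]

    def test_random_tables_match_recount(self, rng):
        rows = []
        for i in range(30):
            treated = bool(rng.integers(2))
            l1, l4 = rng.choice(["PN", "MES"], 2)
            rows += [(f"p{i}", "day1", treated, l1), (f"p{i}", "day4", treated, l4)]
        df = self._labels(rows)
        result = tabulate_switches(df)
        recount = np.zeros((2, 2), int)
        for i in range(30):
            grp = df[df.pair_id == f"p{i}"]
            sw = grp.label.iloc[0] != grp.label.iloc[1]
            recount[int(grp.treated.iloc[0]), 0 if sw else 1] += 1
        assert np.array_equal(result.table, recount)


class TestFisherExact:
    def test_printed_table_value(self):
        p = fisher_exact_two_sided([[7, 3], [1, 8]])
        assert p == pytest.approx(0.019767, abs=1e-4)
        assert p == pytest.approx(fisher_enumeration_oracle([[7, 3], [1, 8]]), rel=1e-9)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_matches_enumeration_on_small_tables(self):
        for a in range(0, 5):
            for b in range(0, 5):
                for c in range(0, 4):
                    for d in range(0, 4):
                        table = [[a, b], [c, d]]
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        assert fisher_exact_two_sided(table) == pytest.approx(
                            fisher_enumeration_oracle(table), rel=1e-9
                        ), table

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            assert fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0


class TestScoreChangeSummary:
    def _scores(self, untreated_changes, treated_changes):
        rows = []
        for i, delta in enumerate(untreated_changes):
            rows.append((f"u{i}", "day1", False, 0.0, 0.0))
            rows.append((f"u{i}", "day4", False, delta, delta))
        for i, delta in enumerate(treated_changes):
            rows.append((f"t{i}", "day1", True, 0.0, 0.0))
            rows.append((f"t{i}", "day4", True, delta, delta))
        return pd.DataFrame(rows, columns=["pair_id", "timepoint", "treated", "PN", "MES"])

    def test_identical_arms_ratio_one(self):
        out = score_change_summary(self._scores([0.2, 0.3], [0.2, 0.3]))
        assert out["PN"]["fold_ratio"] == pytest.approx(1.0)

    def test_planted_threefold_ratio_recovered(self, rng):
        ratios = []
        for _ in range(30):
            untreated = np.abs(rng.normal(0.3, 0.05, 10))
            treated = np.abs(rng.normal(0.1, 0.02, 9))
            out = score_change_summary(self._scores(untreated, treated))
            ratios.append(out["PN"]["fold_ratio"])
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.15)

    def test_single_pair_arm_rejected(self):
        with pytest.raises(InvalidParameterError):
            score_change_summary(self._scores([0.2, 0.3], [0.2]))
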