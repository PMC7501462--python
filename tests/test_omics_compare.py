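"""Regulon-based time alignment, proteome PCA, expression Z-scoring."""

import numpy as np
import pandas as pd
import pytest

from ecswitch.omics_compare import (
    ExpressionMatrix,
    align_by_regulon,
    expression_from_proteomes,
    pca_scores,
    zscore_expression,
)


def make_expr(values, strain="A", times=None):
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{j}" for j in range(values.shape[1])]
    n = values.shape[1]
    meta = pd.DataFrame({
        "strain": [strain] * n,
        "time": times if times is not None else list(range(n)),
        "replicate": ["r1"] * n,
    })
    return ExpressionMatrix(values, meta)


class TestAlignment:
    def test_identical_matrices_identity_map(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(size=(6, 8)))
        amap = align_by_regulon(expr, expr, {"g0", "g1", "g2"})
        assert amap.pairs == [(i, i) for i in range(8)]
        assert amap.score == pytest.approx(0.0)

    def test_planted_shift_recovered(self):
        from collections import Counter

        base = np.concatenate([np.zeros(4), np.ones(4)])  # step profile
        profile_a = base[2:8]  # step after 2 samples
        profile_b = base[0:8]  # same step, delayed by 2 sampling steps
        a = make_expr(np.tile(profile_a, (3, 1)))
        b = make_expr(np.tile(profile_b, (3, 1)), strain="B")
        amap = align_by_regulon(a, b, {"g0", "g1", "g2"})
        offsets = [j - i for i, j in amap.pairs]
        # z-scoring per strain makes matched levels close but not equal
        # (different pre/post proportions), so assert the offset only
        assert Counter(offsets).most_common(1)[0][0] == 2

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(7)
        a = make_expr(rng.normal(size=(5, 7)))
        b = make_expr(rng.normal(size=(5, 6)), strain="B")
        fwd = align_by_regulon(a, b, {"g0", "g1"})
        rev = align_by_regulon(b, a, {"g0", "g1"})
        assert fwd.score == pytest.approx(rev.score)
        assert sorted((j, i) for i, j in fwd.pairs) == sorted(rev.pairs)

    def test_empty_regulon_overlap_raises(self):
        expr = make_expr(np.ones((2, 3)))
        with pytest.raises(ValueError):
            align_by_regulon(expr, expr, {"missing"})

    def test_synthetic_strains_align_by_time_since_depletion(self, cfg0, toy_tables):
        """Depletion at 35 vs 47 h: aligned pairs pair up the pre/post
        phases, matching time-since-depletion within one interval."""
        from ecswitch.synthetic_data import (
            PHO_REGULON, build_toy_gem, make_proteome, make_timeseries)

        _, kcats, proteins = toy_tables
        samples = {}
        for strain in ("M145", "M1152"):
            model = build_toy_gem(cfg0, strain)
            ts = make_timeseries(cfg0, strain)
            samples[strain] = make_proteome(model, ts, cfg0, kcats, proteins)
        a = expression_from_proteomes(samples["M145"])
        b = expression_from_proteomes(samples["M1152"])
        amap = align_by_regulon(a, b, set(PHO_REGULON))
        t_dep = {"M145": 35.0, "M1152": 47.0}
        for i, j in amap.pairs:
            rel_a = amap.times_a[i] - t_dep["M145"]
            rel_b = amap.times_b[j] - t_dep["M1152"]
            # same side of the switch; grids have ~9-14 h spacing
            assert abs(rel_a - rel_b) <= 14.0
            assert (rel_a > 0) == (rel_b > 0)


class TestPca:
    def test_duplicate_groups_one_axis(self):
        # two exact groups along one direction -> PC1 explains everything
        col_a, col_b = np.zeros(5), np.ones(5)
        values = np.column_stack([col_a, col_a, col_b, col_b])
        res = pca_scores(make_expr(values), n_components=2, scale=False)
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_shares_non_increasing_and_bounded(self):
        rng = np.random.default_rng(3)
        res = pca_scores(make_expr(rng.normal(size=(10, 8))), n_components=5)
        assert np.all(np.diff(res.percent_variance) <= 1e-9)
        assert res.percent_variance.sum() <= 100.0 + 1e-9

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        res = pca_scores(make_expr(rng.normal(size=(6, 7))), n_components=3)
        for col in res.loadings.columns:
            loads = res.loadings[col].to_numpy()
            assert loads[np.argmax(np.abs(loads))] > 0

    def test_rank_truncation_warns(self, caplog):
        res = pca_scores(make_expr(np.random.default_rng(0).normal(size=(3, 3))),
                         n_components=10)
        assert res.scores.shape[1] <= 2

    def test_planted_time_and_strain_structure(self):
        """Large time drift on one gene set, smaller strain offset on a
        disjoint set: PC1 orders time, PC2 separates strains."""
        rng = np.random.default_rng(11)
        n_time, n_genes = 6, 40
        cols, strains, times = [], [], []
        for strain, offset in (("A", 0.0), ("B", 1.0)):
            for t in range(n_time):
                drift = np.zeros(n_genes)
                drift[:20] = 3.0 * t  # strong time signal
                drift[20:] = 5.0 * offset  # weaker (fewer samples span it)
                cols.append(drift + rng.normal(0, 0.1, n_genes))
                strains.append(strain)
                times.append(float(t))
        values = pd.DataFrame(np.column_stack(cols),
                              index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{j}" for j in range(len(cols))])
        meta = pd.DataFrame({"strain": strains, "time": times,
                             "replicate": ["r1"] * len(cols)})
        res = pca_scores(ExpressionMatrix(values, meta), n_components=2, scale=False)
        pc1, pc2 = res.scores["PC1"].to_numpy(), res.scores["PC2"].to_numpy()
        t_arr, s_arr = np.array(times), np.array(strains)
        # PC1 sorts samples by time within each strain
        for strain in ("A", "B"):
            sel = s_arr == strain
            order = np.argsort(t_arr[sel])
            assert (np.diff(pc1[sel][order]) > 0).all() or (np.diff(pc1[sel][order]) < 0).all()
        # PC2 separates the strains
        assert (pc2[s_arr == "A"].max() < pc2[s_arr == "B"].min()
                or pc2[s_arr == "B"].max() < pc2[s_arr == "A"].min())


class TestZscore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(13)
        out = zscore_expression(make_expr(rng.uniform(1, 5, size=(4, 6))))
        z = out.values.to_numpy()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_constant_gene_flagged_zero(self):
        values = np.vstack([np.full(4, 7.0), np.arange(4.0)])
        out = zscore_expression(make_expr(values))
        assert out.zero_variance == {"g0"}
        assert (out.values.loc["g0"] == 0).all()

    def test_log_transform_arithmetic(self):
        out = zscore_expression(make_expr([[0.0, 1.0, 3.0]]), log_transform=True)
        # log2(x+1) of {0,1,3} is {0,1,2}: evenly spaced, so the z-scores
        # are those of an arithmetic sequence
        assert out.values.iloc[0].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(3, 5))
        a = zscore_expression(make_expr(base))
        b = zscore_expression(make_expr(base * 4.0 + 2.0))
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-9)

    def test_negative_values_rejected_for_log(self):
        with pytest.raises(ValueError):
            zscore_expression(make_expr([[-1.0, 2.0]]), log_transform=True)
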