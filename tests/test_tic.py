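"""Tests of the feature split, Boruta selection, PC1 scoring, projection and
the maximally selected survival cutpoint."""

import numpy as np
import pandas as pd
import pytest

import ticscore as ts
from ticscore.tic import _ordered_cluster_code


def _split_fixture(seed=0, n=60, n_up=2, n_down=1):
    """Genes tracking the cluster gradient up, down, and not at all.

    The up-program is larger than the down-program so the mean-z cluster
    ordering is anchored (with perfectly balanced programs the ordering is
    still deterministic but data-noise-driven).
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(np.repeat(["x", "y", "z"], n // 3),
                       index=[f"s{i}" for i in range(n)])
    grade = labels.map({"x": 0.0, "y": 1.0, "z": 2.0}).to_numpy()
    cols = {f"up{i}": grade + rng.normal(0, 0.05, n) for i in range(n_up)}
    cols |= {f"down{i}": -grade + rng.normal(0, 0.05, n) for i in range(n_down)}
    cols["flat"] = rng.normal(0, 1.0, n)
    expr = pd.DataFrame(cols, index=labels.index).T
    return expr, labels


class TestSplitFeatures:
    def test_gradient_genes_assigned_by_sign(self):
        expr, labels = _split_fixture()
        split = ts.split_features(expr, labels)
        assert "up0" in split.alpha_genes
        assert "down0" in split.beta_genes
        # ties in the 3-level code cap |rho| below 1 even for a perfect gradient
        assert split.correlations["up0"] > 0.9
        assert split.correlations["down0"] < -0.9

    def test_alpha_beta_disjoint_nonempty_on_default_cohort(self, default_analysis):
        split = default_analysis.split
        assert split.alpha_genes and split.beta_genes
        assert not set(split.alpha_genes) & set(split.beta_genes)

    def test_single_cluster_rejected(self):
        expr, labels = _split_fixture()
        with pytest.raises(ValueError):
            ts.split_features(expr, pd.Series("x", index=labels.index))

    def test_interior_peak_gene_excluded(self):
        # gradient genes dominate the ordering; the interior-peak gene has no
        # direction along it and must be excluded
        expr, labels = _split_fixture(n_up=5, n_down=2)
        grade = labels.map({"x": 0.0, "y": 1.0, "z": 2.0}).to_numpy()
        peak = pd.DataFrame(
            {"peak": np.where(grade == 1.0, 3.0, 0.0)
             + np.random.default_rng(1).normal(0, 0.05, len(labels))},
            index=labels.index,
        ).T
        split = ts.split_features(pd.concat([expr, peak]), labels)
        assert "peak" not in split.alpha_genes + split.beta_genes
        assert len(split.alpha_genes) == 5 and len(split.beta_genes) == 2

    def test_cluster_code_orders_by_mean_expression(self):
        expr, labels = _split_fixture()
        code = _ordered_cluster_code(expr, labels)
        # 'z' samples sit highest on the mean z over genes (up dominates down?
        # no: symmetric) -> check ordering is deterministic and complete
        assert sorted(code.unique()) == [1, 2, 3]
        assert code.groupby(labels).nunique().eq(1).all()


class TestBoruta:
    def test_shadow_count_equals_real_count(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 7)))
        y = (X[0] > 0).astype(int)
        res = ts.boruta_select(X, y, max_iter=12, seed=0)
        assert res.importance_history.shape[1] == 7
        assert len(res.shadow_max_history) == res.n_iterations

    def test_planted_feature_confirmed_noise_rejected(self):
        ok = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(40 + seed)
            X = pd.DataFrame(rng.normal(size=(200, 21)),
                             columns=[f"f{i}" for i in range(21)])
            y = (X["f0"] > X["f0"].median()).astype(int)
            res = ts.boruta_select(X, y, max_iter=50, seed=seed)
            noise_rejected = (res.status.iloc[1:] == "rejected").mean()
            ok += (res.status["f0"] == "confirmed") and noise_rejected >= 0.9
        assert ok >= 4

    def test_null_rarely_confirms(self):
        clean = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(85 + seed)
            X = pd.DataFrame(rng.normal(size=(200, 20)))
            y = rng.integers(0, 2, size=200)
            res = ts.boruta_select(X, y, max_iter=40, seed=seed)
            clean += (res.status == "confirmed").sum() == 0
        assert clean >= 4

    def test_contract_errors(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="samples"):
            ts.boruta_select(X, [0, 1, 0, 1])
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="classes"):
            ts.boruta_select(X, np.zeros(20))
        with pytest.raises(ValueError, match="max_iter"):
            ts.boruta_select(X, np.r_[np.zeros(10), np.ones(10)], max_iter=5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 6)))
        y = (X[0] + X[1] > 0).astype(int)
        r1 = ts.boruta_select(X, y, max_iter=15, seed=9)
        r2 = ts.boruta_select(X, y, max_iter=15, seed=9)
        assert (r1.status == r2.status).all()


class TestFitProject:
    def test_single_gene_sets_reduce_to_zscores(self):
        # with one gene per feature set, each PC1 is exactly that gene's
        # z-score and the score is their difference
        expr, labels = _split_fixture(seed=2, n_up=1, n_down=1)
        # anchor the ordering with an extra up gene, then drop it from the fit
        anchor = expr.loc[["up0"]].rename(index={"up0": "up_anchor"})
        full = pd.concat([expr, anchor])
        split = ts.split_features(full, labels)
        split.alpha_genes.remove("up_anchor")
        assert split.alpha_genes == ["up0"] and split.beta_genes == ["down0"]
        model = ts.fit_tic(expr, split)

        def z(row):
            v = expr.loc[row].to_numpy()
            return (v - v.mean()) / v.std()

        assert np.allclose(model.train_scores.to_numpy(), z("up0") - z("down0"),
                           atol=1e-9)

    def test_training_scores_centered(self, default_analysis):
        assert abs(default_analysis.scores.mean()) < 1e-9

    def test_constant_expression_shift_leaves_scores_unchanged(self):
        expr, labels = _split_fixture(seed=3)
        split = ts.split_features(expr, labels)
        m1 = ts.fit_tic(expr, split)
        m2 = ts.fit_tic(expr + 7.5, split)
        assert np.allclose(m1.train_scores, m2.train_scores, atol=1e-9)

    def test_self_projection_reproduces_training_scores(self, default_analysis):
        proj = ts.project_tic(default_analysis.model,
                              default_analysis.expr_log.values)
        assert np.allclose(proj.to_numpy(),
                           default_analysis.scores.to_numpy(), atol=1e-9)

    def test_excessive_missingness_rejected(self, default_analysis):
        model = default_analysis.model
        keep = list(model.genes[: int(len(model.genes) * 0.6)])
        with pytest.raises(ValueError, match="%"):
            ts.project_tic(model, default_analysis.expr_log.values.loc[keep])

    def test_empty_feature_set_named(self):
        expr, labels = _split_fixture(seed=4)
        split = ts.split_features(expr, labels)
        split.beta_genes.clear()
        with pytest.raises(ValueError, match="beta"):
            ts.fit_tic(expr, split)

    def test_model_json_roundtrip(self, default_analysis, tmp_path):
        path = tmp_path / "model.json"
        default_analysis.model.to_json(path)
        back = ts.TICModel.from_json(path)
        assert np.allclose(back.alpha_loadings, default_analysis.model.alpha_loadings)
        proj = ts.project_tic(back, default_analysis.expr_log.values)
        assert np.allclose(proj, default_analysis.scores, atol=1e-6)


def _bimodal_survival(seed, n=120, gap=4.0):
    rng = np.random.default_rng(seed)
    mode = rng.integers(0, 2, size=n)
    scores = pd.Series(rng.normal(mode * gap, 1.0),
                       index=[f"s{i}" for i in range(n)])
    lam = np.where(mode == 1, 1 / 2000, 1 / 400)
    t = rng.exponential(1 / lam)
    c = rng.exponential(1500, size=n)
    surv = pd.DataFrame(
        {"OS_time_days": np.minimum(t, c).clip(min=0.001),
         "OS_event": (t <= c).astype(int)},
        index=scores.index,
    )
    return scores, surv, gap


class TestOptimalCutpoint:
    def test_cut_falls_between_planted_modes(self):
        good = 0
        n_seeds = 30
        for seed in range(n_seeds):
            scores, surv, gap = _bimodal_survival(seed)
            cut = ts.optimal_cutpoint(scores, surv)
            good += 1.0 < cut.cutoff < gap - 1.0
        assert good / n_seeds >= 0.9

    def test_candidates_respect_percentile_bounds(self):
        scores, surv, _ = _bimodal_survival(99)
        cut = ts.optimal_cutpoint(scores, surv)
        n = len(scores)
        high = (scores > cut.cutoff).sum()
        assert min(high, n - high) >= 0.1 * n * 0.9

    def test_null_scan_is_anticonservative(self):
        """Independent score and survival: the unadjusted minimum p over the
        scan rejects more often than nominal (the logged caveat)."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            scores = pd.Series(rng.normal(size=60),
                               index=[f"s{i}" for i in range(60)])
            t = rng.exponential(100, size=60)
            surv = pd.DataFrame(
                {"OS_time_days": t, "OS_event": np.ones(60, int)},
                index=scores.index,
            )
            cut = ts.optimal_cutpoint(scores, surv)
            rejections += cut.pvalue < 0.05
        assert rejections / n_seeds > 0.05

    def test_degenerate_inputs_rejected(self):
        idx = [f"s{i}" for i in range(12)]
        surv = pd.DataFrame(
            {"OS_time_days": np.arange(1, 13), "OS_event": 1}, index=idx
        )
        with pytest.raises(ValueError, match="identical"):
            ts.optimal_cutpoint(pd.Series(1.0, index=idx), surv)
        surv0 = surv.assign(OS_event=0)
        with pytest.raises(ValueError, match="events"):
            ts.optimal_cutpoint(pd.Series(np.arange(12.0), index=idx), surv0)
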