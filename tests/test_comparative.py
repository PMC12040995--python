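import numpy as np
import pytest
import scipy.special

import dendropy

from ectonet.comparative import (
    add_sister_tip,
    all_subsets_pgls,
    beta_glmm_roles,
    beta_regression,
    adjust_proportions,
    _marginal_loglik,
    pgls_fit,
    phylo_covariance,
    read_newick,
    sex_difference_predictor,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestSexDifferencePredictor:
    @pytest.mark.parametrize(
        "f,m,expected",
        [(0.4, 0.4, 0.0), (0.2, 0.4, np.log(2)), (0.4, 0.2, np.log(2))],
    )
    def test_examples_and_symmetry(self, f, m, expected):
        assert sex_difference_predictor(f, m) == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sex_difference_predictor(0.0, 0.4)


class TestPhyloCovariance:
    def test_star_tree_unit_branches_identity(self):
        pc = phylo_covariance(_tree("(A:3,B:1,C:2);"), unit_branches=True)
        assert pc.C == pytest.approx(np.eye(3))

    def test_cherry_plus_outgroup(self):
        pc = phylo_covariance(_tree("((A:1,B:1):1,C:1);"), unit_branches=True)
        idx = {t: i for i, t in enumerate(pc.tips)}
        assert pc.C[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert pc.C[idx["A"], idx["C"]] == pytest.approx(0.0)
        assert np.diag(pc.C)[idx["A"]] == pytest.approx(2.0)
        assert np.diag(pc.C)[idx["C"]] == pytest.approx(1.0)

    def test_branch_lengths_respected_without_unit_flag(self):
        pc = phylo_covariance(_tree("((A:1,B:1):2,C:3);"))
        idx = {t: i for i, t in enumerate(pc.tips)}
        assert pc.C[idx["A"], idx["B"]] == pytest.approx(2.0)
        assert np.diag(pc.C) == pytest.approx([3.0, 3.0, 3.0])

    def test_matches_r_ape_vcv_when_available(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        nwk = "((A:1.5,B:1.5):0.5,(C:1,D:1):1);"
        pc = phylo_covariance(_tree(nwk))
        script = (
            'suppressMessages(library(ape));'
            f't <- read.tree(text="{nwk}");'
            'v <- vcv(t); cat(rownames(v), "\\n"); write.table(v, row.names=FALSE, col.names=FALSE)'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        lines = out.stdout.strip().splitlines()
        order = lines[0].split()
        ref = np.loadtxt(lines[1:])
        idx = [pc.tips.index(t) for t in order]
        assert pc.C[np.ix_(idx, idx)] == pytest.approx(ref, abs=1e-8)

    def test_subset_missing_species_listed(self):
        pc = phylo_covariance(_tree("(A:1,B:1);"))
        with pytest.raises(ValueError, match="ghost"):
            pc.subset(["A", "ghost"])

    def test_add_sister_tip_unit_cherry(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        add_sister_tip(tree, "A", "A2")
        pc = phylo_covariance(tree)
        idx = {t: i for i, t in enumerate(pc.tips)}
        assert pc.C[idx["A"], idx["A2"]] == pytest.approx(2.0)
        assert pc.C[idx["A"], idx["A"]] == pytest.approx(3.0)

    def test_read_newick_rejects_duplicate_tips(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,A:1);")
        with pytest.raises(ValueError, match="duplicate"):
            read_newick(p)


class TestPGLS:
    def test_identity_covariance_equals_ols(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ np.array([1.0, 2.0, -0.5]) + rng.normal(size=n)
        fit = pgls_fit(y, X, np.eye(n))
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        assert fit.beta == pytest.approx(ols.params, abs=1e-10)
        assert fit.se == pytest.approx(ols.bse, abs=1e-10)
        assert fit.r2 == pytest.approx(ols.rsquared, abs=1e-10)

    def test_exact_linear_fit(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = 3.0 + 2.0 * np.arange(n)
        fit = pgls_fit(y, X, np.eye(n))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.beta == pytest.approx([3.0, 2.0])

    def test_collinear_design_rejected(self, rng):
        n = 20
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            pgls_fit(rng.normal(size=n), X, np.eye(n))

    def test_singular_covariance_rejected(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        C = np.ones((n, n))  # rank 1
        with pytest.raises(ValueError, match="singular"):
            pgls_fit(rng.normal(size=n), X, C)

    def test_brownian_slope_recovery(self, rng):
        """GLS under the true tree covariance is unbiased for the slope."""
        from ectonet.synthdata import yule_tree

        tree = yule_tree([f"s{i}" for i in range(40)], seed=5)
        C = phylo_covariance(tree).C
        Lchol = np.linalg.cholesky(C + 1e-10 * np.eye(40))
        ests = []
        for _ in range(100):
            x = rng.normal(size=40)
            y = 2.0 * x + Lchol @ rng.normal(size=40)
            fit = pgls_fit(y, np.column_stack([np.ones(40), x]), C + 1e-10 * np.eye(40))
            ests.append(fit.beta[1])
        assert np.mean(ests) == pytest.approx(2.0, abs=0.1)


class TestAllSubsets:
    def test_single_predictor_two_models(self, rng):
        n = 15
        preds = {"a": rng.normal(size=n)}
        _, ranking = all_subsets_pgls(rng.normal(size=n), preds, np.eye(n))
        assert len(ranking) == 2
        assert ranking[0]["delta_aic"] == 0.0

    def test_sixteen_models_for_four_predictors(self, rng):
        n = 25
        preds = {k: rng.normal(size=n) for k in "abcd"}
        _, ranking = all_subsets_pgls(rng.normal(size=n), preds, np.eye(n))
        assert len(ranking) == 16

    def test_true_predictor_selected(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 2.0 * x + 0.2 * rng.normal(size=n)
        preds = {"signal": x, "noise": rng.normal(size=n)}
        best, _ = all_subsets_pgls(y, preds, np.eye(n))
        assert "signal" in best.names

    def test_null_response_prefers_intercept_only(self, rng):
        wins = 0
        for _ in range(50):
            n = 30
            preds = {k: rng.normal(size=n) for k in "ab"}
            _, ranking = all_subsets_pgls(rng.normal(size=n), preds, np.eye(n))
            wins += ranking[0]["subset"] == "(intercept)"
        assert wins >= 25  # majority under the null

    def test_aic_shift_invariance_under_scaling(self, rng):
        n = 20
        preds = {"a": rng.normal(size=n), "b": rng.normal(size=n)}
        y = rng.normal(size=n)
        _, r1 = all_subsets_pgls(y, preds, np.eye(n))
        _, r2 = all_subsets_pgls(2.5 * y, preds, np.eye(n))
        d1 = {row["subset"]: row["delta_aic"] for row in r1}
        d2 = {row["subset"]: row["delta_aic"] for row in r2}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-8)


class TestBetaModels:
    def _sim(self, rng, shift=0.8, phi=30.0, sigma=0.5, G=20):
        b = rng.normal(0, sigma, G)
        y, sex, grp = [], [], []
        for g in range(G):
            for sx, s in (("F", 0.0), ("M", shift)):
                mu = scipy.special.expit(-1.0 + s + b[g])
                y.append(rng.beta(mu * phi, (1 - mu) * phi))
                sex.append(sx)
                grp.append(g)
        y = np.array(y)
        X = np.column_stack([np.ones(len(y)), (np.array(sex) == "M").astype(float)])
        return y, X, np.array(grp)

    def test_adjust_proportions_offsets_boundary(self):
        out = adjust_proportions(np.array([0.0, 0.5, 1.0]))
        assert out == pytest.approx([1e-7, 0.5, 1 - 1e-7])

    def test_glmm_at_zero_variance_matches_beta_regression(self, rng):
        y, X, grp = self._sim(rng, sigma=0.0)
        fe = beta_regression(y, X)
        ll0 = _marginal_loglik(
            adjust_proportions(y), X, grp, fe["beta"], fe["phi"], 1e-8
        )
        assert ll0 == pytest.approx(fe["loglik"], abs=1e-6)

    def test_no_sex_effect_detected_as_null(self, rng):
        y, X, grp = self._sim(rng, shift=0.0)
        fit = beta_glmm_roles(y, X, grp)
        assert abs(fit["beta"][1]) < 0.5
        assert fit["p"][1] > 0.01

    def test_glmm_nests_fixed_effects_model(self, rng):
        y, X, grp = self._sim(rng)
        fit = beta_glmm_roles(y, X, grp)
        fe = beta_regression(y, X)
        if not fit["collapsed"]:
            assert fit["loglik"] >= fe["loglik"] - 1e-6

    def test_laplace_close_to_adaptive_quadrature(self, rng):
        y, X, grp = self._sim(rng)
        lap = beta_glmm_roles(y, X, grp, n_agh=1)
        agh = beta_glmm_roles(y, X, grp, n_agh=7)
        assert lap["beta"][1] == pytest.approx(agh["beta"][1], abs=0.05)

    def test_shift_recovery(self, rng):
        ests = [self._fit_shift(rng) for _ in range(30)]
        assert np.mean(ests) == pytest.approx(0.8, abs=0.15)

    def _fit_shift(self, rng):
        y, X, grp = self._sim(rng)
        return beta_glmm_roles(y, X, grp)["beta"][1]

    def test_single_species_rejected(self, rng):
        y = rng.beta(2, 2, 4)
        X = np.column_stack([np.ones(4), [0, 1, 0, 1]])
        with pytest.raises(ValueError, match="species"):
            beta_glmm_roles(y, X, np.zeros(4, dtype=int))
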