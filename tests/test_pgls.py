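import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.linalg import solve_triangular

from conftest import random_tree
from migbrain import pgls, simulate
from migbrain.tree import phylo_vcv, read_newick, transform_branch_lengths


def _design(rng, n, slope=0.5):
    x = rng.normal(0, 1, n)
    return x


class TestOLSLimits:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(0)
        tree = transform_branch_lengths(random_tree(40, rng), "grafen")
        x = rng.normal(0, 1, 40)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, 40)
        fit = pgls.pgls_fit(y, x[:, None], tree, species=tree.tip_labels,
                            estimate_lambda=False, lam=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, ols.params, atol=1e-8)
        np.testing.assert_allclose(fit.standard_errors, ols.bse, atol=1e-8)

    def test_star_tree_equals_ols_for_any_lambda(self):
        rng = np.random.default_rng(1)
        n = 25
        tree = read_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")
        x = rng.normal(0, 1, n)
        y = 2.0 - 0.3 * x + rng.normal(0, 0.5, n)
        fit = pgls.pgls_fit(y, x[:, None], tree, species=tree.tip_labels)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, ols.params, atol=1e-8)


class TestGLSOracle:
    def test_five_tip_tree_matches_direct_gls_solve(self):
        # brute-force GLS with the explicit VCV at lambda = 1
        rng = np.random.default_rng(2)
        tree = random_tree(5, rng)
        V = phylo_vcv(tree).matrix
        x = rng.normal(0, 1, 5)
        y = rng.normal(0, 1, 5)
        X = np.column_stack([np.ones(5), x])
        Vi = np.linalg.inv(V)
        beta_direct = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        fit = pgls.pgls_fit(y, x[:, None], tree, species=tree.tip_labels,
                            estimate_lambda=False, lam=1.0)
        np.testing.assert_allclose(fit.coefficients, beta_direct, atol=1e-8)

    def test_profile_peak_beats_endpoints(self):
        rng = np.random.default_rng(3)
        tree = transform_branch_lengths(random_tree(60, rng), "grafen")
        y = simulate.simulate_continuous(tree, 0.7, 1.0, seed=5).to_numpy()
        x = rng.normal(0, 1, 60)
        est = pgls.pgls_fit(y, x[:, None], tree, species=tree.tip_labels)
        at0 = pgls.pgls_fit(y, x[:, None], tree, species=tree.tip_labels,
                            estimate_lambda=False, lam=0.0)
        at1 = pgls.pgls_fit(y, x[:, None], tree, species=tree.tip_labels,
                            estimate_lambda=False, lam=1.0)
        assert est.log_likelihood >= at0.log_likelihood - 1e-9
        assert est.log_likelihood >= at1.log_likelihood - 1e-9


class TestPartialR2:
    def test_zero_effect_gives_near_zero(self):
        rng = np.random.default_rng(4)
        tree = transform_branch_lengths(random_tree(80, rng), "grafen")
        y = simulate.simulate_continuous(tree, 0.5, 1.0, seed=6).to_numpy()
        x = rng.normal(0, 1, 80)   # unrelated focal predictor
        z = rng.normal(0, 1, 80)
        X = np.column_stack([x, z])
        full = pgls.pgls_fit(y, X, tree, species=tree.tip_labels,
                             names=["focal", "other"])
        red = pgls.pgls_fit(y, z[:, None], tree, species=tree.tip_labels,
                            names=["other"])
        assert pgls.partial_r2(full, red) < 0.08

    def test_perfect_predictor_gives_one(self):
        rng = np.random.default_rng(5)
        tree = transform_branch_lengths(random_tree(30, rng), "grafen")
        x = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        y = 2 * x            # exactly explained by the focal predictor
        full = pgls.pgls_fit(y, np.column_stack([x, z]), tree,
                             species=tree.tip_labels,
                             estimate_lambda=False, lam=0.5)
        red = pgls.pgls_fit(y, z[:, None], tree, species=tree.tip_labels,
                            estimate_lambda=False, lam=0.5)
        assert pgls.partial_r2(full, red) == pytest.approx(1.0, abs=1e-6)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(6)
        tree = transform_branch_lengths(random_tree(20, rng), "grafen")
        y = rng.normal(0, 1, 20)
        f = pgls.pgls_fit(y, rng.normal(0, 1, (20, 1)), tree,
                          species=tree.tip_labels)
        with pytest.raises(ValueError):
            pgls.partial_r2(f, f)


class TestInputValidation:
    def test_species_mismatch_names_offenders(self):
        rng = np.random.default_rng(7)
        tree = transform_branch_lengths(random_tree(10, rng), "grafen")
        y = rng.normal(0, 1, 10)
        labels = list(tree.tip_labels)
        labels[0] = "nessie"
        with pytest.raises(ValueError, match="nessie"):
            pgls.pgls_fit(y, rng.normal(0, 1, (10, 1)), tree, species=labels)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(8)
        tree = transform_branch_lengths(random_tree(12, rng), "grafen")
        x = rng.normal(0, 1, 12)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="singular"):
            pgls.pgls_fit(rng.normal(0, 1, 12), X, tree,
                          species=tree.tip_labels)

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(9)
        tree = transform_branch_lengths(random_tree(12, rng), "grafen")
        y = rng.normal(0, 1, 12)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pgls.pgls_fit(y, rng.normal(0, 1, (12, 1)), tree,
                          species=tree.tip_labels)


class TestSubsetAnalysis:
    def test_groups_fit_and_small_groups_skipped(self):
        st = simulate.simulate_study(simulate.StudyTruth(n_tips=120, seed=11))
        t = st.table.copy()
        t["log_brain"] = np.log(t["brain_mass_g"])
        # make one family artificially tiny
        t.loc[t["family"] == "famF", "family"] = "famA"
        t.loc[t.index[:4], "family"] = "famTiny"
        res = pgls.subset_analysis(
            t, st.tree, "family", response="log_brain",
            predictors=["migration_category"], min_species=10,
        )
        assert any(isinstance(v, str) and "skipped" in v for v in res.values())
        fitted = [v for v in res.values() if not isinstance(v, str)]
        assert fitted and all(f.n_species >= 10 for f in fitted)

    def test_listwise_deletion_counts(self):
        st = simulate.simulate_study(simulate.StudyTruth(n_tips=80, seed=12))
        t = st.table.copy()
        t["log_brain"] = np.log(t["brain_mass_g"])
        t.loc[t.index[:7], "migration_category"] = np.nan
        complete = t.dropna(subset=["log_brain", "migration_category"])
        fit = pgls.pgls_fit(
            complete["log_brain"].to_numpy(),
            complete[["migration_category"]].set_index(complete["species"]),
            st.tree, species=list(complete["species"]),
        )
        assert fit.n_species == len(t) - 7


class TestRecovery:
    def test_brownian_simulation_recovers_slope_and_lambda(self):
        # short replicate check; the full calibration lives in the
        # acceptance suite
        hits_beta, high_lambda = 0, 0
        reps = 10
        for r in range(reps):
            st = simulate.simulate_study(
                simulate.StudyTruth(n_tips=200, lambda_true=1.0, seed=100 + r))
            t = st.table
            y = np.log(t["brain_mass_g"].to_numpy())
            X = pd.DataFrame({
                "migration": t["migration_category"].to_numpy(),
                "log_body": np.log(t["body_mass_g"].to_numpy()),
            }, index=t["species"])
            fit = pgls.pgls_fit(y, X, st.tree, species=list(t["species"]))
            i = fit.names.index("migration")
            if abs(fit.coefficients[i] - (-0.025)) <= 2 * fit.standard_errors[i]:
                hits_beta += 1
            if fit.lambda_hat > 0.8:
                high_lambda += 1
        assert hits_beta >= 8
        assert high_lambda >= 8
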