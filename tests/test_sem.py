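import numpy as np
import pandas as pd
import pytest

from conftest import tracing_correlation
from migbrain import sem, simulate


@pytest.fixture(scope="module")
def path_data():
    df, truth = simulate.simulate_path_data(600, seed=1)
    return df, truth


@pytest.fixture(scope="module")
def preset_a():
    return sem.candidate_models()[0]


class TestModelSpec:
    def test_parse_and_classify(self):
        m = sem.parse_model("X -> Y\nZ -> Y\nX ~~ Z")
        assert m.endogenous() == ["Y"]
        assert sorted(m.exogenous()) == ["X", "Z"]
        # 6 moments vs 2 edges + 2 exo variances + 1 covariance + 1 error
        assert m.degrees_of_freedom() == 0

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            sem.parse_model("X -> Y\nY -> X")

    def test_endogenous_covariance_rejected(self):
        with pytest.raises(ValueError, match="endogenous"):
            sem.parse_model("X -> Y\nY ~~ X")

    def test_comments_and_blank_lines(self):
        m = sem.parse_model("# top\nX -> Y # arrow\n\nZ -> Y\n")
        assert len(m.edges) == 2


class TestSemFit:
    def test_saturated_model_fits_perfectly(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("XZY"))
        # fully saturated recursive model: 3 edges + 2 exo (var+cov) + ...
        m = sem.parse_model("X -> Y\nZ -> Y\nX -> Z")
        assert m.degrees_of_freedom() == 0
        fit = sem.sem_fit(m, d)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        obs = np.corrcoef(d.to_numpy(), rowvar=False)
        got = fit.implied_correlation.loc[list("XZY"), list("XZY")].to_numpy()
        idx = [list(d.columns).index(v) for v in "XZY"]
        np.testing.assert_allclose(got, obs[np.ix_(idx, idx)], atol=1e-4)

    def test_single_path_equals_pearson_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        y = 0.6 * x + rng.standard_normal(400)
        z = rng.standard_normal(400)  # isolated third variable
        d = pd.DataFrame({"X": x, "Y": y, "Z": z})
        m = sem.parse_model("X -> Y\nZ -> Y")
        fit = sem.sem_fit(m, d)
        r_xy = np.corrcoef(x, y)[0, 1]
        # Z nearly uncorrelated, so the X coefficient ~ partial ~ marginal r
        assert fit.coefficients[("X", "Y")] == pytest.approx(r_xy, abs=0.02)

    def test_coefficient_recovery(self, path_data, preset_a):
        df, truth = path_data
        fit = sem.sem_fit(preset_a, df)
        for edge, true_c in truth["coefficients"].items():
            got = fit.coefficients[edge]
            se = fit.coefficient_se[edge]
            assert abs(got - true_c) < max(3 * se, 0.05), edge

    def test_fiml_equals_complete_case_on_complete_data(self, path_data,
                                                        preset_a):
        df, _ = path_data
        a = sem.sem_fit(preset_a, df, use_missing=False)
        b = sem.sem_fit(preset_a, df, use_missing=True)
        for edge in a.coefficients:
            assert a.coefficients[edge] == pytest.approx(
                b.coefficients[edge], abs=1e-4)
        assert a.chi_square == pytest.approx(b.chi_square, abs=0.5)

    def test_fiml_uses_incomplete_rows(self, preset_a):
        df, _ = simulate.simulate_path_data(500, seed=3, missing_fraction=0.2)
        fit = sem.sem_fit(preset_a, df, use_missing=True)
        assert fit.n_effective > len(df.dropna())

    def test_unidentified_model_rejected(self):
        d = pd.DataFrame(np.random.default_rng(2).standard_normal((50, 3)),
                         columns=list("ABC"))
        m = sem.PathModel(variables=list("ABC"),
                          edges=[("A", "C"), ("B", "C"), ("A", "B")],
                          covariances=[])
        # add a spurious extra covariance to exceed the moment count
        m2 = sem.PathModel(variables=list("ABC"),
                           edges=[("A", "B"), ("A", "C"), ("B", "C")],
                           covariances=[])
        assert m2.degrees_of_freedom() == 0  # saturated is fine
        with pytest.raises(ValueError, match="at least 3"):
            sem.sem_fit(sem.parse_model("A -> B"), d)


class TestDecomposition:
    def test_chain_model_tracing(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.standard_normal(n)
        mzn = rng.standard_normal(n)
        mz = 0.7 * x + np.sqrt(1 - 0.49) * mzn
        y = 0.5 * mz + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        d = pd.DataFrame({"X": x, "M": mz, "Y": y})
        m = sem.parse_model("X -> M\nM -> Y")
        fit = sem.sem_fit(m, d)
        dec = sem.effect_decomposition(fit, "X", "Y")
        a = fit.coefficients[("X", "M")]
        b = fit.coefficients[("M", "Y")]
        assert dec["direct"] == 0.0
        assert dec["indirect"] == pytest.approx(a * b, abs=1e-9)
        assert dec["unanalyzed"] == pytest.approx(0.0, abs=1e-9)

    def test_direct_only_model_is_100_percent(self):
        rng = np.random.default_rng(5)
        n = 1000
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = -0.4 * x + 0.3 * z + rng.standard_normal(n)
        d = pd.DataFrame({"X": x, "Z": z, "Y": y})
        fit = sem.sem_fit(sem.parse_model("X -> Y\nZ -> Y"), d)
        dec = sem.effect_decomposition(fit, "X", "Y")
        # Z is sampled independently of X, so nothing is unanalyzed beyond
        # sampling noise and the direct path carries ~everything
        assert dec["percent_direct"] == pytest.approx(100.0, abs=8.0)

    def test_identity_direct_indirect_unanalyzed_total(self, path_data,
                                                       preset_a):
        df, _ = path_data
        fit = sem.sem_fit(preset_a, df)
        dec = sem.effect_decomposition(fit, "Migration", "Brain")
        assert (dec["direct"] + dec["indirect"] + dec["unanalyzed"]
                == pytest.approx(dec["total"], abs=1e-12))

    def test_implied_correlation_matches_wright_tracing_oracle(self,
                                                               path_data,
                                                               preset_a):
        df, _ = path_data
        fit = sem.sem_fit(preset_a, df)
        coefs = fit.coefficients
        exo = {("Latitude", "Body"): fit.exo_covariances[("Latitude", "Body")]}
        for x in preset_a.variables:
            for y in preset_a.endogenous():
                if x == y:
                    continue
                oracle = tracing_correlation(x, y, coefs, exo)
                assert fit.implied_correlation.loc[y, x] == pytest.approx(
                    oracle, abs=1e-6), (x, y)

    def test_target_must_be_endogenous(self, path_data, preset_a):
        df, _ = path_data
        fit = sem.sem_fit(preset_a, df)
        with pytest.raises(ValueError, match="endogenous"):
            sem.effect_decomposition(fit, "Brain", "Latitude")

    def test_truth_decomposition_near_published_share(self):
        # the default generating coefficients put ~69% of the
        # migration-brain correlation on the direct arrow
        truth = simulate.path_truth_decomposition()
        assert truth["percent_direct"] == pytest.approx(69.0, abs=1.0)


class TestModelComparison:
    def test_ranking_and_good_fit_flag(self, path_data):
        df, _ = path_data
        ranking = sem.compare_candidate_models(sem.candidate_models(), df)
        assert ranking.loc[0, "model"] == "A"   # generating structure wins
        assert bool(ranking.loc[0, "good_fit"])
        assert set(ranking["model"]) == {"A", "B", "C", "D"}

    def test_failure_reported_not_fatal(self, path_data):
        df, _ = path_data
        broken = sem.PathModel(
            variables=["Latitude", "Body", "Brain", "NotAColumn"],
            edges=[("Latitude", "Brain"), ("Body", "Brain"),
                   ("NotAColumn", "Brain")],
        )
        ranking = sem.compare_candidate_models(
            [broken, sem.candidate_models()[0]], df)
        row = ranking[ranking["model"] == "model"].iloc[0]
        assert row["error"] != ""

    def test_needs_two_models(self, path_data):
        df, _ = path_data
        with pytest.raises(ValueError):
            sem.compare_candidate_models([sem.candidate_models()[0]], df)
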