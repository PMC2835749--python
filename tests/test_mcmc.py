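import numpy as np
import pytest
from scipy import stats

from migbrain import ctmc, mcmc, simulate
from migbrain.tree import read_newick, transform_branch_lengths


@pytest.fixture(scope="module")
def small_tree():
    return transform_branch_lengths(simulate.simulate_tree(40, seed=1), "unit")


@pytest.fixture(scope="module")
def big_tree():
    return transform_branch_lengths(simulate.simulate_tree(300, seed=5),
                                    "unit")


@pytest.fixture(scope="module")
def big_states(big_tree):
    m = ctmc.PairedBinaryModel(
        kind="dependent",
        rates={"q12": 0.05, "q13": 0.0, "q21": 0.05, "q24": 0.05,
               "q31": 0.05, "q34": 0.05, "q42": 0.05, "q43": 0.5})
    return ctmc.simulate_pair(big_tree, m, root_state=2, seed=6)


@pytest.fixture(scope="module")
def small_states(small_tree):
    m = ctmc.PairedBinaryModel(
        kind="dependent",
        rates={"q12": 0.05, "q13": 0.0, "q21": 0.05, "q24": 0.05,
               "q31": 0.05, "q34": 0.05, "q42": 0.05, "q43": 0.5})
    return ctmc.simulate_pair(small_tree, m, root_state=2, seed=2)


FAST = dict(iterations=4000, burn_in=1000, thinning=3)


class TestMetropolis:
    def test_prior_only_sampling_matches_exponential_prior(self, small_tree,
                                                           small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "independent",
                             prior_rate_mean=10.0, iterations=32_000,
                             burn_in=2000, thinning=3, seed=7,
                             likelihood_off=True)
        draws = s.rates.ravel()
        ks = stats.kstest(draws, "expon", args=(0, 10.0)).statistic
        assert ks < 0.05

    def test_identical_tips_pull_rates_below_prior_mean(self, small_tree):
        states = ctmc.JointTraitStates(
            states={lab: 1 for lab in small_tree.tip_labels})
        s = mcmc.mcmc_sample(small_tree, states, "independent",
                             prior_rate_mean=10.0, seed=3, **FAST)
        assert s.rates.mean() < 10.0

    def test_bit_identical_under_fixed_seed(self, small_tree, small_states):
        a = mcmc.mcmc_sample(small_tree, small_states, "dependent", seed=11,
                             **FAST)
        b = mcmc.mcmc_sample(small_tree, small_states, "dependent", seed=11,
                             **FAST)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.log_likelihoods, b.log_likelihoods)

    def test_draw_count_contract(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "independent",
                             iterations=3000, burn_in=600, thinning=4, seed=0)
        assert s.n_draws == (3000 - 600) // 4

    def test_posterior_detects_rate_asymmetry(self, big_tree, big_states):
        # data generated with q43 = 10 x q34 on a tree large enough to
        # carry the signal
        s = mcmc.mcmc_sample(big_tree, big_states, "dependent", seed=5,
                             iterations=8000, burn_in=2000, thinning=3)
        freq = mcmc.rate_inequality_summary(s, [("q43", "q34")])
        assert freq["q43>q34"] > 0.9

    def test_invalid_settings_rejected(self, small_tree, small_states):
        with pytest.raises(ValueError):
            mcmc.mcmc_sample(small_tree, small_states, "independent",
                             iterations=100, burn_in=200, seed=0)


class TestRJ:
    def test_true_zero_rate_occupies_zero_bin(self, small_tree, small_states):
        # q13 = 0 in the generating model
        s = mcmc.rj_mcmc(small_tree, small_states, seed=21,
                         iterations=12_000, burn_in=3000, thinning=3)
        occ = s.zero_bin_occupancy()
        prior = mcmc.rj_mcmc(small_tree, small_states, seed=22,
                             likelihood_off=True, **FAST)
        prior_occ = np.mean(list(prior.zero_bin_occupancy().values()))
        assert occ["q13"] > 2 * prior_occ
        assert occ["q13"] > 0.4

    def test_equal_rates_favor_few_bins(self):
        tree = transform_branch_lengths(simulate.simulate_tree(60, seed=31),
                                        "unit")
        m = ctmc.PairedBinaryModel(
            kind="dependent", rates={k: 0.15 for k in ctmc.DEP_RATE_NAMES})
        states = ctmc.simulate_pair(tree, m, root_state=1, seed=32)
        s = mcmc.rj_mcmc(tree, states, seed=33, iterations=12_000,
                         burn_in=3000, thinning=3)
        n_bins = [len(set(p.split(","))) for p in s.partitions]
        # modal bin count well below the saturated 8-bin model
        assert np.median(n_bins) <= 4

    def test_bit_identical_under_fixed_seed(self, small_tree, small_states):
        a = mcmc.rj_mcmc(small_tree, small_states, seed=44, **FAST)
        b = mcmc.rj_mcmc(small_tree, small_states, seed=44, **FAST)
        assert np.array_equal(a.rates, b.rates)
        assert a.partitions == b.partitions

    def test_zero_bin_rates_are_exactly_zero(self, small_tree, small_states):
        s = mcmc.rj_mcmc(small_tree, small_states, seed=45, **FAST)
        for i, part in enumerate(s.partitions):
            for j, tag in enumerate(part.split(",")):
                if tag == "z":
                    assert s.rates[i, j] == 0.0


class TestEvidence:
    def test_identical_loglik_draws_return_that_value(self, small_tree,
                                                      small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "independent", seed=0,
                             **FAST)
        s.log_likelihoods = np.full(200, -12.5)
        assert mcmc.harmonic_mean_logml(s) == pytest.approx(-12.5)

    def test_two_draw_hand_arithmetic(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "independent", seed=0,
                             **FAST)
        s.log_likelihoods = np.array([np.log(1.0), np.log(1 / 3)])
        got = mcmc.harmonic_mean_logml(s, min_draws=2)
        assert got == pytest.approx(np.log(0.5), abs=1e-12)

    def test_too_few_draws_rejected(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "independent", seed=0,
                             **FAST)
        s.log_likelihoods = s.log_likelihoods[:10]
        with pytest.raises(ValueError):
            mcmc.harmonic_mean_logml(s)

    def test_band_assignment(self):
        assert mcmc._band(0.0) == "none"
        assert mcmc._band(3.0) == "positive"
        assert mcmc._band(7.0) == "strong"
        assert mcmc._band(12.0) == "very strong"

    def test_mismatched_data_rejected(self, small_tree, small_states):
        other = ctmc.JointTraitStates(
            states={lab: 1 for lab in small_tree.tip_labels})
        a = mcmc.mcmc_sample(small_tree, small_states, "dependent", seed=0,
                             **FAST)
        b = mcmc.mcmc_sample(small_tree, other, "independent", seed=0, **FAST)
        with pytest.raises(ValueError, match="different data"):
            mcmc.log_bayes_factor(a, b)

    def test_harmonic_mean_agrees_with_thermodynamic_integration(self):
        # 2-tip toy model, single free rate: compare the harmonic-mean
        # estimate with a power-posterior (thermodynamic integration)
        # estimate of the same marginal likelihood
        tree = read_newick("(A:1,B:1);")
        states = ctmc.JointTraitStates(states={"A": 1, "B": 4})
        prior_mean = 1.0

        def ll(q):
            m = ctmc.PairedBinaryModel(
                kind="independent",
                rates={"alpha1": q, "beta1": q, "alpha2": q, "beta2": q})
            return ctmc.loglik(tree, states, m)

        # thermodynamic integration over a fine grid by quadrature of
        # E_beta[logL], expectations computed by direct numeric integration
        qs = np.linspace(1e-6, 60, 4000)
        lls = np.array([ll(q) for q in qs])
        prior = stats.expon.pdf(qs, scale=prior_mean)
        betas = np.linspace(0, 1, 21)
        e_ll = []
        for b in betas:
            w = prior * np.exp(b * (lls - lls.max()))
            w /= np.trapezoid(w, qs)
            e_ll.append(np.trapezoid(w * lls, qs))
        ti = np.trapezoid(e_ll, betas)

        rng = np.random.default_rng(99)
        # posterior draws by rejection-free grid sampling (1 dim)
        post = prior * np.exp(lls - lls.max())
        post /= np.trapezoid(post, qs)
        cdf = np.cumsum(post) / post.sum()
        idx = np.searchsorted(cdf, rng.uniform(size=20_000))
        draw_ll = lls[np.clip(idx, 0, len(qs) - 1)]
        neg = -draw_ll
        m = neg.max()
        hm = -(m + np.log(np.exp(neg - m).sum()) - np.log(len(neg)))
        assert hm == pytest.approx(ti, abs=0.35)


class TestRootPosterior:
    def test_uniform_tips_with_high_retention_give_confident_root(
            self, small_tree):
        # all tips migratory + large-brained under a model that rarely
        # loses either state: the root must be that state too
        states = ctmc.JointTraitStates(
            states={lab: 4 for lab in small_tree.tip_labels})
        s = mcmc.mcmc_sample(small_tree, states, "dependent", seed=1, **FAST)
        s.rates = np.tile(np.full(8, 0.02), (s.n_draws, 1))  # high retention
        root = mcmc.root_state_posterior(s, small_tree, states)
        assert root["p_large_brain_mean"] > 0.95
        assert root["p_resident_mean"] < 0.05

    def test_symmetric_setup_gives_balanced_root(self, small_tree):
        # symmetric rates with perfectly ambiguous (uniform-prior) partials
        # at saturation: marginal root probabilities near 1/2
        states = ctmc.JointTraitStates(
            states={lab: (1 if i % 2 else 4)
                    for i, lab in enumerate(small_tree.tip_labels)})
        s = mcmc.mcmc_sample(small_tree, states, "dependent", seed=9, **FAST)
        s.rates = np.tile(np.full(8, 50.0), (s.n_draws, 1))
        root = mcmc.root_state_posterior(s, small_tree, states, max_draws=50)
        assert root["p_large_brain_mean"] == pytest.approx(0.5, abs=0.05)
        assert root["p_resident_mean"] == pytest.approx(0.5, abs=0.05)

    def test_probabilities_normalized(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "dependent", seed=2,
                             **FAST)
        root = mcmc.root_state_posterior(s, small_tree, small_states)
        assert root["joint_mean"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_recovers_true_root_state(self):
        hits = 0
        for rep in range(8):
            tree = transform_branch_lengths(
                simulate.simulate_tree(150, seed=200 + rep), "unit")
            m = ctmc.PairedBinaryModel(
                kind="dependent",
                rates={k: 0.03 for k in ctmc.DEP_RATE_NAMES})
            states = ctmc.simulate_pair(tree, m, root_state=2,
                                        seed=300 + rep)
            s = mcmc.mcmc_sample(tree, states, "dependent",
                                 seed=400 + rep, **FAST)
            root = mcmc.root_state_posterior(s, tree, states, max_draws=300)
            if int(np.argmax(root["joint_mean"])) + 1 == 2:
                hits += 1
        assert hits >= 5

    def test_inequality_complementarity(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "dependent", seed=3,
                             **FAST)
        f = mcmc.rate_inequality_summary(s, [("q12", "q21"), ("q21", "q12")])
        assert f["q12>q21"] + f["q21>q12"] <= 1.0

    def test_forced_ties_give_zero(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "dependent", seed=4,
                             **FAST)
        s.rates[:, s.rate_names.index("q12")] = 0.3
        s.rates[:, s.rate_names.index("q21")] = 0.3
        f = mcmc.rate_inequality_summary(s, [("q12", "q21")])
        assert f["q12>q21"] == 0.0

    def test_unknown_rate_name_rejected(self, small_tree, small_states):
        s = mcmc.mcmc_sample(small_tree, small_states, "independent", seed=5,
                             **FAST)
        with pytest.raises(KeyError):
            mcmc.rate_inequality_summary(s, [("q43", "q34")])


class TestMultiChain:
    def test_chains_agree_within_monte_carlo_error(self, small_tree,
                                                   small_states):
        chains = [mcmc.mcmc_sample(small_tree, small_states, "independent",
                                   seed=1000 + c, iterations=12_000,
                                   burn_in=3000, thinning=3)
                  for c in range(3)]
        means = np.array([c.rates.mean(axis=0) for c in chains])

        def batch_se(x, n_batches=20):
            # batch-means standard error, robust to autocorrelation
            b = len(x) // n_batches
            bm = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
            return bm.std(ddof=1) / np.sqrt(n_batches)

        ses = np.array([[batch_se(c.rates[:, j]) for j in range(4)]
                        for c in chains])
        for j in range(means.shape[1]):
            spread = means[:, j].max() - means[:, j].min()
            combined = np.sqrt((ses[:, j] ** 2).sum())
            assert spread <= 3 * combined + 0.05 * abs(means[:, j].mean())
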