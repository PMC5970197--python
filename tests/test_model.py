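import numpy as np
import pandas as pd
import pytest

import accesstf as a
from accesstf import model as md
from accesstf.errors import ConfigurationError, FitError


def make_params(**kw):
    base = dict(beta0=0.0, beta1=0.0, beta2=0.0, beta3=0.0, K0=1.0, r0=0.5, K1=5.0, r1=0.8)
    base.update(kw)
    return md.ModelParams(**base)


def feature_frame(f, d, c, n):
    return pd.DataFrame({"f": f, "d": d, "c": c, "n": n})


class TestNBPmf:
    def test_hand_values(self):
        assert md.nb_pmf(0, 1, 0.5) == pytest.approx(0.5)
        # C(2,1) * (1-0.5)^2 * 0.5^1 = 0.25
        assert md.nb_pmf(1, 2, 0.5) == pytest.approx(0.25)

    def test_normalization(self):
        n = np.arange(0, 2000)
        assert md.nb_pmf(n, 3, 0.7).sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_integer_size_allowed(self):
        p = md.nb_pmf(np.arange(500), 2.5, 0.3)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            md.nb_pmf(1, -1.0, 0.5)
        with pytest.raises(ConfigurationError):
            md.nb_pmf(1, 1.0, 1.5)


class TestLogisticPrior:
    def test_zero_coefficients_give_half(self):
        p = make_params()
        assert md.logistic_prior(p, 0.3, 0.9, 0.1) == pytest.approx(0.5)

    def test_closed_form(self):
        p = make_params(beta1=1.0)
        assert md.logistic_prior(p, 1.0, 0.0, 0.0) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_monotone_in_f_for_positive_beta1(self):
        p = make_params(beta1=2.0)
        f = np.linspace(0, 1, 50)
        y = md.logistic_prior(p, f, 0.5, 0.5)
        assert np.all(np.diff(y) > 0)


class TestInitialization:
    def test_exact_five_percent_with_distinct_counts(self):
        counts = np.arange(100)
        init = md.initialize_prior_states(counts)
        assert init.sum() == 5
        counts = np.arange(10000)
        assert md.initialize_prior_states(counts).sum() == 500

    def test_all_equal_counts_rejected(self):
        with pytest.raises(FitError):
            md.initialize_prior_states(np.full(100, 7))

    def test_ties_at_cutoff_included(self):
        counts = np.array([0] * 90 + [5] * 10)
        init = md.initialize_prior_states(counts)
        assert init.sum() == 10  # all tied top counts included


class TestEStep:
    def test_equal_emissions_return_prior(self):
        p = make_params(beta0=0.7, beta1=-0.3, K0=2.0, r0=0.6, K1=2.0, r1=0.6)
        rng = np.random.default_rng(0)
        feats = feature_frame(
            rng.uniform(0, 1, 200), rng.uniform(0, 1, 200), rng.uniform(0, 1, 200),
            rng.integers(0, 30, 200),
        )
        gamma = md.e_step(p, feats)
        y = md.logistic_prior(p, feats["f"], feats["d"], feats["c"])
        np.testing.assert_allclose(gamma, y, atol=1e-12)

    def test_bayes_arithmetic_three_to_one(self):
        # choose r's so the bound pmf at n=1 is exactly 3x the unbound pmf
        r0 = 0.05
        target = 3 * (1 - r0) * r0  # K=1 pmf at n=1 is (1-r) r
        r1 = (1 - np.sqrt(1 - 4 * target)) / 2
        p = make_params(K0=1.0, r0=r0, K1=1.0, r1=r1)  # betas 0 -> y = 0.5
        gamma = md.e_step(p, feature_frame([0.5], [0.5], [0.5], [1]))
        assert gamma[0] == pytest.approx(0.75, abs=1e-10)

    def test_posterior_monotone_in_n_vs_likelihood_ratio(self):
        p = make_params(K0=1.0, r0=0.4, K1=3.0, r1=0.8)
        n = np.arange(0, 60)
        feats = feature_frame(np.full(60, 0.5), np.full(60, 0.5), np.full(60, 0.5), n)
        gamma = md.e_step(p, feats)
        # brute-force likelihood ratio check: LR increasing implies gamma increasing
        lr = md.nb_pmf(n, 3.0, 0.8) / md.nb_pmf(n, 1.0, 0.4)
        assert np.all(np.diff(lr) > 0)
        assert np.all(np.diff(gamma) >= 0)
        unsaturated = gamma < 1 - 1e-12  # strictly increasing until it saturates
        assert np.all(np.diff(gamma[unsaturated]) > 0)


class TestMStep:
    def test_objective_never_decreases_over_random_starts(self):
        rng = np.random.default_rng(3)
        sc = a.SimulationScenario(n_motifs=800, seed=3)
        tab = a.simulate_motif_dataset(sc)
        for _ in range(10):
            gamma = rng.uniform(0, 1, len(tab))
            before = make_params(
                beta0=rng.normal(), beta1=rng.normal(), beta2=rng.normal(),
                beta3=rng.normal(), K0=rng.uniform(0.5, 5), r0=rng.uniform(0.2, 0.8),
                K1=rng.uniform(0.5, 5), r1=rng.uniform(0.2, 0.8),
            )
            after = md.m_step(tab, gamma, previous=before)
            assert md.expected_complete_loglik(after, tab, gamma) >= (
                md.expected_complete_loglik(before, tab, gamma) - 1e-6
            )

    def test_decoupled_case_matches_plain_logistic_fit(self):
        # equal emissions: the NB terms are constant in beta, so the M-step
        # betas are a plain logistic regression of gamma on (f, d, c)
        rng = np.random.default_rng(4)
        n = 2000
        feats = feature_frame(
            rng.uniform(0, 1, n), rng.uniform(0, 1, n), rng.uniform(0, 1, n),
            rng.integers(0, 10, n),
        )
        true = make_params(beta0=-1.0, beta1=2.0, beta2=0.5, beta3=-0.5)
        gamma = np.asarray(md.logistic_prior(true, feats["f"], feats["d"], feats["c"]))
        fitted = md.m_step(feats, gamma)
        # fractional-response logistic regression recovers the generating betas
        assert fitted.beta0 == pytest.approx(true.beta0, abs=0.05)
        assert fitted.beta1 == pytest.approx(true.beta1, abs=0.05)
        assert fitted.beta2 == pytest.approx(true.beta2, abs=0.05)
        assert fitted.beta3 == pytest.approx(true.beta3, abs=0.05)

    def test_separated_simulation_recovers_nb_means(self):
        sc = a.SimulationScenario(n_motifs=5000, seed=5)
        tab = a.simulate_motif_dataset(sc)
        params = md.m_step(tab, tab["b"].to_numpy(float))  # oracle responsibilities
        truth = sc.true_params
        assert params.bound_mean == pytest.approx(truth.bound_mean, rel=0.05)
        assert params.unbound_mean == pytest.approx(truth.unbound_mean, rel=0.05)


class TestFitEM:
    def test_loglik_non_decreasing_and_posterior_recovery(self):
        sc = a.SimulationScenario(n_motifs=10000, seed=6)
        tab = a.simulate_motif_dataset(sc)
        params, report = md.fit_em(tab, seed=6)
        ll = np.array(report.loglik)
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))
        assert report.converged
        gamma = md.e_step(params, tab)
        assert np.corrcoef(tab["gamma_true"], gamma)[0, 1] > 0.95

    def test_refit_from_converged_params_is_a_fixed_point(self):
        sc = a.SimulationScenario(n_motifs=3000, seed=7)
        tab = a.simulate_motif_dataset(sc)
        params, _ = md.fit_em(tab, seed=7)
        _, report2 = md.fit_em(tab, seed=7, init_gamma=md.e_step(params, tab))
        assert report2.iterations <= 2

    def test_initialization_robustness(self):
        # two admissible initializations agree on a well-separated simulation
        sc = a.SimulationScenario(n_motifs=5000, seed=8)
        tab = a.simulate_motif_dataset(sc)
        p1, _ = md.fit_em(tab, seed=8, top_fraction=0.05)
        p2, _ = md.fit_em(tab, seed=8, top_fraction=0.10)
        g1, g2 = md.e_step(p1, tab), md.e_step(p2, tab)
        assert np.mean(np.abs(g1 - g2)) < 0.02


class TestPredict:
    def test_prediction_equals_final_training_responsibilities(self):
        sc = a.SimulationScenario(n_motifs=2000, seed=9)
        tab = a.simulate_motif_dataset(sc)
        params, _ = md.fit_em(tab, seed=9)
        pred = md.predict(params, tab)
        np.testing.assert_allclose(pred["gamma"], md.e_step(params, tab), atol=1e-12)

    def test_zero_count_pulls_posterior_below_prior(self):
        p = make_params(beta0=-1.0, K0=1.0, r0=0.3, K1=5.0, r1=0.8)
        pred = md.predict(p, feature_frame([0.5], [0.5], [0.5], [0]))
        assert pred["gamma"][0] < pred["y"][0]

    def test_batch_equals_per_motif(self):
        p = make_params(beta1=1.0, K1=4.0, r1=0.7)
        rng = np.random.default_rng(10)
        feats = feature_frame(
            rng.uniform(0, 1, 20), rng.uniform(0, 1, 20), rng.uniform(0, 1, 20),
            rng.integers(0, 40, 20),
        )
        batch = md.predict(p, feats)
        for i in range(20):
            single = md.predict(p, feats.iloc[[i]].reset_index(drop=True))
            assert single["gamma"][0] == pytest.approx(batch["gamma"][i], abs=1e-12)


class TestSplit:
    def test_disjoint_seeded_and_sized(self):
        feats = pd.DataFrame({"f": np.arange(300.0)})
        tr, te = md.split_train_test(feats, 100, 100, seed=1)
        assert len(tr) == 100 and len(te) == 100
        assert not set(tr["f"]) & set(te["f"])
        tr2, te2 = md.split_train_test(feats, 100, 100, seed=1)
        assert tr["f"].tolist() == tr2["f"].tolist()

    def test_downscales_small_population_with_warning(self):
        feats = pd.DataFrame({"f": np.arange(50.0)})
        with pytest.warns(UserWarning):
            tr, te = md.split_train_test(feats, 100, 100, seed=2)
        assert len(tr) + len(te) <= 50 and len(tr) > 0 and len(te) > 0
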