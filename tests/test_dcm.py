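"""Mixed conditional logit: likelihood, sampler, diagnostics, DIC, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from ducksel import dcm
from ducksel.dcm import (
    ChoiceData,
    McmcConfig,
    Posterior,
    Priors,
    choice_probabilities,
    gelman_rubin,
    loglik,
    null_dic,
    rank_models,
    sample_posterior,
    summarize,
)
from ducksel.synthetic import simulate_choice_data


def make_data(rng, n_sets=6, n_alts=4, k=2, n_animals=2, scale=1.0):
    X = rng.normal(0, scale, size=(n_sets, n_alts, k))
    animal = rng.integers(0, n_animals, size=n_sets)
    return ChoiceData(
        X=X,
        mask=np.ones((n_sets, n_alts), dtype=bool),
        animal=animal,
        animal_ids=list(range(n_animals)),
        var_names=[f"x{i}" for i in range(k)],
    )


def enumeration_loglik(data, beta):
    """Independent oracle: direct exponentiation with exact summation."""
    total = []
    for n in range(data.n_sets):
        b = beta[data.animal[n]]
        utils = [
            math.fsum(float(data.X[n, j, k]) * float(b[k]) for k in range(data.n_vars))
            for j in range(data.X.shape[1])
            if data.mask[n, j]
        ]
        denom = math.fsum(math.exp(u) for u in utils)
        total.append(utils[0] - math.log(denom))
    return math.fsum(total)


class TestLoglik:
    def test_zero_beta_is_uniform_choice(self, rng):
        data = make_data(rng, n_sets=9, n_alts=5)
        expected = -np.log(data.set_sizes.astype(float)).sum()
        assert loglik(data, np.zeros((2, 2))) == pytest.approx(expected, rel=1e-12)

    def test_single_alternative_sets_contribute_zero(self, rng):
        data = make_data(rng, n_sets=4, n_alts=1)
        beta = rng.normal(size=(2, 2))
        assert loglik(data, beta) == pytest.approx(0.0, abs=1e-14)

    def test_matches_enumeration_oracle(self, rng):
        data = make_data(rng, n_sets=3, n_alts=4, k=2)
        beta = rng.normal(size=(2, 2))
        assert loglik(data, beta) == pytest.approx(enumeration_loglik(data, beta), abs=1e-10)

    def test_stable_for_large_utilities(self, rng):
        data = make_data(rng, n_sets=5, n_alts=4, k=1, scale=1.0)
        beta = np.full((2, 1), 600.0)
        val = loglik(data, beta)
        assert np.isfinite(val)

    def test_location_invariance_within_sets(self, rng):
        # adding a per-set constant to every alternative's covariates leaves
        # choice probabilities unchanged (conditional-logit identification)
        data = make_data(rng, n_sets=6, n_alts=5)
        beta = rng.normal(size=(2, 2))
        p0 = choice_probabilities(data, beta)
        shifted = ChoiceData(
            X=data.X + rng.normal(size=(data.n_sets, 1, data.n_vars)),
            mask=data.mask,
            animal=data.animal,
            animal_ids=data.animal_ids,
            var_names=data.var_names,
        )
        np.testing.assert_allclose(choice_probabilities(shifted, beta), p0, atol=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        data = make_data(rng, n_sets=8, n_alts=6)
        beta = rng.normal(size=(2, 2)) * 5
        p = choice_probabilities(data, beta)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_shared_beta_equals_pooled_conditional_logit(self, rng):
        # the sigma -> 0 limit: every animal at beta = mu reproduces the
        # pooled fixed-effect conditional logit likelihood
        data = make_data(rng, n_sets=10, n_alts=4, n_animals=3)
        mu = rng.normal(size=2)
        pooled = 0.0
        for n in range(data.n_sets):
            eta = data.X[n] @ mu
            pooled += eta[0] - np.log(np.exp(eta).sum())
        hier = loglik(data, np.tile(mu, (3, 1)))
        assert hier == pytest.approx(pooled, rel=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        data = make_data(rng)
        with pytest.raises(ValueError, match="shape"):
            loglik(data, np.zeros((5, 3)))


class TestGelmanRubin:
    def test_same_distribution_approaches_one(self):
        rng = np.random.default_rng(42)
        chains = rng.normal(size=(3, 5000))
        assert gelman_rubin(chains) <= 1.05

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 500))
        chains[1] += 10.0
        assert gelman_rubin(chains) > 1.1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        chains = rng.normal(size=(4, 200, 3))
        got = gelman_rubin(chains)
        # independent evaluation of the between/within variance form
        m, n, p = chains.shape
        for k in range(p):
            arr = chains[:, :, k]
            means = arr.mean(axis=1)
            b = n / (m - 1) * ((means - means.mean()) ** 2).sum()
            w = np.mean([np.var(arr[c], ddof=1) for c in range(m)])
            v_hat = (n - 1) / n * w + b / n
            assert got[k] == pytest.approx(np.sqrt(v_hat / w), abs=1e-10)

    def test_degenerate_chains_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gelman_rubin(np.ones((2, 100)))

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestDic:
    def test_null_model_closed_form(self, rng):
        data = make_data(rng, n_sets=12, n_alts=5)
        null = ChoiceData(
            X=data.X[:, :, :0],
            mask=data.mask,
            animal=data.animal,
            animal_ids=data.animal_ids,
            var_names=[],
        )
        expected = 2.0 * np.log(data.set_sizes.astype(float)).sum()
        assert null_dic(null) == pytest.approx(expected, rel=1e-14)
        post = Posterior(
            mu=np.zeros((2, 10, 0)),
            sigma=np.zeros((2, 10, 0)),
            beta=np.zeros((2, 10, 2, 0)),
            var_names=[],
            animal_ids=null.animal_ids,
        )
        d = dcm.dic(post, null)
        assert d["pD"] == 0.0 and d["DIC"] == pytest.approx(expected, rel=1e-14)

    def test_point_mass_chains_have_zero_pd(self, rng):
        data = make_data(rng, n_sets=5)
        beta_hat = rng.normal(size=(2, 2))
        beta_draws = np.tile(beta_hat, (2, 50, 1, 1))
        post = Posterior(
            mu=np.zeros((2, 50, 2)),
            sigma=np.ones((2, 50, 2)),
            beta=beta_draws,
            var_names=data.var_names,
            animal_ids=data.animal_ids,
        )
        d = dcm.dic(post, data)
        assert d["pD"] == pytest.approx(0.0, abs=1e-9)
        assert d["DIC"] == pytest.approx(-2 * loglik(data, beta_hat), rel=1e-12)

    def test_dbar_matches_oracle_recompute(self, rng):
        data = make_data(rng, n_sets=4, n_alts=3)
        draws = rng.normal(size=(2, 6, 2, 2)) * 0.5
        post = Posterior(
            mu=np.zeros((2, 6, 2)),
            sigma=np.ones((2, 6, 2)),
            beta=draws,
            var_names=data.var_names,
            animal_ids=data.animal_ids,
        )
        d = dcm.dic(post, data)
        oracle = np.mean(
            [-2.0 * enumeration_loglik(data, b) for b in draws.reshape(-1, 2, 2)]
        )
        assert d["Dbar"] == pytest.approx(oracle, abs=1e-9)


class TestRankModels:
    def test_delta_and_competitive_flags(self):
        res = {
            "full": {"DIC": 100.0, "fingerprint": "d"},
            "resource": {"DIC": 103.0, "fingerprint": "d"},
            "random": {"DIC": 120.0, "fingerprint": "d"},
        }
        table = rank_models(res)
        assert list(table["model"]) == ["full", "resource", "random"]
        np.testing.assert_allclose(table["delta_DIC"], [0.0, 3.0, 20.0])
        assert list(table["competitive"]) == [True, True, False]

    def test_identical_models_all_zero_delta(self):
        res = {m: {"DIC": 55.5, "fingerprint": "x"} for m in ("a", "b", "c")}
        table = rank_models(res)
        assert (table["delta_DIC"] == 0).all() and table["competitive"].all()

    def test_mismatched_data_rejected(self):
        res = {"a": {"DIC": 1.0, "fingerprint": "x"}, "b": {"DIC": 2.0, "fingerprint": "y"}}
        with pytest.raises(ValueError, match="different"):
            rank_models(res)


class TestSummarize:
    def _post(self, mu_draws):
        mu = np.asarray(mu_draws)[None, :, None].repeat(2, axis=0)
        return Posterior(
            mu=mu,
            sigma=np.ones_like(mu),
            beta=np.zeros((2, mu.shape[1], 1, 1)),
            var_names=["v"],
            animal_ids=[0],
        )

    def test_all_positive_draws_important(self):
        s = summarize(self._post(np.linspace(0.5, 1.5, 200)), rhats={})
        assert bool(s.iloc[0]["important"])

    def test_symmetric_draws_not_important(self):
        s = summarize(self._post(np.linspace(-1, 1, 201)), rhats={})
        assert not bool(s.iloc[0]["important"])

    def test_percentiles_match_sorting_oracle(self, rng):
        draws = rng.normal(size=400)
        s = summarize(self._post(draws), rhats={})
        pooled = np.sort(np.concatenate([draws, draws]))
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        assert s.iloc[0]["cri_lo"] == pytest.approx(lo, rel=1e-12)
        assert s.iloc[0]["cri_hi"] == pytest.approx(hi, rel=1e-12)


class TestSampler:
    def test_deterministic_under_seed(self):
        data, _ = simulate_choice_data(4, 10, 4, mu=[0.5], sigma=0.2, seed=3)
        cfg = McmcConfig(chains=2, iterations=200, burn_in=100, seed=9)
        p1 = sample_posterior(data, Priors(), cfg)
        p2 = sample_posterior(data, Priors(), cfg)
        np.testing.assert_array_equal(p1.mu, p2.mu)
        np.testing.assert_array_equal(p1.beta, p2.beta)

    def test_zero_information_reproduces_prior(self, rng):
        # all alternatives share identical covariates -> constant likelihood,
        # so the mu posterior must return its Normal(0, 2.786) prior
        X = np.tile(rng.normal(size=(30, 1, 1)), (1, 4, 1))
        data = ChoiceData(
            X=X,
            mask=np.ones((30, 4), dtype=bool),
            animal=np.zeros(30, dtype=int),
            animal_ids=[0],
            var_names=["v"],
        )
        cfg = McmcConfig(chains=3, iterations=6000, burn_in=1000, seed=2)
        post = sample_posterior(data, Priors(), cfg)
        mu = post.pooled("mu")[:, 0]
        se = mu.std() / np.sqrt(200)  # generous effective-sample allowance
        assert abs(mu.mean()) < 4 * se + 0.15
        assert mu.var() == pytest.approx(2.786, rel=0.25)

    def test_posterior_sd_shrinks_with_more_data(self):
        cfg = McmcConfig(chains=2, iterations=1500, burn_in=500, seed=5)
        small, _ = simulate_choice_data(6, 15, 6, mu=[0.8], sigma=0.2, seed=21)
        large, _ = simulate_choice_data(6, 150, 6, mu=[0.8], sigma=0.2, seed=21)
        sd_small = sample_posterior(small, Priors(), cfg).pooled("mu").std()
        sd_large = sample_posterior(large, Priors(), cfg).pooled("mu").std()
        assert sd_large < sd_small

    def test_nonconvergence_is_flagged_not_silent(self, rng):
        data, _ = simulate_choice_data(4, 10, 4, mu=[0.5], sigma=0.2, seed=3)
        cfg = McmcConfig(chains=2, iterations=30, burn_in=15, seed=1, max_doublings=0)
        fit = dcm.fit_model(data, "full", Priors(), cfg)
        assert isinstance(fit.converged, bool)  # flag present either way

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(chains=1)
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=100)


class TestCandidateColumns:
    def test_aggregates(self, catalog, rng):
        units = pd.DataFrame(
            rng.uniform(0, 10, size=(20, len(catalog))), columns=catalog.abbreviations
        )
        res = dcm.candidate_columns(units, catalog, "resource")
        assert "marsh" in res.columns
        marshes = ["PUB-MARSH", "PRI-MARSH", "WAL-MARSH", "CWS-MARSH"]
        np.testing.assert_allclose(res["marsh"], units[marshes].sum(axis=1))
        risk = dcm.candidate_columns(units, catalog, "risk")
        assert set(risk.columns) == {"risk_high", "risk_intermediate", "risk_none"}
        np.testing.assert_allclose(risk["risk_high"], units["PUB-WATER"] + units["PUB-MARSH"])
        assert dcm.candidate_columns(units, catalog, "random").shape[1] == 0
        full = dcm.candidate_columns(units, catalog, "full", retained=["PRI-AGRI"])
        assert list(full.columns) == ["PRI-AGRI"]

    def test_unknown_model_rejected(self, catalog):
        with pytest.raises(ValueError, match="unknown candidate model"):
            dcm.candidate_columns(pd.DataFrame(), catalog, "bogus")
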