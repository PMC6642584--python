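"""Covariance-based componentwise boosting."""

import numpy as np
import pytest

from synthreg import (
    BoostingConfig,
    StandardizedPooled,
    StudyDataset,
    SynthesisBoosting,
    boost_fit,
    boost_step,
    build_pooled,
    candidate_gammas,
    residual_boost_oracle,
)

from conftest import random_pooled, random_study


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_steps": -1}, {"shrinkage": 0.0}, {"shrinkage": 1.5},
        {"selection_cap": 0},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            BoostingConfig(**kwargs)


class TestCandidateGammas:
    def test_first_step_equals_delta(self, rng):
        sp = StandardizedPooled.from_pooled(
            random_pooled(rng, sizes=(25, 20), p=6, overlap="partial"))
        np.testing.assert_allclose(candidate_gammas(sp).to_numpy(), sp.delta_)

    def test_single_snp_correction(self, rng):
        sp = StandardizedPooled.from_pooled(random_pooled(rng, sizes=(20,), p=1))
        b = 0.37
        gamma = candidate_gammas(sp, {"s0": b})
        assert gamma["s0"] == pytest.approx(sp.delta_[0] - b, abs=1e-12)

    def test_matches_residual_evaluation_complete_data(self, rng):
        pooled = random_pooled(rng, sizes=(30, 25), p=8)
        sp = StandardizedPooled.from_pooled(pooled)
        beta = np.zeros(8)
        beta[[1, 4, 6]] = [0.2, -0.1, 0.05]
        r = sp.y - sp.X @ beta
        expect = (sp.X.T @ r) / sp.n
        got = candidate_gammas(sp, beta).to_numpy()
        np.testing.assert_allclose(got, expect, atol=1e-12)


class TestBoostStep:
    def test_update_arithmetic_and_argmax(self):
        # engineered gammas: pick the strongest score, shrink its update
        sp = StandardizedPooled(
            np.array([[0, 0, 2.0], [2, 0, 0], [0, 2, 0], [2, 2, 2]]),
            ["case", "control", "case", "control"],
            np.zeros(4, dtype=int), snp_ids=["a", "b", "c"])
        cfg = BoostingConfig(n_steps=5, shrinkage=0.1)
        gam = candidate_gammas(sp).to_numpy()
        j_star, beta = boost_step(sp, {}, cfg)
        best = int(np.argmax(gam**2))
        assert j_star == sp.snp_ids[best]
        assert beta[j_star] == pytest.approx(0.1 * gam[best])

    def test_tie_broken_by_superset_order(self):
        # duplicate column -> identical gamma^2, first id must win
        g = np.array([[0, 0], [2, 2], [0, 0], [2, 2]], dtype=float)
        s = StudyDataset("A", ["s1", "s2"], g, ["control", "case", "control", "case"])
        sp = StandardizedPooled.from_pooled(build_pooled([s]))
        j_star, _ = boost_step(sp, {}, BoostingConfig(n_steps=1, shrinkage=0.1))
        assert j_star == "s1"

    def test_converged_sentinel_on_orthogonal_outcome(self):
        # x ⟂ y for the only SNP -> all gammas zero
        g = np.array([[0.0], [0.0], [2.0], [2.0]])
        s = StudyDataset("A", ["s1"], g, ["case", "control", "case", "control"])
        sp = StandardizedPooled.from_pooled(build_pooled([s]))
        j_star, beta = boost_step(sp, {}, BoostingConfig(n_steps=1, shrinkage=0.1))
        assert j_star is None and beta == {}


class TestBoostFit:
    def test_zero_steps(self, rng):
        fit = boost_fit(random_pooled(rng), BoostingConfig(n_steps=0))
        assert fit.active_set == [] and fit.history == []

    def test_single_snp_geometric_recursion(self, rng):
        pooled = random_pooled(rng, sizes=(40,), p=1)
        sp = StandardizedPooled.from_pooled(pooled)
        delta = sp.delta_[0]
        for M, nu in [(1, 0.1), (7, 0.05), (30, 0.3)]:
            fit = boost_fit(sp, BoostingConfig(n_steps=M, shrinkage=nu))
            assert fit.coef[0] == pytest.approx(
                delta * (1 - (1 - nu) ** M), abs=1e-12)

    def test_single_snp_limit(self, rng):
        pooled = random_pooled(rng, sizes=(40,), p=1)
        sp = StandardizedPooled.from_pooled(pooled)
        delta = sp.delta_[0]
        fit = boost_fit(sp, BoostingConfig(n_steps=200, shrinkage=0.1))
        assert abs(fit.coef[0] - delta) < (1 - 0.1) ** 200 * abs(delta) + 1e-12

    def test_one_coordinate_changes_per_step(self, rng):
        pooled = random_pooled(rng, sizes=(30, 20), p=8, overlap="partial")
        fit = boost_fit(pooled, BoostingConfig(n_steps=25, shrinkage=0.1))
        assert len(fit.history) == 25
        # replay: each record changes exactly its own coordinate
        beta = {}
        for rec in fit.history:
            prev = beta.get(rec.snp, 0.0)
            beta[rec.snp] = rec.beta
            assert rec.beta != prev or rec.gamma == 0

    def test_selected_gamma_dominates_at_each_step(self, rng):
        pooled = random_pooled(rng, sizes=(30, 20), p=6, overlap="partial")
        sp = StandardizedPooled.from_pooled(pooled)
        cfg = BoostingConfig(n_steps=15, shrinkage=0.1)
        fit = boost_fit(sp, cfg)
        beta = {}
        for rec in fit.history:
            gammas = candidate_gammas(sp, beta)
            assert abs(rec.gamma) >= gammas.abs().max() - 1e-10
            beta[rec.snp] = rec.beta

    def test_selection_cap_stops_entries(self, rng):
        pooled = random_pooled(rng, sizes=(40,), p=10)
        fit = boost_fit(pooled, BoostingConfig(n_steps=100, shrinkage=0.1,
                                               selection_cap=3))
        assert len(fit.active_set) <= 3

    def test_active_set_bounded_by_steps(self, rng):
        fit = boost_fit(random_pooled(rng, sizes=(40,), p=10),
                        BoostingConfig(n_steps=5, shrinkage=0.1))
        assert len(fit.active_set) <= 5

    def test_equivalent_to_residual_oracle_multi_study(self, rng):
        pooled = random_pooled(rng, sizes=(35, 25, 15), p=12)
        cfg = BoostingConfig(n_steps=40, shrinkage=0.1)
        ours = boost_fit(pooled, cfg)
        oracle = residual_boost_oracle(pooled, cfg)
        np.testing.assert_allclose(ours.coef, oracle.coef, atol=1e-10)
        assert [r.snp for r in ours.history] == [r.snp for r in oracle.history]

    def test_permutation_invariant_selection_identities(self, rng):
        study = random_study(rng, n=50, p=8)
        cfg = BoostingConfig(n_steps=20, shrinkage=0.1)
        fit1 = boost_fit(build_pooled([study]), cfg)
        perm = rng.permutation(8)
        permuted = StudyDataset("A", [study.snp_ids[c] for c in perm],
                                study.genotypes[:, perm], study.status)
        fit2 = boost_fit(build_pooled([permuted]), cfg)
        assert [r.snp for r in fit1.history] == [r.snp for r in fit2.history]
        assert fit1.beta == pytest.approx(fit2.beta)


class TestEstimatorAPI:
    def test_fit_sets_sklearn_attributes(self, rng):
        pooled = random_pooled(rng, sizes=(30, 20), p=6, overlap="partial")
        X, y, sidx = pooled.to_arrays()
        est = SynthesisBoosting(n_steps=20, shrinkage=0.1)
        est.fit(X, y, studies=sidx, snp_ids=pooled.superset)
        assert est.coef_.shape == (6,)
        assert est.n_features_in_ == 6
        assert set(est.active_set_) <= set(pooled.superset)
        scores = est.decision_function(X)
        assert scores.shape == (X.shape[0],)
        assert np.isfinite(scores).all()

    def test_matches_functional_path(self, rng):
        pooled = random_pooled(rng, sizes=(30, 20), p=6)
        X, y, sidx = pooled.to_arrays()
        est = SynthesisBoosting(n_steps=15, shrinkage=0.1).fit(X, y, studies=sidx)
        fit = boost_fit(pooled, BoostingConfig(n_steps=15, shrinkage=0.1))
        np.testing.assert_allclose(est.coef_, fit.coef, atol=1e-12)

    def test_clone_and_get_params(self):
        from sklearn.base import clone

        est = SynthesisBoosting(n_steps=7, shrinkage=0.2, selection_cap=3)
        params = est.get_params()
        assert params == {"n_steps": 7, "shrinkage": 0.2, "selection_cap": 3}
        clone(est)  # must not raise
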