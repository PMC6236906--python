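import numpy as np
import pytest
from scipy.optimize import minimize

import hseghmm as h
from hseghmm.em_fit import DEFAULT_BOUNDS, count_parameters
from hseghmm.emission import ObservationArrays
from hseghmm.hmm_core import PosteriorResult

from conftest import random_chain, random_log_emissions


def _posterior_from(gamma, pair_sums, loglik=0.0):
    return PosteriorResult(
        gamma=np.asarray(gamma, float),
        pair_sums=np.asarray(pair_sums, float),
        loglik=loglik,
    )


class TestMStepChain:
    def test_one_hot_first_row(self):
        gamma = np.zeros((4, 3))
        gamma[0, 2] = 1.0
        gamma[1:] = 1.0 / 3
        chain = h.m_step_chain(_posterior_from(gamma, np.full((3, 3), 1.0)))
        np.testing.assert_allclose(chain.init, [0.0, 0.0, 1.0])

    def test_uniform_pair_sums_give_uniform_rows(self):
        gamma = np.full((5, 4), 0.25)
        chain = h.m_step_chain(_posterior_from(gamma, np.full((4, 4), 0.7)))
        np.testing.assert_allclose(chain.trans, 0.25)

    def test_zero_visit_state_gets_uniform_row(self):
        gamma = np.full((5, 3), 1 / 3)
        pair = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [0.5, 0.5, 3.0]])
        chain = h.m_step_chain(_posterior_from(gamma, pair))
        np.testing.assert_allclose(chain.trans[1], 1 / 3)
        np.testing.assert_allclose(chain.trans.sum(axis=1), 1.0)

    def test_matches_constrained_optimization_oracle(self, rng):
        # maximize sum_ij pair[i,j] log P[i,j] per row on the simplex
        J = 3
        pair = rng.gamma(2.0, 1.0, size=(J, J))
        gamma = rng.dirichlet(np.ones(J), size=6)
        chain = h.m_step_chain(_posterior_from(gamma, pair))
        for i in range(J):
            def neg_obj(p, row=pair[i]):
                return -np.sum(row * np.log(np.clip(p, 1e-300, None)))

            res = minimize(
                neg_obj, np.full(J, 1.0 / J), method="SLSQP",
                bounds=[(1e-12, 1.0)] * J,
                constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
                options={"ftol": 1e-14, "maxiter": 500},
            )
            np.testing.assert_allclose(chain.trans[i], res.x, atol=1e-5)


class TestQTheta:
    def _small_dataset(self, rng, space, params, n=15):
        loci = []
        for k in range(n):
            het = rng.random() < 0.4
            loci.append(
                h.LocusObservation(
                    chrom="1", pos=k + 1, logR=float(rng.normal()),
                    logOR=float(rng.normal()) if het else None,
                )
            )
        return loci

    def test_one_hot_gamma_equals_labeled_loglik(self, rng, space12, params_t):
        loci = self._small_dataset(rng, space12, params_t)
        labels = rng.integers(0, len(space12), len(loci))
        gamma = np.eye(len(space12))[labels]
        got = h.q_theta(params_t, gamma, loci, space12)
        expect = sum(
            h.joint_log_emission(obs, space12[j], params_t, space12)
            for obs, j in zip(loci, labels)
        )
        assert got == pytest.approx(expect, abs=1e-9)

    def test_linear_in_gamma(self, rng, space12, params_t):
        loci = self._small_dataset(rng, space12, params_t)
        gamma = rng.dirichlet(np.ones(len(space12)), size=len(loci))
        assert h.q_theta(params_t, 2.0 * gamma, loci, space12) == pytest.approx(
            2.0 * h.q_theta(params_t, gamma, loci, space12)
        )

    def test_term_by_term_summation(self, rng, space12, params_t):
        loci = self._small_dataset(rng, space12, params_t, n=6)
        gamma = rng.dirichlet(np.ones(len(space12)), size=len(loci))
        expect = sum(
            gamma[k, j] * h.joint_log_emission(obs, space12[j], params_t, space12)
            for k, obs in enumerate(loci)
            for j in range(len(space12))
        )
        assert h.q_theta(params_t, gamma, loci, space12) == pytest.approx(
            expect, abs=1e-9
        )


class TestMStepGlobal:
    def test_ascent_contract(self, rng, space4, params_t):
        ds = h.simulate(h.SimConfig(n_loci=300, seed=7))
        gamma = rng.dirichlet(np.ones(len(space4)), size=300)
        start = h.GlobalParams(
            purity=0.5, ploidy=2.0, logR_scale2=1.0, logOR_scale2=1.0, df=5.0,
            family="t",
        )
        new = h.m_step_global(gamma, ds.loci, space4, start)
        assert h.q_theta(new, gamma, ds.loci, space4) >= (
            h.q_theta(start, gamma, ds.loci, space4) - 1e-9
        )

    def test_one_state_normal_variance_closed_form(self, rng):
        # with purity/ploidy pinned, the optimal variance is the weighted
        # mean squared residual around the fixed state mean
        space = h.build_state_space(["AB"])
        n = 400
        w = rng.normal(0.3, 0.9, n)
        loci = [
            h.LocusObservation(chrom="1", pos=k + 1, logR=float(w[k]))
            for k in range(n)
        ]
        gamma = np.ones((n, 1))
        purity, ploidy = 0.9, 1.6
        mu = h.expected_logR(space[0], purity, ploidy)
        start = h.GlobalParams(
            purity=purity, ploidy=ploidy, logR_scale2=0.2, logOR_scale2=0.5,
            family="normal",
        )
        bounds = {"purity": (purity, purity), "ploidy": (ploidy, ploidy)}
        new = h.m_step_global(gamma, loci, space, start, bounds=bounds)
        assert new.logR_scale2 == pytest.approx(np.mean((w - mu) ** 2), rel=1e-4)

    def test_self_consistency_at_truth(self):
        # huge-N data generated at the start point: the optimizer stays put
        ds = h.simulate(h.SimConfig(n_loci=20_000, seed=11))
        space = ds.space_true
        truth_params = h.GlobalParams(
            purity=0.9, ploidy=1.6, logR_scale2=0.3, logOR_scale2=0.5, df=4.0,
            family="t",
        )
        gamma = np.eye(len(space))[ds.truth]
        new = h.m_step_global(gamma, ds.loci, space, truth_params)
        assert new.purity == pytest.approx(0.9, abs=0.01)
        assert new.ploidy == pytest.approx(1.6, abs=0.03)
        assert new.logR_scale2 == pytest.approx(0.3, abs=0.03)
        assert new.logOR_scale2 == pytest.approx(0.5, abs=0.05)
        assert new.df == pytest.approx(4.0, abs=0.6)


class TestInformationCriteria:
    def test_trivial_values(self):
        # at n_obs = e^2 the BIC penalty ln(n) equals the AIC penalty 2
        aic, bic = h.information_criteria(0.0, 1, np.e**2)
        assert aic == pytest.approx(2.0)
        assert bic == pytest.approx(2.0, abs=1e-12)

    def test_formulas(self):
        aic, bic = h.information_criteria(-100.0, 7, 50)
        assert aic == pytest.approx(214.0)
        assert bic == pytest.approx(200.0 + np.log(50) * 7)

    def test_parameter_count_full_twelve_state_t(self):
        assert count_parameters(12, "t") == 11 + 132 + 5 == 148

    def test_parameter_count_two_state_t(self):
        assert count_parameters(2, "t") == 1 + 2 + 5 == 8

    def test_parameter_count_normal_family(self):
        assert count_parameters(12, "normal") == 147

    def test_gap_identity_recovers_count(self):
        # (BIC - AIC) / (ln N - 2) equals the parameter count by construction
        n_obs = 36_914
        for n_params in (148, 8):
            aic, bic = h.information_criteria(-31_000.0, n_params, n_obs)
            assert (bic - aic) / (np.log(n_obs) - 2.0) == pytest.approx(n_params)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            h.information_criteria(0.0, 0, 10)


class TestFit:
    def test_one_state_recovery(self, rng):
        space = h.build_state_space(["AB"])
        n = 3000
        sigma2 = 0.49
        mu = h.expected_logR(space[0], 0.9, 1.6)
        w = rng.normal(mu, np.sqrt(sigma2), n)
        loci = [
            h.LocusObservation(chrom="1", pos=k + 1, logR=float(w[k]))
            for k in range(n)
        ]
        init = h.GlobalParams(
            purity=0.9, ploidy=1.6, logR_scale2=0.2, logOR_scale2=0.5,
            family="normal",
        )
        res = h.fit(
            loci, space, family="normal", init=init,
            bounds={"purity": (0.9, 0.9), "ploidy": (1.6, 1.6)},
        )
        mc_se = sigma2 * np.sqrt(2.0 / n)
        assert res.globals.logR_scale2 == pytest.approx(
            np.var(w), abs=3 * mc_se
        )
        assert res.converged

    def test_loglik_trace_non_decreasing(self):
        ds = h.simulate(h.SimConfig(n_loci=400, seed=3))
        res = h.fit(ds.loci, ds.space_true, family="t", max_iter=100)
        trace = res.loglik_trace
        assert np.all(np.diff(trace) >= -1e-8 * (1.0 + np.abs(trace[:-1])))

    def test_decoded_copy_numbers_consistent_with_states(self):
        ds = h.simulate(h.SimConfig(n_loci=400, seed=5))
        res = h.fit(ds.loci, ds.space_true, family="t", max_iter=100)
        for j, total in zip(res.decoded, res.decoded_total_cn):
            assert total == res.space[j].total_cn

    def test_reproducible_given_same_inputs(self):
        ds = h.simulate(h.SimConfig(n_loci=300, seed=9))
        res1 = h.fit(ds.loci, ds.space_true, family="t", max_iter=60)
        res2 = h.fit(ds.loci, ds.space_true, family="t", max_iter=60)
        assert res1.loglik == res2.loglik
        np.testing.assert_array_equal(res1.decoded, res2.decoded)

    def test_needs_two_loci(self, space4):
        with pytest.raises(ValueError):
            h.fit(
                [h.LocusObservation(chrom="1", pos=1, logR=0.0)],
                space4,
            )

    def test_explicit_init_is_honored(self):
        ds = h.simulate(h.SimConfig(n_loci=300, seed=13))
        init = h.GlobalParams(
            purity=0.9, ploidy=1.6, logR_scale2=0.3, logOR_scale2=0.5, df=4.0,
            family="t",
        )
        res = h.fit(ds.loci, ds.space_true, family="t", init=init, max_iter=100)
        assert res.converged
        assert res.globals.ploidy == pytest.approx(1.6, abs=0.15)


class TestStandardErrors:
    def test_one_state_normal_known_mean_closed_form(self, rng):
        space = h.build_state_space(["AB"])
        n = 2000
        sigma2 = 0.81
        mu = h.expected_logR(space[0], 0.9, 1.6)
        w = rng.normal(mu, np.sqrt(sigma2), n)
        loci = [
            h.LocusObservation(chrom="1", pos=k + 1, logR=float(w[k]))
            for k in range(n)
        ]
        init = h.GlobalParams(
            purity=0.9, ploidy=1.6, logR_scale2=0.5, logOR_scale2=0.5,
            family="normal",
        )
        res = h.fit(
            loci, space, family="normal", init=init,
            bounds={"purity": (0.9, 0.9), "ploidy": (1.6, 1.6)},
        )
        se = h.standard_errors(res, loci, space, free=["logR_scale2"])
        s2_hat = res.globals.logR_scale2
        assert se["logR_scale2"] == pytest.approx(
            s2_hat * np.sqrt(2.0 / n), rel=0.05
        )

    def test_se_shrinks_like_sqrt_n(self, rng):
        space = h.build_state_space(["AB"])
        ses = []
        for n in (1000, 4000):
            mu = h.expected_logR(space[0], 0.9, 1.6)
            w = rng.normal(mu, 1.0, n)
            loci = [
                h.LocusObservation(chrom="1", pos=k + 1, logR=float(w[k]))
                for k in range(n)
            ]
            init = h.GlobalParams(
                purity=0.9, ploidy=1.6, logR_scale2=1.0, logOR_scale2=0.5,
                family="normal",
            )
            res = h.fit(
                loci, space, family="normal", init=init,
                bounds={"purity": (0.9, 0.9), "ploidy": (1.6, 1.6)},
            )
            se = h.standard_errors(res, loci, space, free=["logR_scale2"])
            ses.append(se["logR_scale2"])
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.15)

    def test_singular_hessian_yields_missing(self):
        # purity and ploidy are jointly unidentifiable in a one-state space,
        # so the full Hessian is singular
        ds = h.simulate(h.SimConfig(n_loci=200, seed=17))
        space = h.build_state_space(["AB"])
        init = h.GlobalParams(
            purity=0.5, ploidy=2.0, logR_scale2=1.0, logOR_scale2=0.5,
            family="normal",
        )
        res = h.fit(ds.loci, space, family="normal", init=init, max_iter=30)
        se = h.standard_errors(res, ds.loci, space, free=["purity", "ploidy"])
        assert se["purity"] is None or se["ploidy"] is None
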