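"""Second-stage sampler: conjugate updates, slice sampling, resampling MH,
reversible jump, and posterior summaries."""

import math
from collections import Counter

import numpy as np
import pytest

from hierpk.population_model import ModelSpec, SelectionState
from hierpk.stage1_mcmc import Stage1Prior
from hierpk.stage2_mcmc import (
    Stage2Config,
    Stage2Draws,
    _resample_log_ratio,
    conditional_effect_summaries,
    gibbs_normal_mean,
    inclusion_probabilities,
    prior_inclusion_marginal,
    resample_profile_params,
    rj_prior_chain,
    run_stage2,
    slice_update_sd,
    typical_parameters,
    variance_decomposition,
)


class TestGibbsNormalMean:
    def test_flat_prior_centres_on_children(self, rng):
        # prior variance -> infinity: full conditional centred at child mean
        draws = np.array(
            [gibbs_normal_mean(0.0, 1e9, 15.0, 3, 2.0, rng) for _ in range(4000)]
        )
        assert draws.mean() == pytest.approx(5.0, abs=0.1)
        assert draws.std() == pytest.approx(2.0 / math.sqrt(3), rel=0.1)

    def test_matches_conjugate_closed_form(self, rng):
        # prior N(1, 2^2), 3 children with sd 0.5 summing to 9
        m0, s0, ssum, n, sd = 1.0, 2.0, 9.0, 3, 0.5
        prec = 1 / s0**2 + n / sd**2
        mean = (m0 / s0**2 + ssum / sd**2) / prec
        draws = np.array(
            [gibbs_normal_mean(m0, s0, ssum, n, sd, rng) for _ in range(6000)]
        )
        assert draws.mean() == pytest.approx(mean, abs=0.01)
        assert draws.std() == pytest.approx(1 / math.sqrt(prec), rel=0.05)

    def test_matches_grid_posterior(self, rng):
        # dense-grid oracle on a 3-child toy
        m0, s0, sd = 0.5, 3.0, 1.5
        children = np.array([1.0, 2.5, 0.2])
        grid = np.linspace(-5, 8, 4001)
        logp = -0.5 * ((grid - m0) / s0) ** 2
        for c in children:
            logp -= 0.5 * ((c - grid) / sd) ** 2
        w = np.exp(logp - logp.max())
        mean_grid = (grid * w).sum() / w.sum()
        var_grid = ((grid - mean_grid) ** 2 * w).sum() / w.sum()
        draws = np.array(
            [
                gibbs_normal_mean(m0, s0, children.sum(), 3, sd, rng)
                for _ in range(6000)
            ]
        )
        assert draws.mean() == pytest.approx(mean_grid, abs=0.05)
        assert draws.var() == pytest.approx(var_grid, rel=0.1)


class TestSliceUpdateSd:
    def test_invariant_distribution_matches_grid(self, rng):
        # 10 children with fixed sum of squares; long-run slice samples must
        # match the analytic full conditional (truncated to (0, 100))
        n, ss = 10, 22.0
        sigma = 1.0
        draws = []
        for _ in range(6000):
            sigma = slice_update_sd(sigma, n, ss, rng)
            draws.append(sigma)
        draws = np.sort(np.array(draws[500:]))
        grid = np.linspace(1e-3, 15.0, 3000)
        logf = -n * np.log(grid) - ss / (2 * grid**2)
        pdf = np.exp(logf - logf.max())
        cdf = np.cumsum(pdf) / pdf.sum()
        emp = np.searchsorted(draws, grid, side="right") / len(draws)
        assert np.abs(emp - cdf).max() <= 0.05

    def test_support_respected(self, rng):
        sigma = 50.0
        for _ in range(500):
            sigma = slice_update_sd(sigma, 2, 1e6, rng)  # pushes towards large sd
            assert 0.0 < sigma < 100.0

    def test_no_children_samples_uniform_prior(self, rng):
        draws = np.array([slice_update_sd(50.0, 0, 0.0, rng) for _ in range(4000)])
        assert np.all((draws > 0) & (draws < 100))
        # uniform moments
        assert draws.mean() == pytest.approx(50.0, abs=2.5)
        assert draws.std() == pytest.approx(100.0 / math.sqrt(12), rel=0.1)


class TestResampleRatio:
    def test_same_draw_is_accepted(self, rng):
        v = np.array([4.0, -3.7, 0.0, 30.0])
        logr = _resample_log_ratio(v, v, 0.0, 0.0, np.zeros(4), np.ones(4))
        assert logr == 0.0

    def test_one_parameter_normal_density_ratio(self):
        # population N(0,1) on parameter b, flat stage-1 prior, theta = 0 ->
        # theta* = 1: rho = exp(-0.5)
        v_cur = np.array([1.0, 1.0, 0.0, 0.0])
        v_prop = np.array([1.0, 1.0, 0.0, 1.0])
        eta = np.array([0.0, 0.0, 0.0, 0.0])
        # make the log-normal components contribute nothing: same values
        logr = _resample_log_ratio(v_cur, v_prop, 0.0, 0.0, eta, np.ones(4))
        assert logr == pytest.approx(-0.5)

    def test_stage1_prior_ratio_enters_exactly(self):
        prior = Stage1Prior()
        a, b = 3.0, -7.0
        lp = prior.log_density_ab(a, b)
        assert lp == pytest.approx(-0.5 * (9.0 + 49.0) / 100.0**2)

    def test_resample_profile_params_moves(self, onelevel_store, rng):
        entry = next(iter(onelevel_store.entries.values()))
        eta = np.array([4.0, -3.7, 0.0, 30.0])
        sigma = np.array([0.3, 0.3, 0.1, 10.0])
        idx = 0
        seen = {idx}
        for _ in range(200):
            idx = resample_profile_params(
                entry, idx, eta, sigma, onelevel_store.prior, rng
            )
            seen.add(idx)
        assert len(seen) > 10  # chain explores the stored pool


class TestReversibleJump:
    def test_flat_likelihood_recovers_model_prior(self):
        visits = rj_prior_chain(40000, group="interaction", c=4, seed=3)
        merged = Counter("q3" if len(v) == 3 else v for v in visits)
        freqs = np.array([merged[k] for k in merged]) / len(visits)
        assert len(merged) == 12
        assert np.all(np.abs(freqs - 1 / 12) < 0.02)

    def test_binary_group_prior_marginal(self):
        visits = rj_prior_chain(40000, group="binary", c=4, seed=4)
        incl = np.mean([0 in v for v in visits])
        assert incl == pytest.approx(0.5, abs=0.03)

    def test_interaction_never_exceeds_three(self):
        visits = rj_prior_chain(20000, group="interaction", c=4, seed=5)
        assert max(len(v) for v in visits) <= 3

    def test_prior_inclusion_marginal_by_enumeration(self):
        # exact prior inclusion probability, cross-checked by brute force
        import itertools

        from hierpk.population_model import model_prior_logpmf

        for group, c in (("interaction", 4), ("continuous", 7), ("binary", 4)):
            total = 0.0
            for q in range(c + 1):
                for gamma in itertools.combinations(range(c), q):
                    lp = model_prior_logpmf(group, q, np.array(gamma, dtype=int), c)
                    if lp > -math.inf and 0 in gamma:
                        total += math.exp(lp)
            assert prior_inclusion_marginal(group, c) == pytest.approx(total)


class TestRunStage2:
    def test_deterministic_given_seed(self, onelevel_dataset, onelevel_store):
        dataset, _ = onelevel_dataset
        cfg = Stage2Config(iterations=400, burn_in=100, thin=2)
        d1 = run_stage2(onelevel_store, dataset, ModelSpec(), cfg, seed=3)
        d2 = run_stage2(onelevel_store, dataset, ModelSpec(), cfg, seed=3)
        assert np.array_equal(d1.phi, d2.phi)
        assert np.array_equal(d1.theta_idx, d2.theta_idx)

    def test_kappa_lambda_perturbation_leaves_chain_unchanged(
        self, onelevel_dataset, onelevel_store
    ):
        # the acceptance ratio is independent of the error parameters, so
        # arbitrarily perturbing the stored (kappa, lambda) must not change a
        # single decision
        from copy import deepcopy

        dataset, _ = onelevel_dataset
        store2 = deepcopy(onelevel_store)
        for e in store2.entries.values():
            e.draws[:, 4] = np.random.default_rng(0).uniform(0, 100, e.n_draws)
            e.draws[:, 5] = np.random.default_rng(1).uniform(0, 1, e.n_draws)
        cfg = Stage2Config(iterations=400, burn_in=100, thin=2)
        d1 = run_stage2(onelevel_store, dataset, ModelSpec(), cfg, seed=9)
        d2 = run_stage2(store2, dataset, ModelSpec(), cfg, seed=9)
        assert np.array_equal(d1.theta_idx, d2.theta_idx)
        assert np.array_equal(d1.phi, d2.phi)

    def test_single_draw_store_degenerates(self, onelevel_dataset, onelevel_store):
        # H = 1: theta can never move, but the population parameters still mix
        from copy import deepcopy

        dataset, _ = onelevel_dataset
        store1 = deepcopy(onelevel_store)
        for e in store1.entries.values():
            e.draws = e.draws[:1]
        cfg = Stage2Config(iterations=600, burn_in=100, thin=2)
        d = run_stage2(store1, dataset, ModelSpec(), cfg, seed=2)
        assert np.all(d.theta_idx == 0)
        assert d.phi[:, 0].std() > 0

    def test_save_load_round_trip(self, twolevel_dataset, twolevel_store, tmp_path):
        dataset, _ = twolevel_dataset
        cfg = Stage2Config(iterations=300, burn_in=100, thin=3)
        d = run_stage2(
            twolevel_store, dataset,
            ModelSpec(level="two", covariates_on=True), cfg, seed=5,
        )
        d.save(tmp_path / "draws.npz")
        back = Stage2Draws.load(tmp_path / "draws.npz")
        assert np.array_equal(back.phi, d.phi)
        assert np.array_equal(back.incl, d.incl)
        assert back.spec == d.spec
        assert back.cells == d.cells

    def test_multiple_chains_converge(self, onelevel_dataset, onelevel_store):
        from hierpk.stage2_mcmc import run_stage2_chains

        dataset, _ = onelevel_dataset
        chains, bgr = run_stage2_chains(
            onelevel_store, dataset, ModelSpec(),
            Stage2Config(iterations=1000, burn_in=200, thin=2), seed=4, n_chains=2,
        )
        assert len(chains) == 2
        assert not np.array_equal(chains[0].phi, chains[1].phi)
        assert np.all(bgr < 1.1)  # phi and sigma_theta components

    def test_missing_store_entry_rejected(self, onelevel_dataset, onelevel_store):
        dataset, _ = onelevel_dataset
        from copy import deepcopy

        store = deepcopy(onelevel_store)
        store.entries.pop(list(store.entries)[0])
        with pytest.raises(ValueError, match="lacks"):
            run_stage2(
                store, dataset, ModelSpec(), Stage2Config(iterations=10, burn_in=0, thin=1),
                seed=0, exclude=(),
            )


def _toy_draws(incl, beta, names, groups):
    S = incl.shape[0]
    return Stage2Draws(
        phi=np.tile(np.array([4.0, -3.7, 0.0, 30.0]), (S, 1)),
        sigma_theta=np.full((S, 4), 0.2),
        sigma_psi=None,
        sigma_chi=None,
        psi=None,
        chi=None,
        incl=incl,
        beta=beta,
        theta_idx=np.zeros((S, 1), dtype=int),
        spec=ModelSpec(level="one", covariates_on=True, delta_beta=(1, 1, 1, 1)),
        profile_ids=["w00v1d"],
        col_names=names,
        col_groups=groups,
    )


class TestSummaries:
    def test_inclusion_probability_bounds(self):
        incl = np.zeros((10, 4, 2), dtype=bool)
        incl[:5, 0, 0] = True
        d = _toy_draws(incl, np.full((10, 4, 2), np.nan), ["x", "y"], ["continuous"] * 2)
        pr = inclusion_probabilities(d)
        assert pr[0, 0] == 0.5
        assert pr[0, 1] == 0.0  # never selected

    def test_conditional_summaries(self):
        S = 8
        incl = np.zeros((S, 4, 2), dtype=bool)
        beta = np.full((S, 4, 2), np.nan)
        incl[:, 0, 0] = True  # always included -> conditional = marginal
        beta[:, 0, 0] = 0.017
        d = _toy_draws(incl, beta, ["x", "y"], ["binary", "binary"])
        recs = {(r["parameter"], r["covariate"]): r for r in conditional_effect_summaries(d)}
        r = recs[(0, "x")]
        assert r["beta_mean"] == pytest.approx(0.017)
        # log-scale effect reported as percent change: exp(0.017) - 1 = 1.7%
        assert r["pct_per_unit_mean"] == pytest.approx(1.715, rel=1e-3)
        assert recs[(0, "y")]["defined"] is False

    def test_variance_decomposition_one_level(self, onelevel_dataset, onelevel_store):
        dataset, _ = onelevel_dataset
        d = run_stage2(
            onelevel_store, dataset, ModelSpec(),
            Stage2Config(iterations=200, burn_in=50, thin=2), seed=1,
        )
        vd = variance_decomposition(d)
        assert list(vd) == ["theta"]
        assert np.allclose(vd["theta"]["proportion"], 1.0)

    def test_variance_proportions_sum_to_one(self, twolevel_dataset, twolevel_store):
        dataset, _ = twolevel_dataset
        d = run_stage2(
            twolevel_store, dataset, ModelSpec(level="two"),
            Stage2Config(iterations=300, burn_in=100, thin=3), seed=2,
        )
        vd = variance_decomposition(d)
        total = sum(rec["proportion"] for rec in vd.values())
        assert np.allclose(total, 1.0)
        for rec in vd.values():
            assert np.all((rec["proportion"] >= 0) & (rec["proportion"] <= 1))

    def test_typical_parameters_natural_scale(self):
        S = 6
        incl = np.zeros((S, 4, 4), dtype=bool)
        beta = np.full((S, 4, 4), np.nan)
        names = ["study1_breakfast", "study1_dinner", "study2_breakfast", "study2_dinner"]
        d = _toy_draws(incl, beta, names, ["interaction"] * 4)
        typ = typical_parameters(d)
        assert typ["study2_breakfast"][0, 0] == pytest.approx(math.exp(4.0))
        assert typ["study2_breakfast"][3, 0] == pytest.approx(30.0)
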