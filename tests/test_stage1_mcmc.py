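"""First-stage sampler: target correctness, diagnostics, storage."""

import numpy as np
import pytest

from hierpk import pk_model as pk
from hierpk.stage1_mcmc import (
    Stage1Config,
    Stage1Entry,
    Stage1Store,
    bgr_diagnostic,
    fit_diagnostics,
    run_stage1,
    unfittable_flags,
)
from hierpk.synthetic_trial import TrialDesign, generate_trial
from hierpk.trial_data import Profile, ProfileKey


def make_profile(times, y, dosing=None, wt=70.0, t_end=300.0):
    return Profile(
        key=ProfileKey(0, 1, 1),
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(y, dtype=float),
        dosing=dosing or pk.DosingSchedule(),
        context=pk.ProfileContext(wt=wt, t_end=t_end, t_start=0.0),
        meal_time=60.0,
    )


class TestRunStage1:
    def test_draw_count_bookkeeping(self):
        # every thin-th post-burn-in draw of every chain is stored; at the
        # production setting (10^6 iterations, thin 100) this gives 10^4 per chain
        dataset, _ = generate_trial(TrialDesign(n_women=2, n_study1_women=1), seed=1)
        prof = next(iter(dataset.profiles.values()))
        cfg = Stage1Config(burn_in=500, iterations=2000, thin=100, n_chains=2)
        entry = run_stage1(prof, config=cfg, seed=3)
        assert entry.chain_draws.shape == (2, 20, 6)
        assert entry.n_draws == 40
        assert 1_000_000 // 100 == 10_000

    def test_needs_six_observations(self):
        prof = make_profile(np.arange(5.0), np.full(5, 20.0))
        with pytest.raises(ValueError, match="at least 6"):
            run_stage1(prof, seed=0)

    def test_flat_profile_pathology_completes(self):
        # all observations identical: the sampler must still return draws
        # inside the prior supports
        prof = make_profile(np.linspace(0, 300, 12), np.full(12, 25.0))
        cfg = Stage1Config(burn_in=1000, iterations=2000, thin=10)
        entry = run_stage1(prof, config=cfg, seed=4)
        d = entry.draws
        assert np.all((d[:, 0] > 5) & (d[:, 0] < 500))
        assert np.all((d[:, 1] > 0) & (d[:, 1] < 0.25))
        assert np.all((d[:, 4] >= 0) & (d[:, 4] <= 100))
        assert np.all((d[:, 5] >= 0) & (d[:, 5] <= 1))

    def test_posterior_calibration_over_replicates(self):
        # 95% central intervals should cover the known truth in >= 90% of
        # seeded replicates, for each kinetic parameter
        cfg = Stage1Config(burn_in=3000, iterations=6000, thin=10)
        hits = np.zeros(4)
        n_rep = 20
        for rep in range(n_rep):
            dataset, truth = generate_trial(
                TrialDesign(n_women=2, n_study1_women=1, level="one", beta_true=()),
                seed=100 + rep,
            )
            pid = list(dataset.profiles)[rep % 4]
            entry = run_stage1(dataset.profiles[pid], config=cfg, seed=rep)
            lo, hi = np.quantile(entry.draws[:, :4], [0.025, 0.975], axis=0)
            t = truth.theta.loc[pid].to_numpy()
            hits += (t >= lo) & (t <= hi)
        assert np.all(hits >= 0.9 * n_rep), hits

    def test_marginals_match_grid_oracle_on_linear_surrogate(self):
        # with no dosing the regression is linear (mu = a (t - t_end) + b), so
        # the exact posterior is available by dense numerical integration over
        # (a, b, kappa, lambda); stage-1 marginals must agree (KS <= 0.05)
        rng = np.random.default_rng(12)
        times = np.linspace(20.0, 280.0, 10)
        a_t, b_t, k_t = 0.05, 30.0, 3.0
        mu_t = a_t * (times - 300.0) + b_t
        y = mu_t + rng.normal(size=len(times)) * k_t
        prof = make_profile(times, y)
        cfg = Stage1Config(burn_in=5000, iterations=50000, thin=10)
        entry = run_stage1(prof, config=cfg, seed=7)

        a_g = np.linspace(a_t - 0.12, a_t + 0.12, 100)
        b_g = np.linspace(b_t - 25.0, b_t + 25.0, 100)
        k_g = np.linspace(0.2, 15.0, 80)
        l_g = np.linspace(1e-4, 0.9999, 40)
        A, B, K, L = np.meshgrid(a_g, b_g, k_g, l_g, indexing="ij", sparse=True)
        logp = -0.5 * (A**2 + B**2) / 100.0**2  # stage-1 normal priors on a, b
        for t_i, y_i in zip(times, y):
            mu = A * (t_i - 300.0) + B
            var = K**2 + L**2 * mu**2
            logp = logp - 0.5 * np.log(2 * np.pi * var) - 0.5 * (y_i - mu) ** 2 / var
        post = np.exp(logp - logp.max())

        for axis, grid, col in ((0, a_g, 2), (1, b_g, 3), (2, k_g, 4)):
            marg = post.sum(axis=tuple(i for i in range(4) if i != axis))
            cdf_grid = np.cumsum(marg) / marg.sum()
            draws = np.sort(entry.draws[:, col])
            cdf_chain = np.searchsorted(draws, grid, side="right") / len(draws)
            ks = np.abs(cdf_chain - cdf_grid).max()
            assert ks <= 0.05, (col, ks)


class TestBGR:
    def test_identical_chains(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(200, 3))
        stat = bgr_diagnostic(np.stack([c, c]))
        assert np.all(stat <= 1.0)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        c1 = rng.normal(0, 1, size=(200, 1))
        c2 = rng.normal(10, 1, size=(200, 1))
        assert bgr_diagnostic(np.stack([c1, c2]))[0] > 1.1

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 150, 2))
        base = bgr_diagnostic(chains)
        trans = bgr_diagnostic(chains * 7.3 - 11.0)
        assert np.allclose(base, trans, rtol=1e-12)

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            bgr_diagnostic(np.zeros((1, 100, 2)))


class TestStoreAndFlags:
    def test_store_round_trip(self, twolevel_store, tmp_path):
        path = tmp_path / "store.npz"
        twolevel_store.save(path)
        back = Stage1Store.load(path)
        assert back.profile_ids == twolevel_store.profile_ids
        for pid in back.profile_ids:
            assert np.array_equal(
                back.entries[pid].draws, twolevel_store.entries[pid].draws
            )
            assert np.array_equal(
                back.entries[pid].bgr, twolevel_store.entries[pid].bgr
            )
        assert back.config == twolevel_store.config
        assert back.prior == twolevel_store.prior

    def test_boundary_mass_flagged(self):
        rng = np.random.default_rng(3)
        draws = np.column_stack(
            [
                np.full(100, 499.9),  # t_max piled at the upper bound
                rng.uniform(0.01, 0.2, 100),
                rng.normal(size=100),
                rng.normal(size=100),
                rng.uniform(1, 10, 100),
                rng.uniform(0.01, 0.5, 100),
            ]
        )
        entry = Stage1Entry(
            profile_id="x",
            draws=draws,
            chain_draws=draws[None],
            bgr=np.ones(6),
            acceptance=np.full((1, 6), 0.4),
            seed=0,
        )
        assert "boundary" in unfittable_flags(entry)
        entry2 = Stage1Entry(
            profile_id="x",
            draws=draws,
            chain_draws=draws[None],
            bgr=np.array([1.0, 1.3, 1.0, 1.0, 1.0, 1.0]),
            acceptance=np.full((1, 6), 0.4),
            seed=0,
        )
        assert "bgr" in unfittable_flags(entry2)


class TestFitDiagnostics:
    def test_noise_free_fit_has_zero_residuals(self):
        dosing = pk.DosingSchedule(bolus_events=((60.0, 1.0, 8000.0),))
        times = np.linspace(10.0, 290.0, 12)
        theta = np.array([55.0, 0.025, 0.02, 25.0, 2.0, 0.05])
        params = pk.KineticParams(*theta[:4])
        ctx = pk.ProfileContext(wt=70.0, t_end=300.0, t_start=0.0)
        q2 = pk.q2_at(dosing, theta[0], times)
        y = pk.predicted_concentration(params, ctx, times, q2)
        prof = make_profile(times, y, dosing=dosing)
        diag = fit_diagnostics(prof, theta[None, :])
        assert np.allclose(diag["residuals"]["standardized"], 0.0, atol=1e-8)

    def test_standardized_residuals_unit_scale(self, twolevel_dataset, twolevel_store):
        dataset, _ = twolevel_dataset
        z = []
        for pid, entry in twolevel_store.entries.items():
            diag = fit_diagnostics(dataset.profiles[pid], entry.draws)
            z.extend(diag["residuals"]["standardized"].tolist())
        z = np.asarray(z)
        assert abs(z.mean()) < 0.3
        assert 0.7 < z.std() < 1.3

    def test_band_coverage(self, twolevel_dataset, twolevel_store):
        dataset, _ = twolevel_dataset
        inside = total = 0
        for pid, entry in twolevel_store.entries.items():
            prof = dataset.profiles[pid]
            diag = fit_diagnostics(prof, entry.draws, seed=1)
            lo = np.interp(prof.times, diag["grid"]["time"], diag["grid"]["lo"])
            hi = np.interp(prof.times, diag["grid"]["time"], diag["grid"]["hi"])
            inside += int(np.sum((prof.concentrations >= lo) & (prof.concentrations <= hi)))
            total += prof.n_obs
        assert inside / total > 0.85

    def test_requires_draws(self, twolevel_dataset):
        dataset, _ = twolevel_dataset
        prof = next(iter(dataset.profiles.values()))
        with pytest.raises(ValueError):
            fit_diagnostics(prof, np.empty((0, 6)))
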