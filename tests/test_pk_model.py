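"""Forward model: dosing input, compartment ODE, regression, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hierpk import pk_model as pk


def impulse_schedule(dose_mu=8000.0, start=0.0, duration=1.0):
    return pk.DosingSchedule(bolus_events=((start, duration, dose_mu),))


class TestInputRate:
    def test_empty_schedule_is_zero(self):
        d = pk.DosingSchedule()
        assert pk.input_rate(0.0, d) == 0.0
        assert pk.input_rate(123.4, d) == 0.0

    def test_bolus_square_pulse(self):
        # 8 U = 8000 mU over 1 min starting at t = 1080
        d = impulse_schedule(8000.0, start=1080.0)
        assert pk.input_rate(1080.5, d) == pytest.approx(8000.0)
        assert pk.input_rate(1082.0, d) == 0.0
        # right-continuity: active at the start, off at the end
        assert pk.input_rate(1080.0, d) == pytest.approx(8000.0)
        assert pk.input_rate(1081.0, d) == 0.0

    def test_basal_rate_units(self):
        # 0.6 U/h over a day = 10 mU/min
        d = pk.DosingSchedule(basal_segments=((0.0, 1440.0, 10.0),))
        assert pk.input_rate(100.0, d) == pytest.approx(10.0)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pk.DosingSchedule(basal_segments=((0.0, 100.0, 1.0), (50.0, 150.0, 1.0)))


class TestIntegrator:
    def test_no_dosing_stays_at_zero(self):
        states = pk.integrate_compartments(pk.DosingSchedule(), 50.0, [10.0, 100.0])
        for s in states:
            assert s.q1 == 0.0 and s.q2 == 0.0

    def test_impulse_peak(self):
        # 1-min bolus approximates an impulse: Q2(t) = D (t/T) e^{-t/T},
        # maximal at t = T with value D/e
        (state,) = pk.integrate_compartments(impulse_schedule(), 50.0, [50.0])
        assert state.q2 == pytest.approx(8000.0 * np.exp(-1.0), rel=0.01)

    def test_impulse_peaks_at_tmax(self):
        times = np.linspace(5.0, 200.0, 400)
        states = pk.integrate_compartments(impulse_schedule(), 50.0, times)
        q2 = np.array([s.q2 for s in states])
        assert times[np.argmax(q2)] == pytest.approx(50.0, abs=2.0)

    def test_constant_infusion_steady_state(self):
        d = pk.DosingSchedule(basal_segments=((0.0, 5000.0, 10.0),))
        (state,) = pk.integrate_compartments(d, 50.0, [4000.0])
        assert state.q1 == pytest.approx(500.0, rel=1e-5)
        assert state.q2 == pytest.approx(500.0, rel=1e-4)

    def test_mass_balance(self):
        # input up to t minus cumulative efflux int Q2/T equals Q1 + Q2
        d = pk.DosingSchedule(
            basal_segments=((0.0, 300.0, 5.0),), bolus_events=((60.0, 1.0, 4000.0),)
        )
        T = 40.0
        t_grid = np.linspace(0.001, 600.0, 6000)
        states = pk.integrate_compartments(d, T, t_grid)
        q2 = np.array([s.q2 for s in states])
        efflux = np.concatenate([[0.0], np.cumsum((q2[1:] + q2[:-1]) / 2 / T * np.diff(t_grid))])
        inputs = np.array(
            [min(t, 300.0) * 5.0 + (4000.0 if t >= 61 else max(0.0, t - 60) * 4000.0) for t in t_grid]
        )
        total = np.array([s.q1 + s.q2 for s in states])
        assert np.allclose(total, inputs - efflux, atol=1.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pk.integrate_compartments(pk.DosingSchedule(), -1.0, [1.0])
        with pytest.raises(ValueError):
            pk.integrate_compartments(pk.DosingSchedule(), 10.0, [5.0, 1.0])


class TestClosedFormOracle:
    def test_zero_input(self):
        s = pk.closed_form_compartments(pk.DosingSchedule(), 30.0, 100.0)
        assert s.q1 == 0.0 and s.q2 == 0.0

    def test_constant_input_q1(self):
        # scalar linear ODE: Q1(t) = r T (1 - e^{-t/T})
        r, T, t = 7.0, 45.0, 120.0
        d = pk.DosingSchedule(basal_segments=((0.0, 1000.0, r),))
        s = pk.closed_form_compartments(d, T, t)
        assert s.q1 == pytest.approx(r * T * (1 - np.exp(-t / T)), rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10**9))
    def test_integrator_matches_oracle_on_random_schedules(self, seed):
        rng = np.random.default_rng(seed)
        segs, t0 = [], 0.0
        for _ in range(3):
            dur = rng.uniform(10, 300)
            segs.append((t0, t0 + dur, rng.uniform(0, 20)))
            t0 += dur + rng.uniform(0, 50)
        d = pk.DosingSchedule(
            basal_segments=tuple(segs),
            bolus_events=((rng.uniform(0, 500), rng.uniform(1, 10), rng.uniform(0, 9000)),),
        )
        tmax = rng.uniform(10, 200)
        times = np.sort(rng.uniform(1, 900, 20))
        states = pk.integrate_compartments(d, tmax, times)
        scale = max(max(s.q1, s.q2) for s in states) + 1e-12
        for s in states:
            ref = pk.closed_form_compartments(d, tmax, s.t)
            assert s.q1 == pytest.approx(ref.q1, rel=1e-5, abs=1e-5 * scale)
            assert s.q2 == pytest.approx(ref.q2, rel=1e-5, abs=1e-5 * scale)


class TestPredictedConcentration:
    CTX = pk.ProfileContext(wt=70.0, t_end=1380.0, t_start=1050.0)

    def test_zero_mass_gives_intercept(self):
        p = pk.KineticParams(50.0, 0.02, 0.0, 12.5)
        assert pk.predicted_concentration(p, self.CTX, 1380.0, 0.0) == pytest.approx(12.5)

    def test_linear_term(self):
        p = pk.KineticParams(50.0, 0.02, 1.0, 0.0)
        assert pk.predicted_concentration(p, self.CTX, 1390.0, 0.0) == pytest.approx(10.0)

    def test_steady_state_independent_of_tmax(self):
        # mu = conv * rate / (wt * MCR) once Q2 = rate * tmax
        for tmax in (30.0, 80.0):
            p = pk.KineticParams(tmax, 0.02, 0.0, 0.0)
            mu = pk.predicted_concentration(p, self.CTX, 0.0, 10.0 * tmax)
            assert mu == pytest.approx(6.0 * 10.0 / (70.0 * 0.02), rel=1e-12)


class TestLogLikelihood:
    CTX = pk.ProfileContext(wt=70.0, t_end=300.0, t_start=0.0)
    NODOSE = pk.DosingSchedule()

    def test_single_point_at_mean(self):
        p = pk.KineticParams(50.0, 0.02, 0.0, 20.0)
        ll = pk.log_likelihood(
            [10.0], [20.0], p, pk.NuisanceParams(1.0, 0.0), self.CTX, self.NODOSE
        )
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_homoscedastic_matches_direct_sum(self):
        # lambda = 0 reduces to iid Normal; brute-force oracle on 3 points
        p = pk.KineticParams(50.0, 0.02, 0.1, 20.0)
        times = np.array([10.0, 50.0, 200.0])
        y = np.array([18.0, 25.0, 11.0])
        kappa = 3.0
        mu = p.a * (times - 300.0) + p.b
        expected = sum(
            -0.5 * np.log(2 * np.pi * kappa**2) - 0.5 * (yi - mi) ** 2 / kappa**2
            for yi, mi in zip(y, mu)
        )
        ll = pk.log_likelihood(
            times, y, p, pk.NuisanceParams(kappa, 0.0), self.CTX, self.NODOSE
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_multiplicative_scaling_property(self):
        # kappa = 0: scaling y and mu by c changes the log-likelihood by -n log c
        times = np.array([10.0, 50.0, 120.0, 200.0])
        c = 3.7
        p1 = pk.KineticParams(50.0, 0.02, 0.0, 20.0)
        pc = pk.KineticParams(50.0, 0.02, 0.0, 20.0 * c)
        y = np.array([18.0, 22.0, 19.0, 21.0])
        nuis = pk.NuisanceParams(0.0, 0.3)
        ll1 = pk.log_likelihood(times, y, p1, nuis, self.CTX, self.NODOSE)
        llc = pk.log_likelihood(times, y * c, pc, nuis, self.CTX, self.NODOSE)
        assert llc - ll1 == pytest.approx(-len(times) * np.log(c), rel=1e-9)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=10, deadline=None)
    def test_permutation_invariance(self, pyrng):
        times = np.array([10.0, 50.0, 120.0, 200.0, 260.0, 290.0])
        y = np.array([18.0, 25.0, 11.0, 30.0, 15.0, 22.0])
        perm = list(range(6))
        pyrng.shuffle(perm)
        p = pk.KineticParams(50.0, 0.02, 0.05, 20.0)
        nuis = pk.NuisanceParams(2.0, 0.1)
        ll = pk.log_likelihood(times, y, p, nuis, self.CTX, self.NODOSE)
        llp = pk.log_likelihood(times[perm], y[perm], p, nuis, self.CTX, self.NODOSE)
        assert llp == pytest.approx(ll, rel=1e-12)

    def test_degenerate_variance_signalled(self):
        p = pk.KineticParams(50.0, 0.02, 0.0, 0.0)
        with pytest.raises(pk.DegenerateVarianceError):
            pk.log_likelihood(
                [10.0], [0.0], p, pk.NuisanceParams(0.0, 0.5), self.CTX, self.NODOSE
            )

    def test_nuisance_bounds_enforced(self):
        with pytest.raises(ValueError):
            pk.NuisanceParams(-1.0, 0.5)
        with pytest.raises(ValueError):
            pk.NuisanceParams(1.0, 1.5)


def test_kinetic_params_invariants():
    with pytest.raises(ValueError):
        pk.KineticParams(-5.0, 0.02, 0.0, 0.0)
    with pytest.raises(ValueError):
        pk.KineticParams(50.0, 0.0, 0.0, 0.0)
    # a, b unconstrained in sign
    pk.KineticParams(50.0, 0.02, -1.0, -10.0)
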