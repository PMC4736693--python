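"""Numba-compiled numerical core.

Everything in here is a plain-array kernel: the Cash-Karp 4(5) integrator for
the two-compartment absorption cascade, the heteroscedastic Gaussian
log-likelihood, and the componentwise adaptive random-walk Metropolis chain
used both for the independent per-profile fits and (with a population prior
switched on) for the direct single-stage reference sampler.

Dosing input is represented as a piecewise-constant rate: breakpoints ``brk``
(length K+1, increasing, brk[0] == 0) and rates ``rate`` (length K, mU/min on
[brk[i], brk[i+1])).  Callers must extend the representation with a zero-rate
tail covering every requested output time.
"""

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453

# Cash-Karp 4(5) tableau
_C_A21 = 1.0 / 5.0
_C_A31, _C_A32 = 3.0 / 40.0, 9.0 / 40.0
_C_A41, _C_A42, _C_A43 = 3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0
_C_A51, _C_A52, _C_A53, _C_A54 = -11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0
_C_A61, _C_A62, _C_A63, _C_A64, _C_A65 = (
    1631.0 / 55296.0,
    175.0 / 512.0,
    575.0 / 13824.0,
    44275.0 / 110592.0,
    253.0 / 4096.0,
)
_C_B1, _C_B3, _C_B4, _C_B6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
_C_E1 = _C_B1 - 2825.0 / 27648.0
_C_E3 = _C_B3 - 18575.0 / 48384.0
_C_E4 = _C_B4 - 13525.0 / 55296.0
_C_E5 = -277.0 / 14336.0
_C_E6 = _C_B6 - 1.0 / 4.0


@njit(cache=True)
def _ck_step(q1, q2, r, tmax, h):
    """One Cash-Karp step for dQ1 = r - Q1/T, dQ2 = (Q1-Q2)/T.

    Returns (q1_new, q2_new, err1, err2) where err is the 4th/5th order
    embedded error estimate.
    """
    T = tmax
    k1_1 = r - q1 / T
    k1_2 = (q1 - q2) / T

    y1 = q1 + h * _C_A21 * k1_1
    y2 = q2 + h * _C_A21 * k1_2
    k2_1 = r - y1 / T
    k2_2 = (y1 - y2) / T

    y1 = q1 + h * (_C_A31 * k1_1 + _C_A32 * k2_1)
    y2 = q2 + h * (_C_A31 * k1_2 + _C_A32 * k2_2)
    k3_1 = r - y1 / T
    k3_2 = (y1 - y2) / T

    y1 = q1 + h * (_C_A41 * k1_1 + _C_A42 * k2_1 + _C_A43 * k3_1)
    y2 = q2 + h * (_C_A41 * k1_2 + _C_A42 * k2_2 + _C_A43 * k3_2)
    k4_1 = r - y1 / T
    k4_2 = (y1 - y2) / T

    y1 = q1 + h * (_C_A51 * k1_1 + _C_A52 * k2_1 + _C_A53 * k3_1 + _C_A54 * k4_1)
    y2 = q2 + h * (_C_A51 * k1_2 + _C_A52 * k2_2 + _C_A53 * k3_2 + _C_A54 * k4_2)
    k5_1 = r - y1 / T
    k5_2 = (y1 - y2) / T

    y1 = q1 + h * (
        _C_A61 * k1_1 + _C_A62 * k2_1 + _C_A63 * k3_1 + _C_A64 * k4_1 + _C_A65 * k5_1
    )
    y2 = q2 + h * (
        _C_A61 * k1_2 + _C_A62 * k2_2 + _C_A63 * k3_2 + _C_A64 * k4_2 + _C_A65 * k5_2
    )
    k6_1 = r - y1 / T
    k6_2 = (y1 - y2) / T

    q1n = q1 + h * (_C_B1 * k1_1 + _C_B3 * k3_1 + _C_B4 * k4_1 + _C_B6 * k6_1)
    q2n = q2 + h * (_C_B1 * k1_2 + _C_B3 * k3_2 + _C_B4 * k4_2 + _C_B6 * k6_2)
    e1 = h * (_C_E1 * k1_1 + _C_E3 * k3_1 + _C_E4 * k4_1 + _C_E5 * k5_1 + _C_E6 * k6_1)
    e2 = h * (_C_E1 * k1_2 + _C_E3 * k3_2 + _C_E4 * k4_2 + _C_E5 * k5_2 + _C_E6 * k6_2)
    return q1n, q2n, e1, e2


@njit(cache=True)
def integrate_piecewise(brk, rate, tmax, out_times, rtol, atol):
    """Adaptive Cash-Karp integration from t=0, Q1=Q2=0.

    Dosing discontinuities (the breakpoints) and all output times are forced
    step boundaries.  Returns (q1_out, q2_out, status); status != 0 signals a
    non-finite state or step-size underflow.
    """
    n_out = out_times.shape[0]
    q1_out = np.zeros(n_out)
    q2_out = np.zeros(n_out)
    q1 = 0.0
    q2 = 0.0
    t = 0.0
    h = tmax / 10.0
    seg = 0
    n_seg = rate.shape[0]
    for iout in range(n_out):
        target = out_times[iout]
        while t < target:
            # advance segment pointer; rate constant until next breakpoint
            while seg < n_seg - 1 and brk[seg + 1] <= t:
                seg += 1
            stop = target
            if seg < n_seg - 1 and brk[seg + 1] < stop:
                stop = brk[seg + 1]
            r = rate[seg]
            while t < stop:
                if stop - t < 1e-9:
                    t = stop
                    break
                h_try = h
                clipped = False
                if t + h_try > stop:
                    h_try = stop - t
                    clipped = True
                accepted = False
                while not accepted:
                    q1n, q2n, e1, e2 = _ck_step(q1, q2, r, tmax, h_try)
                    s1 = atol + rtol * (abs(q1) if abs(q1) > abs(q1n) else abs(q1n))
                    s2 = atol + rtol * (abs(q2) if abs(q2) > abs(q2n) else abs(q2n))
                    err = abs(e1) / s1
                    if abs(e2) / s2 > err:
                        err = abs(e2) / s2
                    if not (np.isfinite(q1n) and np.isfinite(q2n)):
                        return q1_out, q2_out, 1
                    if err <= 1.0:
                        t = t + h_try
                        q1 = q1n
                        q2 = q2n
                        accepted = True
                        fac = 5.0
                        if err > 0.0:
                            fac = 0.9 * err ** (-0.2)
                            if fac > 5.0:
                                fac = 5.0
                        # boundary-clipped steps must not shrink the natural step
                        if not clipped:
                            h = h_try * fac
                    else:
                        clipped = False
                        fac = 0.9 * err ** (-0.25)
                        if fac < 0.1:
                            fac = 0.1
                        h_try = h_try * fac
                        if h_try < 1e-12:
                            return q1_out, q2_out, 2
        # non-negativity is analytic; clip float noise
        q1_out[iout] = q1 if q1 > 0.0 else 0.0
        q2_out[iout] = q2 if q2 > 0.0 else 0.0
    return q1_out, q2_out, 0


@njit(cache=True)
def mean_concentration(q2, tobs, tmax, mcr, a, b, wt, t_end, conv):
    """Regression function: conv*Q2/(tmax*wt*MCR) + a*(t - t_end) + b."""
    mu = np.empty(q2.shape[0])
    denom = tmax * wt * mcr
    for m in range(q2.shape[0]):
        mu[m] = conv * q2[m] / denom + a * (tobs[m] - t_end) + b
    return mu


@njit(cache=True)
def hetero_loglik(y, mu, kappa, lam):
    """Gaussian log-likelihood with variance kappa^2 + lam^2 * mu^2."""
    s = 0.0
    k2 = kappa * kappa
    l2 = lam * lam
    for m in range(y.shape[0]):
        v = k2 + l2 * mu[m] * mu[m]
        if v <= 0.0:
            return -np.inf
        d = y[m] - mu[m]
        s += -0.5 * (LOG2PI + np.log(v)) - 0.5 * d * d / v
    return s


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _theta_from_u(u):
    """Map the unconstrained sampling vector to natural parameters.

    u = (log tmax, logit(MCR/0.25), a, b, logit(kappa/100), logit(lambda)).
    Returns (tmax, mcr, a, b, kappa, lam).
    """
    tmax = np.exp(u[0])
    mcr = 0.25 * _sigmoid(u[1])
    kappa = 100.0 * _sigmoid(u[4])
    lam = _sigmoid(u[5])
    return tmax, mcr, u[2], u[3], kappa, lam


@njit(cache=True)
def _log_target_u(u, q2, y, tobs, wt, t_end, conv, pop_eta, pop_sd, use_pop):
    """Log posterior density on the transformed scale (Jacobian included).

    use_pop == 0: independent-fit target (flat bounded priors on tmax, MCR,
    kappa, lambda; N(0,100^2) on a and b).
    use_pop == 1: hierarchical target with LN(eta, sd^2) on tmax and MCR and
    N(eta, sd^2) on a and b; nuisance priors unchanged.  The physiological
    support box tmax in (5,500), MCR in (0,0.25) applies in both modes.
    """
    tmax, mcr, a, b, kappa, lam = _theta_from_u(u)
    if not (5.0 < tmax < 500.0):
        return -np.inf
    mu = mean_concentration(q2, tobs, tmax, mcr, a, b, wt, t_end, conv)
    ll = hetero_loglik(y, mu, kappa, lam)
    if ll == -np.inf:
        return -np.inf
    if use_pop == 1:
        lt = np.log(tmax)
        lm = np.log(mcr)
        lp = (
            -0.5 * ((lt - pop_eta[0]) / pop_sd[0]) ** 2 - np.log(pop_sd[0]) - lt
            - 0.5 * ((lm - pop_eta[1]) / pop_sd[1]) ** 2 - np.log(pop_sd[1]) - lm
            - 0.5 * ((a - pop_eta[2]) / pop_sd[2]) ** 2 - np.log(pop_sd[2])
            - 0.5 * ((b - pop_eta[3]) / pop_sd[3]) ** 2 - np.log(pop_sd[3])
        )
    else:
        lp = -0.5 * (a / 100.0) ** 2 - 0.5 * (b / 100.0) ** 2
    # log |d theta / d u| for the log / logit transforms
    s1 = _sigmoid(u[1])
    s4 = _sigmoid(u[4])
    s5 = _sigmoid(u[5])
    lj = (
        u[0]
        + np.log(0.25 * s1 * (1.0 - s1))
        + np.log(100.0 * s4 * (1.0 - s4))
        + np.log(s5 * (1.0 - s5))
    )
    return ll + lp + lj


@njit(cache=True)
def mh_chain(
    y,
    tobs,
    brk,
    rate,
    wt,
    t_end,
    conv,
    u0,
    scales0,
    n_burn,
    n_iter,
    thin,
    seed,
    pop_eta,
    pop_sd,
    use_pop,
    rtol,
    atol,
    adapt,
):
    """Componentwise adaptive random-walk Metropolis chain.

    Proposal scales adapt toward a 0.44 acceptance rate during the first
    ``n_burn`` sweeps only (when ``adapt`` is nonzero), preserving detailed
    balance afterwards.  The compartment solution is recomputed only when the
    tmax component moves.  Returns
    (draws[H,6], acc_rate[6], scales[6], u_final[6], status).
    Draw columns: tmax, MCR, a, b, kappa, lambda (natural scale).
    """
    np.random.seed(seed)
    u = u0.copy()
    scales = scales0.copy()
    H = n_iter // thin if thin > 0 else 0
    draws = np.zeros((H, 6))
    acc = np.zeros(6)
    nprop = np.zeros(6)

    tmax = np.exp(u[0])
    q2_buf, st = _integrate_q2(brk, rate, tmax, tobs, rtol, atol)
    if st != 0:
        return draws, acc, scales, u, st
    lt = _log_target_u(u, q2_buf, y, tobs, wt, t_end, conv, pop_eta, pop_sd, use_pop)

    total = n_burn + n_iter
    stored = 0
    for it in range(total):
        for c in range(6):
            old = u[c]
            u[c] = old + scales[c] * np.random.normal()
            ode_ok = True
            if c == 0:
                tmax_new = np.exp(u[0])
                if 5.0 < tmax_new < 500.0:
                    q2_new, st = _integrate_q2(brk, rate, tmax_new, tobs, rtol, atol)
                    if st != 0:
                        return draws, acc, scales, u, st
                else:
                    q2_new = q2_buf
                    ode_ok = False
                lt_new = (
                    _log_target_u(
                        u, q2_new, y, tobs, wt, t_end, conv, pop_eta, pop_sd, use_pop
                    )
                    if ode_ok
                    else -np.inf
                )
            else:
                lt_new = _log_target_u(
                    u, q2_buf, y, tobs, wt, t_end, conv, pop_eta, pop_sd, use_pop
                )
            if lt_new - lt >= 0.0:
                acc_p = 1.0
            elif lt_new == -np.inf:
                acc_p = 0.0
            else:
                acc_p = np.exp(lt_new - lt)
            if np.random.uniform(0.0, 1.0) < acc_p:
                lt = lt_new
                if c == 0 and ode_ok:
                    q2_buf = q2_new
            else:
                u[c] = old
            if it >= n_burn:
                nprop[c] += 1.0
                acc[c] += acc_p
            elif adapt != 0:
                gain = 10.0 / (20.0 + it) ** 0.7
                if gain > 0.25:
                    gain = 0.25
                scales[c] *= np.exp(gain * (acc_p - 0.44))
                if scales[c] < 1e-6:
                    scales[c] = 1e-6
                elif scales[c] > 1e4:
                    scales[c] = 1e4
        if it >= n_burn and thin > 0 and (it - n_burn) % thin == thin - 1:
            if stored < H:
                tmx, mcr, a, b, kappa, lam = _theta_from_u(u)
                draws[stored, 0] = tmx
                draws[stored, 1] = mcr
                draws[stored, 2] = a
                draws[stored, 3] = b
                draws[stored, 4] = kappa
                draws[stored, 5] = lam
                stored += 1
    for c in range(6):
        if nprop[c] > 0:
            acc[c] /= nprop[c]
    return draws, acc, scales, u, 0


@njit(cache=True)
def _integrate_q2(brk, rate, tmax, tobs, rtol, atol):
    q1o, q2o, st = integrate_piecewise(brk, rate, tmax, tobs, rtol, atol)
    return q2o, st
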