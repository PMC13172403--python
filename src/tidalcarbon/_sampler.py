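"""Adaptive Metropolis-within-Gibbs kernel for the Bayesian CRS age-depth model.

The model follows the Bacon/Plum construction: per-section accretion slowness
alpha_j (yr/cm) is a gamma-autoregressive process

    alpha_1 = eps_1,   alpha_j = w*alpha_{j-1} + (1-w)*eps_j,
    eps_j ~ Gamma(shape a, mean mu_a),   w ~ Beta(mem_mean*R, (1-mem_mean)*R)

with ages the cumulative sum of alpha over sections (surface age 0).  The
sampler moves in unconstrained coordinates (log eps_j, logit w, log phi,
log supported_k) with per-coordinate random-walk proposals whose scales are
tuned during burn-in.  Everything is compiled with numba; the seed passed in
fully determines the output.
"""

import numpy as np
from numba import njit

# coordinate layout: [log eps_0 .. log eps_{n_sec-1}, logit w, log phi,
#                     log s_0 .. log s_{n_s-1}]


@njit(cache=True)
def _age_at(cum_ages, d, dc, n_sec):
    # linear interpolation of the piecewise-linear age-depth curve
    k = int(d / dc)
    if k >= n_sec:
        return cum_ages[n_sec]
    frac = d / dc - k
    return cum_ages[k] + frac * (cum_ages[k + 1] - cum_ages[k])


@njit(cache=True)
def _log_posterior(
    eps, w, phi, s,
    dc, n_sec,
    acc_shape, acc_rate, a_w, b_w, phi_shape, phi_rate, s_shape, s_rate,
    pb_top, pb_bot, pb_act, pb_sd, pb_mass, s_index,
    ra_act, ra_sd,
    has_anchor, anchor_depth, anchor_age, anchor_age_sd, anchor_depth_sd,
    lam, student_t, use_likelihood,
    alpha_out, cum_out,
):
    # priors (in transformed space: gamma/beta log-densities + log-Jacobians)
    lp = 0.0
    for j in range(n_sec):
        # Gamma(shape, rate) density of eps + Jacobian d eps/d log eps = eps
        lp += acc_shape * np.log(eps[j]) - acc_rate * eps[j]
    # Beta density of w + logit Jacobian w(1-w)
    lp += a_w * np.log(w) + b_w * np.log(1.0 - w)
    lp += phi_shape * np.log(phi) - phi_rate * phi
    n_s = s.shape[0]
    for k in range(n_s):
        lp += s_shape * np.log(s[k]) - s_rate * s[k]

    # accretion series and cumulative ages at section boundaries
    alpha_out[0] = eps[0]
    for j in range(1, n_sec):
        alpha_out[j] = w * alpha_out[j - 1] + (1.0 - w) * eps[j]
    cum_out[0] = 0.0
    for j in range(n_sec):
        cum_out[j + 1] = cum_out[j] + alpha_out[j] * dc

    if not use_likelihood:
        return lp

    s_mean = 0.0
    for k in range(n_s):
        s_mean += s[k]
    if n_s > 0:
        s_mean /= n_s

    # total 210Pb likelihood
    m = pb_act.shape[0]
    for i in range(m):
        t0 = _age_at(cum_out, pb_top[i], dc, n_sec)
        t1 = _age_at(cum_out, pb_bot[i], dc, n_sec)
        unsup = (phi / lam) * (np.exp(-lam * t0) - np.exp(-lam * t1)) / pb_mass[i]
        sup = s[s_index[i]] if s_index[i] >= 0 else s_mean
        r = (pb_act[i] - (unsup + sup)) / pb_sd[i]
        if student_t:
            lp += -2.5 * np.log(1.0 + r * r / 4.0) - np.log(pb_sd[i])  # t, nu=4
        else:
            lp += -0.5 * r * r - np.log(pb_sd[i])

    # 226Ra measurements inform the supported levels
    for k in range(ra_act.shape[0]):
        r = (ra_act[k] - s[k]) / ra_sd[k]
        lp += -0.5 * r * r

    # accepted 137Cs anchor: age at the peak depth, with the depth
    # uncertainty converted to age through the local accretion slowness
    if has_anchor:
        t = _age_at(cum_out, anchor_depth, dc, n_sec)
        k = int(anchor_depth / dc)
        if k >= n_sec:
            k = n_sec - 1
        sd = np.sqrt(anchor_age_sd**2 + (anchor_depth_sd * alpha_out[k]) ** 2)
        r = (t - anchor_age) / sd
        lp += -0.5 * r * r - np.log(sd)

    return lp


@njit(cache=True)
def run_mcmc(
    seed, n_burn, n_store,
    dc, n_sec,
    acc_shape, acc_rate, a_w, b_w, phi_shape, phi_rate, s_shape, s_rate,
    pb_top, pb_bot, pb_act, pb_sd, pb_mass, s_index,
    ra_act, ra_sd,
    has_anchor, anchor_depth, anchor_age, anchor_age_sd, anchor_depth_sd,
    lam, student_t, use_likelihood,
    eps0, w0, phi0, s0,
):
    np.random.seed(seed)
    n_s = s0.shape[0]
    n_par = n_sec + 2 + n_s

    eps = eps0.copy()
    w = w0
    phi = phi0
    s = s0.copy()

    alpha = np.empty(n_sec)
    cum = np.empty(n_sec + 1)
    lp = _log_posterior(
        eps, w, phi, s, dc, n_sec,
        acc_shape, acc_rate, a_w, b_w, phi_shape, phi_rate, s_shape, s_rate,
        pb_top, pb_bot, pb_act, pb_sd, pb_mass, s_index, ra_act, ra_sd,
        has_anchor, anchor_depth, anchor_age, anchor_age_sd, anchor_depth_sd,
        lam, student_t, use_likelihood, alpha, cum,
    )
    if not np.isfinite(lp):
        # caller raises with a parameter dump
        return (np.empty((0, n_sec + 1)), np.empty(0), np.empty(0),
                np.empty((0, max(n_s, 1))), -1.0)

    scales = np.full(n_par, 0.25)
    batch_acc = np.zeros(n_par)
    batch_n = 0

    ages_store = np.empty((n_store, n_sec + 1))
    phi_store = np.empty(n_store)
    w_store = np.empty(n_store)
    s_store = np.empty((n_store, max(n_s, 1)))
    n_acc_post = 0
    n_try_post = 0

    total = n_burn + n_store
    for it in range(total):
        for p in range(n_par):
            step = scales[p] * np.random.normal()
            if p < n_sec:
                old = eps[p]
                eps[p] = old * np.exp(step)
            elif p == n_sec:
                old = w
                logit = np.log(w / (1.0 - w)) + step
                w = 1.0 / (1.0 + np.exp(-logit))
            elif p == n_sec + 1:
                old = phi
                phi = old * np.exp(step)
            else:
                old = s[p - n_sec - 2]
                s[p - n_sec - 2] = old * np.exp(step)

            lp_new = _log_posterior(
                eps, w, phi, s, dc, n_sec,
                acc_shape, acc_rate, a_w, b_w, phi_shape, phi_rate, s_shape, s_rate,
                pb_top, pb_bot, pb_act, pb_sd, pb_mass, s_index, ra_act, ra_sd,
                has_anchor, anchor_depth, anchor_age, anchor_age_sd, anchor_depth_sd,
                lam, student_t, use_likelihood, alpha, cum,
            )
            accept = np.log(np.random.random()) < lp_new - lp
            if accept:
                lp = lp_new
            else:
                if p < n_sec:
                    eps[p] = old
                elif p == n_sec:
                    w = old
                elif p == n_sec + 1:
                    phi = old
                else:
                    s[p - n_sec - 2] = old
            if it < n_burn:
                if accept:
                    batch_acc[p] += 1.0
            else:
                n_try_post += 1
                if accept:
                    n_acc_post += 1

        # Robbins-Monro style scale adaptation during burn-in, frozen after
        if it < n_burn:
            batch_n += 1
            if batch_n == 50:
                for p in range(n_par):
                    rate = batch_acc[p] / 50.0
                    scales[p] *= np.exp(1.0 * (rate - 0.3))
                    if scales[p] < 1e-3:
                        scales[p] = 1e-3
                    elif scales[p] > 10.0:
                        scales[p] = 10.0
                    batch_acc[p] = 0.0
                batch_n = 0

        if it >= n_burn:
            j = it - n_burn
            # recompute the current state's ages (alpha/cum hold the last
            # proposal's values, which may have been rejected)
            alpha[0] = eps[0]
            for q in range(1, n_sec):
                alpha[q] = w * alpha[q - 1] + (1.0 - w) * eps[q]
            cum[0] = 0.0
            for q in range(n_sec):
                cum[q + 1] = cum[q] + alpha[q] * dc
            ages_store[j, :] = cum
            phi_store[j] = phi
            w_store[j] = w
            for k in range(n_s):
                s_store[j, k] = s[k]

    acc_rate = n_acc_post / n_try_post if n_try_post > 0 else 0.0
    return ages_store, phi_store, w_store, s_store, acc_rate
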