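"""Compiled Metropolis-within-Gibbs kernels for the augmented posterior.

Everything here operates on flat numpy arrays so that numba can compile
the full sweep; the public, documented surface lives in :mod:`.mcmc` and
:mod:`.model`.  Parameter vectors are laid out as

    theta = [Omega, lam, beta0, beta1, p0, r0, tau, r_const]

and variants are encoded as 0 = constant-r N-mixture, 1 = distance-r
N-mixture, 2 = reduced MRDS (no count terms, observed sizes fixed).

Latent-variable moves touch single rows and maintain the running
detection / count log-likelihood sums incrementally; parameter moves
recompute the affected block (detection terms for beta0/beta1/p0, count
terms for r0/tau/r_const) in full.  The inclusion probability Omega and
the group-size mean lam have closed-form or sufficient-statistic
updates, so a sweep costs O(M) with a small constant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# theta indices
I_OMEGA, I_LAM, I_B0, I_B1, I_P0, I_R0, I_TAU, I_RC = range(8)

V_CONST_R, V_DIST_R, V_REDUCED = 0, 1, 2

LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=False)
def _ztpois_cap(lam, lfact, cmax_all):
    """Smallest k with ZT-Poisson CDF >= 1 - 1e-10, floored at the
    largest recorded count and capped at the factorial table."""
    limit = len(lfact) - 2
    # running Poisson terms lam^k e^-lam / k!, normalised by 1 - e^-lam
    norm = -np.expm1(-lam)
    t = lam * np.exp(-lam)
    s = t
    k = 1
    while s < (1.0 - 1e-10) * norm and k < limit:
        k += 1
        t *= lam / k
        s += t
    cap = k
    if cap < cmax_all:
        cap = cmax_all
    if cap > limit:
        cap = limit
    return cap


@njit(cache=False, inline="always")
def _pdet(d, n, theta):
    sig = np.exp(theta[I_B0] + theta[I_B1] * np.log(n))
    return theta[I_P0] * np.exp(-d * d / (2.0 * sig * sig))


@njit(cache=False, inline="always")
def _row_det(z, y1, y2, p):
    """Detection log-likelihood of one row given its inclusion and size."""
    if z == 0:
        # augmented rows have y = (0,0); Bernoulli(0 | 0) terms are log 1
        return 0.0
    ll = 0.0
    if y1 == 1:
        ll += np.log(p)
    else:
        ll += np.log1p(-p)
    if y2 == 1:
        ll += np.log(p)
    else:
        ll += np.log1p(-p)
    return ll


@njit(cache=False, inline="always")
def _ztbinom_term(c, n, r, lfact):
    """Zero-truncated binomial log pmf of one recorded count."""
    if c > n:
        return -np.inf
    if r >= 1.0:
        return 0.0 if c == n else -np.inf
    l1mr = np.log1p(-r)
    lchoose = lfact[n] - lfact[c] - lfact[n - c]
    return (
        lchoose
        + c * np.log(r)
        + (n - c) * l1mr
        - np.log(-np.expm1(n * l1mr))
    )


@njit(cache=False, inline="always")
def _row_counts(i, n_i, d_i, c, theta, variant, lfact):
    """Count log-likelihood of one observed row under the current params."""
    if variant == V_REDUCED:
        return 0.0
    if variant == V_CONST_R:
        r = theta[I_RC]
    else:
        tau = theta[I_TAU]
        r = theta[I_R0] * np.exp(-d_i * d_i / (2.0 * tau * tau))
    ll = 0.0
    for j in range(2):
        cj = c[i, j]
        if cj >= 0:
            ll += _ztbinom_term(cj, n_i, r, lfact)
    return ll


@njit(cache=False)
def _det_loglik_all(z, n, d, y, theta, M):
    total = 0.0
    for i in range(M):
        if z[i] == 1:
            total += _row_det(1, y[i, 0], y[i, 1], _pdet(d[i], n[i], theta))
    return total


@njit(cache=False)
def _count_loglik_all(z, n, d, c, theta, n_obs, variant, lfact):
    total = 0.0
    for i in range(n_obs):
        total += _row_counts(i, n[i], d[i], c, theta, variant, lfact)
    return total


@njit(cache=False)
def full_logpost(z, n, d, y, c, theta, n_obs, M, w, variant,
                 beta_sd, lam_max, tau_max, beta1_min, lfact):
    """Complete unnormalised log posterior; mirrors the reference
    implementation in :mod:`.model` term by term (used for cross-checks
    and for initial cache values)."""
    omega, lam = theta[I_OMEGA], theta[I_LAM]
    # prior
    if not (0.0 < omega <= 1.0) or not (0.0 < theta[I_P0] <= 1.0):
        return -np.inf
    if not (0.0 < theta[I_R0] <= 1.0) or not (0.0 < theta[I_RC] <= 1.0):
        return -np.inf
    if not (0.0 < lam < lam_max) or not (0.0 < theta[I_TAU] < tau_max):
        return -np.inf
    if theta[I_B1] < beta1_min:
        return -np.inf
    lp = -np.log(lam_max) - np.log(tau_max)
    for bidx in (I_B0, I_B1):
        b = theta[bidx]
        lp += -0.5 * (b / beta_sd) ** 2 - 0.5 * LOG_2PI - np.log(beta_sd)
    # process
    n_in = 0
    s_lfact = 0.0
    s_n = 0
    for i in range(M):
        if d[i] < 0.0 or d[i] >= w or n[i] < 1:
            return -np.inf
        n_in += z[i]
        s_n += n[i]
        s_lfact += lfact[n[i]]
    lp += -M * np.log(w)
    if omega >= 1.0:
        if n_in < M:
            return -np.inf
    else:
        lp += n_in * np.log(omega) + (M - n_in) * np.log1p(-omega)
    lp += s_n * np.log(lam) - M * lam - s_lfact - M * np.log(-np.expm1(-lam))
    # likelihood
    for i in range(M):
        if z[i] == 0 and (y[i, 0] == 1 or y[i, 1] == 1):
            return -np.inf
    lp += _det_loglik_all(z, n, d, y, theta, M)
    lp += _count_loglik_all(z, n, d, c, theta, n_obs, variant, lfact)
    return lp


@njit(cache=False)
def z_full_conditional(omega, p):
    """P(z = 1 | all-zero detection history, d, n) for an augmented row:
    prior odds Omega/(1-Omega) times the miss probability (1-p)^2."""
    a = omega * (1.0 - p) * (1.0 - p)
    return a / (a + (1.0 - omega))


@njit(cache=False)
def run_chain(seed, n_iter, n_burn, thin,
              d, y, c, cmax, n_obs, M, w, variant,
              theta0, z0, n0,
              beta_sd, lam_max, tau_max, beta1_min, lbar,
              scales0, adapt, sample_params, lfact,
              theta_out, N_out, sumz_out, latent_out, acc_out):
    """One MCMC chain; fills the ``*_out`` arrays in place.

    Sweep order: z (Gibbs, augmented rows) -> n (discrete MH) -> d
    (uniform-proposal MH, augmented rows) -> Omega (Beta Gibbs) ->
    lam, beta0, beta1, p0 and the count parameters (random-walk MH on
    log / logit scales).  Proposal scales adapt toward a 0.44 acceptance
    rate during burn-in only, so the post-burn-in kernel satisfies
    detailed balance.
    """
    np.random.seed(seed)
    theta = theta0.copy()
    z = z0.copy()
    n = n0.copy()
    d = d.copy()
    scales = scales0.copy()

    cmax_all = 1
    for i in range(M):
        if cmax[i] > cmax_all:
            cmax_all = cmax[i]
    cap = _ztpois_cap(theta[I_LAM], lfact, cmax_all)
    # discrete step range for size proposals, scaled to the support
    nstep = cap // 12 if cap // 12 > 2 else 2

    cur_det = _det_loglik_all(z, n, d, y, theta, M)
    cur_cnt = _count_loglik_all(z, n, d, c, theta, n_obs, variant, lfact)

    n_params = 8
    acc = np.zeros(n_params)
    tries = np.zeros(n_params)
    acc_batch = np.zeros(n_params)
    tries_batch = np.zeros(n_params)

    keep = 0
    for it in range(n_iter):
        omega = theta[I_OMEGA]
        lam = theta[I_LAM]

        # --- z: Gibbs on augmented rows (observed rows have z = 1) ---
        for i in range(n_obs, M):
            p = _pdet(d[i], n[i], theta)
            pz1 = z_full_conditional(omega, p)
            znew = 1 if np.random.random() < pz1 else 0
            if znew != z[i]:
                term = 2.0 * np.log1p(-p)
                cur_det += term if znew == 1 else -term
                z[i] = znew

        # --- n for z=0 augmented rows: the full conditional is just the
        # truncated size prior, shared by every such row, so draw it
        # exactly from one cumulative table per sweep ---
        t = lam * np.exp(-lam)
        cum0 = np.empty(cap)
        cum0[0] = t
        for m in range(2, cap + 1):
            t *= lam / m
            cum0[m - 1] = cum0[m - 2] + t
        tot0 = cum0[cap - 1]
        for i in range(n_obs, M):
            if z[i] == 0 and cmax[i] <= 1:
                u = np.random.random() * tot0
                lo, hi = 0, cap - 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if cum0[mid] < u:
                        lo = mid + 1
                    else:
                        hi = mid
                n[i] = lo + 1

        # --- n elsewhere: discrete MH on [floor_i, cap]; every 10th sweep
        # an exact Gibbs draw from the enumerated full conditional, which
        # decorrelates the (lam, r) ridge that random-walk moves crawl ---
        if it % 10 == 9:
            for i in range(M):
                if variant == V_REDUCED and i < n_obs:
                    continue
                if i >= n_obs and z[i] == 0:
                    continue  # handled by the shared prior table above
                floor = cmax[i] if cmax[i] > 1 else 1
                if floor >= cap:
                    continue
                old_det = _row_det(z[i], y[i, 0], y[i, 1], _pdet(d[i], n[i], theta))
                old_cnt = _row_counts(i, n[i], d[i], c, theta, variant, lfact) \
                    if i < n_obs else 0.0
                # log weights over the support, sampled by inverse CDF
                best = -np.inf
                nsup = cap - floor + 1
                logw = np.empty(nsup)
                for m in range(floor, cap + 1):
                    lw = m * np.log(lam) - lfact[m]
                    lw += _row_det(z[i], y[i, 0], y[i, 1], _pdet(d[i], m, theta))
                    if i < n_obs:
                        lw += _row_counts(i, m, d[i], c, theta, variant, lfact)
                    logw[m - floor] = lw
                    if lw > best:
                        best = lw
                tot = 0.0
                for j in range(nsup):
                    logw[j] = np.exp(logw[j] - best)
                    tot += logw[j]
                u = np.random.random() * tot
                acc_w = 0.0
                pick = cap
                for j in range(nsup):
                    acc_w += logw[j]
                    if u <= acc_w:
                        pick = floor + j
                        break
                if pick != n[i]:
                    new_det = _row_det(z[i], y[i, 0], y[i, 1], _pdet(d[i], pick, theta))
                    new_cnt = _row_counts(i, pick, d[i], c, theta, variant, lfact) \
                        if i < n_obs else 0.0
                    cur_det += new_det - old_det
                    cur_cnt += new_cnt - old_cnt
                    n[i] = pick

        for i in range(M):
            if variant == V_REDUCED and i < n_obs:
                continue  # recorded group size treated as exact
            if i >= n_obs and z[i] == 0:
                continue  # exact prior draw above
            floor = cmax[i] if cmax[i] > 1 else 1
            step = int(np.random.random() * 2.0 * nstep) - nstep
            if step >= 0:
                step += 1  # symmetric on {-nstep..-1, 1..nstep}
            nn = n[i] + step
            if nn < floor or nn > cap:
                continue
            dlp = (nn - n[i]) * np.log(lam) - (lfact[nn] - lfact[n[i]])
            old_det = _row_det(z[i], y[i, 0], y[i, 1], _pdet(d[i], n[i], theta))
            new_det = _row_det(z[i], y[i, 0], y[i, 1], _pdet(d[i], nn, theta))
            dlp += new_det - old_det
            d_cnt = 0.0
            if i < n_obs and variant != V_REDUCED:
                d_cnt = (_row_counts(i, nn, d[i], c, theta, variant, lfact)
                         - _row_counts(i, n[i], d[i], c, theta, variant, lfact))
                dlp += d_cnt
            if dlp >= 0.0 or np.log(np.random.random()) < dlp:
                n[i] = nn
                cur_det += new_det - old_det
                cur_cnt += d_cnt

        # --- d: latent distances of augmented rows ---
        for i in range(n_obs, M):
            if z[i] == 0:
                # likelihood is flat in d, so draw from the uniform prior
                d[i] = w * np.random.random()
                continue
            dd = w * np.random.random()
            old = 2.0 * np.log1p(-_pdet(d[i], n[i], theta))
            new = 2.0 * np.log1p(-_pdet(dd, n[i], theta))
            if new - old >= 0.0 or np.log(np.random.random()) < new - old:
                d[i] = dd
                cur_det += new - old

        if not sample_params:
            # latent-only mode (used to validate the latent moves against
            # exact enumeration at fixed parameters)
            if it >= n_burn and (it - n_burn) % thin == 0 and keep < len(N_out):
                for k in range(n_params):
                    theta_out[keep, k] = theta[k]
                tot = 0
                sz = 0
                for i in range(M):
                    if z[i] == 1:
                        tot += n[i]
                        sz += 1
                N_out[keep] = tot
                sumz_out[keep] = sz
                if latent_out.shape[1] == 2 * M:
                    for i in range(M):
                        latent_out[keep, i] = z[i]
                        latent_out[keep, M + i] = n[i]
                keep += 1
            continue

        # --- Omega: conjugate Beta full conditional ---
        sumz = 0
        for i in range(M):
            sumz += z[i]
        theta[I_OMEGA] = np.random.beta(1.0 + sumz, 1.0 + M - sumz)

        # --- lam: random-walk MH on the log scale (sufficient stats);
        # two cheap O(M) updates per sweep to track the latent sizes ---
        s_n = 0
        for i in range(M):
            s_n += n[i]
        lam0_sweep = theta[I_LAM]
        for _rep in range(2):
            if scales0[I_LAM] < 1e-10:
                break
            tries[I_LAM] += 1.0
            tries_batch[I_LAM] += 1.0
            lam = theta[I_LAM]
            lam_new = lam * np.exp(scales[I_LAM] * np.random.normal())
            if 0.0 < lam_new < lam_max:
                dlp = (s_n * (np.log(lam_new) - np.log(lam))
                       - M * (lam_new - lam)
                       - M * (np.log(-np.expm1(-lam_new)) - np.log(-np.expm1(-lam)))
                       + (np.log(lam_new) - np.log(lam)))  # log-scale Jacobian
                if dlp >= 0.0 or np.log(np.random.random()) < dlp:
                    theta[I_LAM] = lam_new
                    acc[I_LAM] += 1.0
                    acc_batch[I_LAM] += 1.0
        if theta[I_LAM] != lam0_sweep:
            cap = _ztpois_cap(theta[I_LAM], lfact, cmax_all)
            nstep = cap // 12 if cap // 12 > 2 else 2

        # --- beta0, beta1: Gaussian RW; p0: logit RW (detection block) ---
        for pidx in (I_B0, I_B1, I_P0):
            if scales0[pidx] < 1e-10:
                continue  # explicitly frozen parameter
            tries[pidx] += 1.0
            tries_batch[pidx] += 1.0
            prop = theta.copy()
            dlp = 0.0
            if pidx == I_P0:
                x = np.log(theta[I_P0] / (1.0 - theta[I_P0]))
                xn = x + scales[pidx] * np.random.normal()
                pn = 1.0 / (1.0 + np.exp(-xn))
                prop[I_P0] = pn
                # uniform prior on p0 with logit Jacobian
                dlp += (np.log(pn) + np.log1p(-pn)
                        - np.log(theta[I_P0]) - np.log1p(-theta[I_P0]))
            else:
                bn = theta[pidx] + scales[pidx] * np.random.normal()
                if pidx == I_B1 and bn < beta1_min:
                    continue  # outside the truncated prior support
                prop[pidx] = bn
                dlp += -0.5 * (bn * bn - theta[pidx] * theta[pidx]) / (beta_sd * beta_sd)
            new_det = _det_loglik_all(z, n, d, y, prop, M)
            dlp += new_det - cur_det
            if dlp >= 0.0 or np.log(np.random.random()) < dlp:
                theta[pidx] = prop[pidx]
                cur_det = new_det
                acc[pidx] += 1.0
                acc_batch[pidx] += 1.0

        # --- joint (beta0, beta1) move along the likelihood ridge ---
        # With little spread in log group size only beta0 + beta1*lbar is
        # well identified; a directional proposal (beta0 + eps,
        # beta1 - eps/lbar) mixes the ridge that single-site moves crawl
        # along.  Its adaptive scale lives in the otherwise unused
        # Omega slot (Omega itself is updated by exact Gibbs).
        do_ridge = (scales0[I_OMEGA] >= 1e-10 and scales0[I_B0] >= 1e-10
                    and scales0[I_B1] >= 1e-10)
        if do_ridge:
            tries[I_OMEGA] += 1.0
            tries_batch[I_OMEGA] += 1.0
            prop = theta.copy()
            eps = scales[I_OMEGA] * np.random.normal()
            prop[I_B0] = theta[I_B0] + eps
            prop[I_B1] = theta[I_B1] - eps / lbar
            if prop[I_B1] >= beta1_min:
                dlp = (-0.5 * (prop[I_B0] ** 2 - theta[I_B0] ** 2) / (beta_sd * beta_sd)
                       - 0.5 * (prop[I_B1] ** 2 - theta[I_B1] ** 2) / (beta_sd * beta_sd))
                new_det = _det_loglik_all(z, n, d, y, prop, M)
                dlp += new_det - cur_det
                if dlp >= 0.0 or np.log(np.random.random()) < dlp:
                    theta[I_B0] = prop[I_B0]
                    theta[I_B1] = prop[I_B1]
                    cur_det = new_det
                    acc[I_OMEGA] += 1.0
                    acc_batch[I_OMEGA] += 1.0

        # --- count-model parameters ---
        for pidx in (I_R0, I_TAU, I_RC):
            if variant == V_REDUCED:
                continue
            if variant == V_CONST_R and pidx != I_RC:
                continue
            if variant == V_DIST_R and pidx == I_RC:
                continue
            if scales0[pidx] < 1e-10:
                continue
            tries[pidx] += 1.0
            tries_batch[pidx] += 1.0
            prop = theta.copy()
            dlp = 0.0
            ok = True
            if pidx == I_TAU:
                tn = theta[I_TAU] * np.exp(scales[pidx] * np.random.normal())
                if not (0.0 < tn < tau_max):
                    ok = False
                else:
                    prop[I_TAU] = tn
                    dlp += np.log(tn) - np.log(theta[I_TAU])  # Jacobian
            else:
                x = np.log(theta[pidx] / (1.0 - theta[pidx]))
                xn = x + scales[pidx] * np.random.normal()
                rn = 1.0 / (1.0 + np.exp(-xn))
                prop[pidx] = rn
                dlp += (np.log(rn) + np.log1p(-rn)
                        - np.log(theta[pidx]) - np.log1p(-theta[pidx]))
            if ok:
                new_cnt = _count_loglik_all(z, n, d, c, prop, n_obs, variant, lfact)
                dlp += new_cnt - cur_cnt
                if dlp >= 0.0 or np.log(np.random.random()) < dlp:
                    theta[pidx] = prop[pidx]
                    cur_cnt = new_cnt
                    acc[pidx] += 1.0
                    acc_batch[pidx] += 1.0

        # --- proposal adaptation (burn-in only) and cache refresh ---
        if adapt and it < n_burn and (it + 1) % 50 == 0:
            for pidx in range(n_params):
                if tries_batch[pidx] > 0:
                    rate = acc_batch[pidx] / tries_batch[pidx]
                    fac = np.exp(rate - 0.44)
                    s = scales[pidx] * fac
                    if s < 1e-8:
                        s = 1e-8
                    elif s > 20.0:
                        s = 20.0
                    scales[pidx] = s
                acc_batch[pidx] = 0.0
                tries_batch[pidx] = 0.0
        if (it + 1) % 200 == 0:
            # refresh incremental caches to kill floating-point drift
            cur_det = _det_loglik_all(z, n, d, y, theta, M)
            cur_cnt = _count_loglik_all(z, n, d, c, theta, n_obs, variant, lfact)

        # --- record ---
        if it >= n_burn and (it - n_burn) % thin == 0:
            if keep < len(N_out):
                for k in range(n_params):
                    theta_out[keep, k] = theta[k]
                tot = 0
                sz = 0
                for i in range(M):
                    if z[i] == 1:
                        tot += n[i]
                        sz += 1
                N_out[keep] = tot
                sumz_out[keep] = sz
                if latent_out.shape[1] == 2 * M:
                    for i in range(M):
                        latent_out[keep, i] = z[i]
                        latent_out[keep, M + i] = n[i]
                keep += 1

    for pidx in range(n_params):
        acc_out[pidx] = acc[pidx] / tries[pidx] if tries[pidx] > 0 else np.nan
    return keep
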