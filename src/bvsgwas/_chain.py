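"""Numba MCMC kernel for the mixture-prior whole-genome regression.

One cycle updates, in order: the overall mean (Gibbs), each polygenic
effect (single-site Gibbs using the sparse rows of A^-1), SNP effects and
mixture indicators in random disjoint pairs (the two indicators are
enumerated jointly with the two effects integrated out analytically, then
the effects are drawn from their bivariate normal conditional), the
mixture proportion (conjugate Beta), the polygenic and residual variances
(scaled-inverse-chi-square-shaped conditionals under bounded uniform
priors), and finally a Metropolis-Hastings scaling move that multiplies
both mixture variances by a common factor f (log-symmetric proposal)
while rescaling every SNP effect by sqrt(f); its acceptance ratio
f * exp(-dSSE / (2 sigma_e^2)) carries the Jacobian of the joint
transformation.  The residual vector is maintained incrementally and
recomputed from scratch every 1,000 cycles to bound drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True)
def _draw_variance(S, df, lb, ub):
    """Draw from p(v) ~ v^(-df/2-1) exp(-S/2v)-shaped density truncated to [lb, ub].

    This is the full conditional of a variance under a bounded uniform
    prior: scaled inverse chi-square with ``df`` degrees of freedom and
    scale S/df.  Rejection sampling against the untruncated density with
    a clamped fallback; df <= 0 (fewer than 3 observations) falls back to
    a uniform draw, exact for the no-data case.
    """
    if df <= 0.0:
        return lb + (ub - lb) * np.random.random()
    if S <= 0.0:
        return lb
    for _ in range(200):
        chi2 = 2.0 * np.random.standard_gamma(df / 2.0)
        if chi2 > 0.0:
            v = S / chi2
            if lb <= v <= ub:
                return v
    v = S / df  # fall back to the conditional mode region, clamped
    return min(max(v, lb), ub)


@njit(cache=True)
def _log_bernoulli(delta, pi1):
    if delta == 1:
        return np.log(pi1) if pi1 > 0.0 else NEG_INF
    return np.log(1.0 - pi1) if pi1 < 1.0 else NEG_INF


@njit(cache=True)
def _update_snp_pair(Xs, xtx, r, g_snp, alpha, delta, k1, k2,
                     sg0, sg1, se2, pi1):
    """Joint marginalized update of two indicators and their effects."""
    n = r.size
    x1 = Xs[k1]
    x2 = Xs[k2]
    s11 = xtx[k1]
    s22 = xtx[k2]
    s12 = 0.0
    t1 = 0.0
    t2 = 0.0
    for j in range(n):
        s12 += x1[j] * x2[j]
        t1 += x1[j] * r[j]
        t2 += x2[j] * r[j]
    a1_old = alpha[k1]
    a2_old = alpha[k2]
    t1 += s11 * a1_old + s12 * a2_old
    t2 += s12 * a1_old + s22 * a2_old
    b1 = t1 / se2
    b2 = t2 / se2

    logw = np.empty(4)
    best = NEG_INF
    for c in range(4):
        d1 = c & 1
        d2 = (c >> 1) & 1
        v1 = sg1 if d1 == 1 else sg0
        v2 = sg1 if d2 == 1 else sg0
        M11 = 1.0 / v1 + s11 / se2
        M22 = 1.0 / v2 + s22 / se2
        M12 = s12 / se2
        det = M11 * M22 - M12 * M12
        quad = (M22 * b1 * b1 - 2.0 * M12 * b1 * b2 + M11 * b2 * b2) / det
        lw = (_log_bernoulli(d1, pi1) + _log_bernoulli(d2, pi1)
              - 0.5 * (np.log(v1) + np.log(v2)) - 0.5 * np.log(det) + 0.5 * quad)
        logw[c] = lw
        if lw > best:
            best = lw
    total = 0.0
    for c in range(4):
        logw[c] = np.exp(logw[c] - best)
        total += logw[c]
    u = np.random.random() * total
    c = 0
    acc = logw[0]
    while acc < u and c < 3:
        c += 1
        acc += logw[c]
    d1 = c & 1
    d2 = (c >> 1) & 1

    v1 = sg1 if d1 == 1 else sg0
    v2 = sg1 if d2 == 1 else sg0
    M11 = 1.0 / v1 + s11 / se2
    M22 = 1.0 / v2 + s22 / se2
    M12 = s12 / se2
    det = M11 * M22 - M12 * M12
    mean1 = (M22 * b1 - M12 * b2) / det
    mean2 = (M11 * b2 - M12 * b1) / det
    # Cholesky of the 2x2 covariance M^-1
    c11 = M22 / det
    c12 = -M12 / det
    c22 = M11 / det
    L11 = np.sqrt(c11)
    L21 = c12 / L11
    L22 = np.sqrt(max(c22 - L21 * L21, 0.0))
    z1 = np.random.normal()
    z2 = np.random.normal()
    a1 = mean1 + L11 * z1
    a2 = mean2 + L21 * z1 + L22 * z2

    dz1 = a1 - a1_old
    dz2 = a2 - a2_old
    for j in range(n):
        step = x1[j] * dz1 + x2[j] * dz2
        g_snp[j] += step
        r[j] -= step
    alpha[k1] = a1
    alpha[k2] = a2
    delta[k1] = d1
    delta[k2] = d2


@njit(cache=True)
def _update_snp_single(Xs, xtx, r, g_snp, alpha, delta, k, sg0, sg1, se2, pi1):
    n = r.size
    x = Xs[k]
    s = xtx[k]
    t = 0.0
    for j in range(n):
        t += x[j] * r[j]
    a_old = alpha[k]
    t += s * a_old
    b = t / se2
    best = NEG_INF
    logw = np.empty(2)
    for d in range(2):
        v = sg1 if d == 1 else sg0
        prec = 1.0 / v + s / se2
        lw = _log_bernoulli(d, pi1) - 0.5 * np.log(v) - 0.5 * np.log(prec) + 0.5 * b * b / prec
        logw[d] = lw
        if lw > best:
            best = lw
    w0 = np.exp(logw[0] - best)
    w1 = np.exp(logw[1] - best)
    d = 1 if np.random.random() * (w0 + w1) > w0 else 0
    v = sg1 if d == 1 else sg0
    prec = 1.0 / v + s / se2
    a_new = b / prec + np.random.normal() / np.sqrt(prec)
    dz = a_new - a_old
    for j in range(n):
        step = x[j] * dz
        g_snp[j] += step
        r[j] -= step
    alpha[k] = a_new
    delta[k] = d


@njit(cache=True)
def run_chain_kernel(
    y, Xs, xtx, phen_row,
    ainv_indptr, ainv_indices, ainv_data,
    mu_init, pi1_init, beta_a, beta_b,
    sg0_init, ratio, sa_init, se_init,
    sa_lb, sa_ub, se_lb, se_ub, sg0_lb, sg0_ub,
    n_cycles, burn_in, thin,
    mh_step, mh_target, tune_interval,
    seed,
    update_mu, update_pi, update_var_a, update_var_e, do_mh, pair_updates,
):
    np.random.seed(seed)
    n_p = y.size
    m = Xs.shape[0]
    q = phen_row.size

    mu = mu_init
    a = np.zeros(q)
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    sg0 = sg0_init
    sg1 = ratio * sg0_init
    sa2 = sa_init
    se2 = se_init
    pi1 = pi1_init

    r = y - mu
    g_snp = np.zeros(n_p)

    n_post = n_cycles - burn_in
    n_stored = (n_post + thin - 1) // thin
    stored = np.zeros((n_stored, 8))
    delta_sum = np.zeros(m)
    alpha_sum = np.zeros(m)
    a_sum = np.zeros(q)
    mu_sum = 0.0

    step = mh_step
    win_prop = 0
    win_acc = 0
    post_prop = 0
    post_acc = 0
    max_drift = 0.0
    store_i = 0

    for cyc in range(n_cycles):
        post = cyc >= burn_in

        # --- mean ---
        if update_mu == 1 and n_p > 0:
            rbar = 0.0
            for j in range(n_p):
                rbar += r[j]
            rbar /= n_p
            mu_new = mu + rbar + np.random.normal() * np.sqrt(se2 / n_p)
            dmu = mu_new - mu
            for j in range(n_p):
                r[j] -= dmu
            mu = mu_new

        # --- polygenic sweep (pedigree order) ---
        if q > 0:
            for i in range(q):
                aii = 0.0
                s_off = 0.0
                for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    jj = ainv_indices[ptr]
                    if jj == i:
                        aii = ainv_data[ptr]
                    else:
                        s_off += ainv_data[ptr] * a[jj]
                prec = aii / sa2
                num = -s_off / sa2
                row = phen_row[i]
                if row >= 0:
                    e = r[row] + a[i]
                    prec += 1.0 / se2
                    num += e / se2
                a_new = num / prec + np.random.normal() / np.sqrt(prec)
                if row >= 0:
                    r[row] += a[i] - a_new
                a[i] = a_new

        # --- SNP sweep in random disjoint pairs ---
        if m > 0:
            perm = np.random.permutation(m)
            if pair_updates == 1:
                npairs = m // 2
                for p in range(npairs):
                    _update_snp_pair(Xs, xtx, r, g_snp, alpha, delta,
                                     perm[2 * p], perm[2 * p + 1],
                                     sg0, sg1, se2, pi1)
                if m % 2 == 1:
                    _update_snp_single(Xs, xtx, r, g_snp, alpha, delta,
                                       perm[m - 1], sg0, sg1, se2, pi1)
            else:
                for p in range(m):
                    _update_snp_single(Xs, xtx, r, g_snp, alpha, delta,
                                       perm[p], sg0, sg1, se2, pi1)

        # --- mixture proportion ---
        nd = 0
        for k in range(m):
            nd += delta[k]
        if update_pi == 1:
            g1 = np.random.standard_gamma(beta_a + nd)
            g2 = np.random.standard_gamma(beta_b + m - nd)
            pi1 = g1 / (g1 + g2)

        # --- variance components ---
        if update_var_a == 1 and q > 0:
            S = 0.0
            for i in range(q):
                row_dot = 0.0
                for ptr in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    row_dot += ainv_data[ptr] * a[ainv_indices[ptr]]
                S += a[i] * row_dot
            sa2 = _draw_variance(S, q - 2.0, sa_lb, sa_ub)
        if update_var_e == 1:
            sse = 0.0
            for j in range(n_p):
                sse += r[j] * r[j]
            se2 = _draw_variance(sse, n_p - 2.0, se_lb, se_ub)

        # --- MH scaling move on the mixture variances ---
        if do_mh == 1 and m > 0:
            f = np.exp(step * (2.0 * np.random.random() - 1.0))
            sg0_new = f * sg0
            win_prop += 1
            if post:
                post_prop += 1
            if sg0_lb <= sg0_new <= sg0_ub:
                sf = np.sqrt(f)
                dsse = 0.0
                for j in range(n_p):
                    rn = r[j] + (1.0 - sf) * g_snp[j]
                    dsse += rn * rn - r[j] * r[j]
                log_acc = np.log(f) - dsse / (2.0 * se2)
                if np.log(np.random.random()) < log_acc:
                    for j in range(n_p):
                        r[j] += (1.0 - sf) * g_snp[j]
                        g_snp[j] *= sf
                    for k in range(m):
                        alpha[k] *= sf
                    sg0 = sg0_new
                    sg1 = ratio * sg0_new
                    win_acc += 1
                    if post:
                        post_acc += 1
            # step tuning during burn-in only (keeps the post-burn-in kernel fixed)
            if (not post) and win_prop >= tune_interval:
                rate = win_acc / win_prop
                step *= np.exp(0.8 * (rate - mh_target))
                if step < 1e-4:
                    step = 1e-4
                elif step > 5.0:
                    step = 5.0
                win_prop = 0
                win_acc = 0

        # --- periodic residual recompute (drift guard) ---
        if (cyc + 1) % 1000 == 0 and n_p > 0:
            g_true = np.zeros(n_p)
            for k in range(m):
                ak = alpha[k]
                if ak != 0.0:
                    xk = Xs[k]
                    for j in range(n_p):
                        g_true[j] += xk[j] * ak
            r_true = y - mu - g_true
            for i in range(q):
                row = phen_row[i]
                if row >= 0:
                    r_true[row] -= a[i]
            for j in range(n_p):
                d = abs(r_true[j] - r[j])
                if d > max_drift:
                    max_drift = d
                r[j] = r_true[j]
                g_snp[j] = g_true[j]

        # --- accumulate ---
        if post:
            mu_sum += mu
            for k in range(m):
                delta_sum[k] += delta[k]
                alpha_sum[k] += alpha[k]
            for i in range(q):
                a_sum[i] += a[i]
            if (cyc - burn_in) % thin == 0:
                vsnp = 0.0
                if n_p > 1:
                    gbar = 0.0
                    for j in range(n_p):
                        gbar += g_snp[j]
                    gbar /= n_p
                    for j in range(n_p):
                        vsnp += (g_snp[j] - gbar) ** 2
                    vsnp /= n_p
                stored[store_i, 0] = mu
                stored[store_i, 1] = sa2
                stored[store_i, 2] = se2
                stored[store_i, 3] = sg0
                stored[store_i, 4] = sg1
                stored[store_i, 5] = pi1
                stored[store_i, 6] = vsnp
                stored[store_i, 7] = nd
                store_i += 1

    denom = float(n_post) if n_post > 0 else 1.0
    accept_rate = post_acc / post_prop if post_prop > 0 else np.nan
    return (stored, delta_sum / denom, alpha_sum / denom, a_sum / denom,
            mu_sum / denom, accept_rate, step, max_drift)
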