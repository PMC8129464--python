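"""Compiled Metropolis-within-Gibbs kernel for the full hierarchy.

One call runs one chain over packed, flat data arrays.  Mean-type
parameters (species means, supra-species mean, human-population mean)
use exact bivariate-normal conjugate draws; curve parameters, scale
factors and variance/correlation parameters use adaptive random-walk
Metropolis steps; mixture indicators use categorical Gibbs draws.
Parameters with no data in their conditional are drawn exactly from
that conditional prior, so prior-only fits mix perfectly.

Component indicator coding (0-based): ``0..K-1`` species
exchangeability, ``K`` human-only exchangeability, ``K+1``
non-exchangeable.
"""

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))

_ADAPT_WINDOW = 50
_ADAPT_TARGET = 0.35


@njit(cache=True)
def run_chain(
    seed,
    n_iter,
    n_burn,
    thin,
    # animal data (flat, padded by offsets)
    sp_idx,          # (M,) int64 species index per study
    a_off,           # (M+1,) int64
    a_dose, a_n, a_r,   # flat float64
    # human data
    h_off,           # (L+1,) int64
    h_dose, h_n, h_r,
    # mixture weights and non-exchangeable priors
    W,               # (L, K+2) float64
    m0,              # (L, 2)
    r0,              # (L, 3) sd1, sd2, corr of the non-exchangeable cov
    # hyperpriors
    b1, s1, b2, s2,
    zc,              # (4,) half-normal scales for tau1..tau4
    c1, c2,          # half-normal scales for sigma1, sigma2
    d_ref,
    dmeanlog, dsdlog,   # (K,) translation prior
    nu,              # (L,) bridging prior sd
    # fixed-parameter flags (oracle reductions / Model E)
    fix_mu_s, fix_psi, fix_delta,
    fix_eps,         # (L,) bool
    # initial / fixed values
    init_mu_s,       # (K, 2)
    init_psi,        # (3,) tau1, tau2, rho
    init_delta,      # (K,)
    # outputs
    out,             # (n_kept, P) float64, filled in place
    zout,            # (n_kept, L) int64
):
    np.random.seed(seed)
    M = sp_idx.shape[0]
    K = init_mu_s.shape[0]
    L = h_off.shape[0] - 1

    # ---- state ----------------------------------------------------------
    theta = np.empty((M, 2))
    for i in range(M):
        theta[i, 0] = init_mu_s[sp_idx[i], 0]
        theta[i, 1] = init_mu_s[sp_idx[i], 1]
    mu_s = init_mu_s.copy()
    m = np.array([b1, b2])
    mu_h = np.array([b1, b2])
    gamma = np.empty((L, 2))
    for l in range(L):
        gamma[l, 0] = b1
        gamma[l, 1] = b2
    delta = init_delta.copy()
    eps = np.ones(L)
    tau1, tau2, rho = init_psi[0], init_psi[1], init_psi[2]
    tau3 = 0.674 * zc[2]
    tau4 = 0.674 * zc[3]
    sig1 = 0.674 * c1
    sig2 = 0.674 * c2
    kappa = 0.0
    eta = 0.0
    zz = np.zeros(L, dtype=np.int64)
    for l in range(L):
        u = np.random.random()
        acc = 0.0
        zz[l] = K + 1
        for c in range(K + 2):
            acc += W[l, c]
            if u < acc:
                zz[l] = c
                break

    # ---- proposal scales and acceptance counters ------------------------
    th_step = np.full(M, 0.4)
    ga_step = np.full(L, 0.4)
    ga2_step = np.full(L, 0.4)
    # empirical-covariance accumulators for the 2-d blocks (adaptive
    # Metropolis); accumulation runs during the first half of burn-in,
    # shaped proposals are used from the second half onward
    th_m1 = np.zeros(M); th_m2 = np.zeros(M)
    th_c11 = np.zeros(M); th_c12 = np.zeros(M); th_c22 = np.zeros(M)
    ga_m1 = np.zeros(L); ga_m2 = np.zeros(L)
    ga_c11 = np.zeros(L); ga_c12 = np.zeros(L); ga_c22 = np.zeros(L)
    adapt_cnt = 0
    half_burn = n_burn // 2
    de_step = np.full(K, 0.2)
    ep_step = np.full(L, 0.2)
    cv_step = np.full(9, 0.4)   # tau1,tau2,rho, sig1,sig2,kappa, tau3,tau4,eta
    th_acc = np.zeros(M)
    ga_acc = np.zeros(L)
    ga2_acc = np.zeros(L)
    de_acc = np.zeros(K)
    ep_acc = np.zeros(L)
    cv_acc = np.zeros(9)

    lwork = np.empty(K + 2)

    # ---- helpers (closures over state) ----------------------------------
    def bvn_lp(x1, x2, mm1, mm2, ss1, ss2, cc):
        om = 1.0 - cc * cc
        u1 = (x1 - mm1) / ss1
        u2 = (x2 - mm2) / ss2
        return (
            -LOG2PI
            - np.log(ss1 * ss2)
            - 0.5 * np.log(om)
            - 0.5 * (u1 * u1 - 2.0 * cc * u1 * u2 + u2 * u2) / om
        )

    def curve_ll(t1, t2, scale, dose, nn, rr, j0, j1):
        s = np.exp(t2)
        ll = 0.0
        for j in range(j0, j1):
            lp = t1 + s * np.log(scale * dose[j] / d_ref)
            if lp > 0.0:
                ll += rr[j] * lp - nn[j] * (lp + np.log1p(np.exp(-lp)))
            else:
                ll += rr[j] * lp - nn[j] * np.log1p(np.exp(lp))
        return ll

    def comp_params(l, c):
        if c < K:
            return mu_s[c, 0], mu_s[c, 1], tau1, tau2, rho
        elif c == K:
            return mu_h[0], mu_h[1], tau3, tau4, eta
        return m0[l, 0], m0[l, 1], r0[l, 0], r0[l, 1], r0[l, 2]

    def prec2(ss1, ss2, cc):
        om = 1.0 - cc * cc
        return (
            1.0 / (ss1 * ss1 * om),
            -cc / (ss1 * ss2 * om),
            1.0 / (ss2 * ss2 * om),
        )

    def conj_draw(pm1, pm2, pa, pb, pd, qa, qb, qd, nobs, sy1, sy2):
        A11 = pa + nobs * qa
        A12 = pb + nobs * qb
        A22 = pd + nobs * qd
        rhs1 = pa * pm1 + pb * pm2 + qa * sy1 + qb * sy2
        rhs2 = pb * pm1 + pd * pm2 + qb * sy1 + qd * sy2
        det = A11 * A22 - A12 * A12
        C11 = A22 / det
        C12 = -A12 / det
        C22 = A11 / det
        mm1 = C11 * rhs1 + C12 * rhs2
        mm2 = C12 * rhs1 + C22 * rhs2
        l11 = np.sqrt(C11)
        l21 = C12 / l11
        l22 = np.sqrt(C22 - l21 * l21)
        u1 = np.random.normal()
        u2 = np.random.normal()
        return mm1 + l11 * u1, mm2 + l21 * u1 + l22 * u2

    def shaped_prop(stepv, cnt, s1v, s2v, c11, c12, c22):
        u1 = np.random.normal()
        u2 = np.random.normal()
        if cnt < 200:
            return stepv * u1, stepv * u2
        mu1 = s1v / cnt
        mu2 = s2v / cnt
        C11 = c11 / cnt - mu1 * mu1 + 1e-4
        C12 = c12 / cnt - mu1 * mu2
        C22 = c22 / cnt - mu2 * mu2 + 1e-4
        l11 = np.sqrt(C11)
        l21 = C12 / l11
        l22 = np.sqrt(max(C22 - l21 * l21, 1e-8))
        return stepv * l11 * u1, stepv * (l21 * u1 + l22 * u2)

    def psi_ll(t1v, t2v, rv):
        s = 0.0
        for i in range(M):
            k = sp_idx[i]
            s += bvn_lp(theta[i, 0], theta[i, 1], mu_s[k, 0], mu_s[k, 1], t1v, t2v, rv)
        for l in range(L):
            if zz[l] < K:
                s += bvn_lp(
                    gamma[l, 0], gamma[l, 1], mu_s[zz[l], 0], mu_s[zz[l], 1], t1v, t2v, rv
                )
        return s

    def sigma_ll(s1v, s2v, kv):
        s = 0.0
        for k in range(K):
            s += bvn_lp(mu_s[k, 0], mu_s[k, 1], m[0], m[1], s1v, s2v, kv)
        return s

    def phi_ll(t3v, t4v, ev):
        s = 0.0
        for l in range(L):
            if zz[l] == K:
                s += bvn_lp(gamma[l, 0], gamma[l, 1], mu_h[0], mu_h[1], t3v, t4v, ev)
        return s

    keep = 0
    for it in range(n_iter):
        # -- 1. study-level curve parameters ------------------------------
        for i in range(M):
            k = sp_idx[i]
            cur = curve_ll(
                theta[i, 0], theta[i, 1], delta[k], a_dose, a_n, a_r, a_off[i], a_off[i + 1]
            ) + bvn_lp(theta[i, 0], theta[i, 1], mu_s[k, 0], mu_s[k, 1], tau1, tau2, rho)
            d1, d2 = shaped_prop(
                th_step[i], adapt_cnt, th_m1[i], th_m2[i], th_c11[i], th_c12[i], th_c22[i]
            )
            p1 = theta[i, 0] + d1
            p2 = theta[i, 1] + d2
            prop = curve_ll(
                p1, p2, delta[k], a_dose, a_n, a_r, a_off[i], a_off[i + 1]
            ) + bvn_lp(p1, p2, mu_s[k, 0], mu_s[k, 1], tau1, tau2, rho)
            if np.log(np.random.random()) < prop - cur:
                theta[i, 0] = p1
                theta[i, 1] = p2
                th_acc[i] += 1.0

        # -- 2. species means (conjugate) ---------------------------------
        if not fix_mu_s:
            qa, qb, qd = prec2(tau1, tau2, rho)
            pa, pb, pd = prec2(sig1, sig2, kappa)
            for k in range(K):
                sy1 = 0.0
                sy2 = 0.0
                nobs = 0.0
                for i in range(M):
                    if sp_idx[i] == k:
                        sy1 += theta[i, 0]
                        sy2 += theta[i, 1]
                        nobs += 1.0
                for l in range(L):
                    if zz[l] == k:
                        sy1 += gamma[l, 0]
                        sy2 += gamma[l, 1]
                        nobs += 1.0
                mu_s[k, 0], mu_s[k, 1] = conj_draw(
                    m[0], m[1], pa, pb, pd, qa, qb, qd, nobs, sy1, sy2
                )

        # -- 3. supra-species mean (conjugate) ----------------------------
        pa = 1.0 / (s1 * s1)
        pd = 1.0 / (s2 * s2)
        if K > 0:
            qa, qb, qd = prec2(sig1, sig2, kappa)
            sy1 = 0.0
            sy2 = 0.0
            for k in range(K):
                sy1 += mu_s[k, 0]
                sy2 += mu_s[k, 1]
            m[0], m[1] = conj_draw(b1, b2, pa, 0.0, pd, qa, qb, qd, float(K), sy1, sy2)
        else:
            m[0] = b1 + s1 * np.random.normal()
            m[1] = b2 + s2 * np.random.normal()

        # -- 3b. interweaved (non-centered) update of the supra-species
        # mean: with e_k = mu_s_k - m held fixed, the study-level and
        # subgroup-level terms inform m directly, which decouples its
        # mixing from the between-species variance.
        if K > 0 and not fix_mu_s:
            qa, qb, qd = prec2(tau1, tau2, rho)
            pa = 1.0 / (s1 * s1)
            pd = 1.0 / (s2 * s2)
            sy1 = 0.0
            sy2 = 0.0
            nobs = 0.0
            for i in range(M):
                k = sp_idx[i]
                sy1 += theta[i, 0] - (mu_s[k, 0] - m[0])
                sy2 += theta[i, 1] - (mu_s[k, 1] - m[1])
                nobs += 1.0
            for l in range(L):
                if zz[l] < K:
                    sy1 += gamma[l, 0] - (mu_s[zz[l], 0] - m[0])
                    sy2 += gamma[l, 1] - (mu_s[zz[l], 1] - m[1])
                    nobs += 1.0
            new1, new2 = conj_draw(b1, b2, pa, 0.0, pd, qa, qb, qd, nobs, sy1, sy2)
            for k in range(K):
                mu_s[k, 0] += new1 - m[0]
                mu_s[k, 1] += new2 - m[1]
            m[0] = new1
            m[1] = new2

        # -- 4. human-population mean (conjugate) -------------------------
        qa, qb, qd = prec2(tau3, tau4, eta)
        sy1 = 0.0
        sy2 = 0.0
        nobs = 0.0
        for l in range(L):
            if zz[l] == K:
                sy1 += gamma[l, 0]
                sy2 += gamma[l, 1]
                nobs += 1.0
        mu_h[0], mu_h[1] = conj_draw(b1, b2, pa, 0.0, pd, qa, qb, qd, nobs, sy1, sy2)

        # -- 5. subgroup curve parameters ---------------------------------
        for l in range(L):
            cm1, cm2, cs1, cs2, cc = comp_params(l, zz[l])
            if h_off[l + 1] == h_off[l]:
                # no data: exact conditional draw from the component
                u1 = np.random.normal()
                u2 = np.random.normal()
                gamma[l, 0] = cm1 + cs1 * u1
                gamma[l, 1] = cm2 + cs2 * (cc * u1 + np.sqrt(1.0 - cc * cc) * u2)
            else:
                cur = curve_ll(
                    gamma[l, 0], gamma[l, 1], eps[l], h_dose, h_n, h_r, h_off[l], h_off[l + 1]
                ) + bvn_lp(gamma[l, 0], gamma[l, 1], cm1, cm2, cs1, cs2, cc)
                d1, d2 = shaped_prop(
                    ga_step[l], adapt_cnt, ga_m1[l], ga_m2[l], ga_c11[l], ga_c12[l], ga_c22[l]
                )
                p1 = gamma[l, 0] + d1
                p2 = gamma[l, 1] + d2
                prop = curve_ll(
                    p1, p2, eps[l], h_dose, h_n, h_r, h_off[l], h_off[l + 1]
                ) + bvn_lp(p1, p2, cm1, cm2, cs1, cs2, cc)
                if np.log(np.random.random()) < prop - cur:
                    gamma[l, 0] = p1
                    gamma[l, 1] = p2
                    ga_acc[l] += 1.0
                # slope-only refinement: the log-slope direction mixes
                # slowest when doses cluster at the panel's low end
                cur = curve_ll(
                    gamma[l, 0], gamma[l, 1], eps[l], h_dose, h_n, h_r, h_off[l], h_off[l + 1]
                ) + bvn_lp(gamma[l, 0], gamma[l, 1], cm1, cm2, cs1, cs2, cc)
                p2 = gamma[l, 1] + ga2_step[l] * np.random.normal()
                prop = curve_ll(
                    gamma[l, 0], p2, eps[l], h_dose, h_n, h_r, h_off[l], h_off[l + 1]
                ) + bvn_lp(gamma[l, 0], p2, cm1, cm2, cs1, cs2, cc)
                if np.log(np.random.random()) < prop - cur:
                    gamma[l, 1] = p2
                    ga2_acc[l] += 1.0

        # -- 5b. joint (z, gamma) independence move: propose a fresh
        # component from the prior weights and fresh curve parameters
        # from that component; the acceptance ratio reduces to the
        # human-likelihood ratio.  This lets subgroups jump between
        # well-separated mixture components in one step.
        for l in range(L):
            if h_off[l + 1] == h_off[l]:
                continue
            u = np.random.random()
            acc = 0.0
            cnew = K + 1
            for c in range(K + 2):
                acc += W[l, c]
                if u < acc:
                    cnew = c
                    break
            cm1, cm2, cs1, cs2, cc = comp_params(l, cnew)
            u1 = np.random.normal()
            u2 = np.random.normal()
            p1 = cm1 + cs1 * u1
            p2 = cm2 + cs2 * (cc * u1 + np.sqrt(1.0 - cc * cc) * u2)
            cur = curve_ll(
                gamma[l, 0], gamma[l, 1], eps[l], h_dose, h_n, h_r, h_off[l], h_off[l + 1]
            )
            prop = curve_ll(p1, p2, eps[l], h_dose, h_n, h_r, h_off[l], h_off[l + 1])
            if np.log(np.random.random()) < prop - cur:
                gamma[l, 0] = p1
                gamma[l, 1] = p2
                zz[l] = cnew

        # -- 6. mixture indicators (categorical Gibbs) --------------------
        for l in range(L):
            best = -np.inf
            for c in range(K + 2):
                if W[l, c] <= 0.0:
                    lwork[c] = -np.inf
                    continue
                cm1, cm2, cs1, cs2, cc = comp_params(l, c)
                lwork[c] = np.log(W[l, c]) + bvn_lp(
                    gamma[l, 0], gamma[l, 1], cm1, cm2, cs1, cs2, cc
                )
                if lwork[c] > best:
                    best = lwork[c]
            tot = 0.0
            for c in range(K + 2):
                lwork[c] = np.exp(lwork[c] - best)
                tot += lwork[c]
            u = np.random.random() * tot
            acc = 0.0
            for c in range(K + 2):
                acc += lwork[c]
                if u < acc:
                    zz[l] = c
                    break

        # -- 7. translation factors ---------------------------------------
        if not fix_delta:
            for k in range(K):
                has = False
                for i in range(M):
                    if sp_idx[i] == k and a_off[i + 1] > a_off[i]:
                        has = True
                ld = np.log(delta[k])
                if not has:
                    delta[k] = np.exp(dmeanlog[k] + dsdlog[k] * np.random.normal())
                    continue
                cur = -0.5 * ((ld - dmeanlog[k]) / dsdlog[k]) ** 2
                for i in range(M):
                    if sp_idx[i] == k:
                        cur += curve_ll(
                            theta[i, 0], theta[i, 1], delta[k],
                            a_dose, a_n, a_r, a_off[i], a_off[i + 1],
                        )
                ldp = ld + de_step[k] * np.random.normal()
                dp = np.exp(ldp)
                prop = -0.5 * ((ldp - dmeanlog[k]) / dsdlog[k]) ** 2
                for i in range(M):
                    if sp_idx[i] == k:
                        prop += curve_ll(
                            theta[i, 0], theta[i, 1], dp,
                            a_dose, a_n, a_r, a_off[i], a_off[i + 1],
                        )
                if np.log(np.random.random()) < prop - cur:
                    delta[k] = dp
                    de_acc[k] += 1.0

        # -- 8. bridging factors ------------------------------------------
        for l in range(L):
            if fix_eps[l]:
                continue
            if h_off[l + 1] == h_off[l]:
                e = 1.0 + nu[l] * np.random.normal()
                while e <= 0.0 or e >= 2.0:
                    e = 1.0 + nu[l] * np.random.normal()
                eps[l] = e
            else:
                ep = eps[l] + ep_step[l] * np.random.normal()
                if 0.0 < ep < 2.0:
                    cur = -0.5 * ((eps[l] - 1.0) / nu[l]) ** 2 + curve_ll(
                        gamma[l, 0], gamma[l, 1], eps[l],
                        h_dose, h_n, h_r, h_off[l], h_off[l + 1],
                    )
                    prop = -0.5 * ((ep - 1.0) / nu[l]) ** 2 + curve_ll(
                        gamma[l, 0], gamma[l, 1], ep,
                        h_dose, h_n, h_r, h_off[l], h_off[l + 1],
                    )
                    if np.log(np.random.random()) < prop - cur:
                        eps[l] = ep
                        ep_acc[l] += 1.0

        # -- 9. within-species covariance (tau1, tau2, rho) ---------------
        if not fix_psi:
            nmem = M
            for l in range(L):
                if zz[l] < K:
                    nmem += 1
            if nmem == 0:
                tau1 = np.abs(np.random.normal()) * zc[0]
                tau2 = np.abs(np.random.normal()) * zc[1]
                rho = 2.0 * np.random.random() - 1.0
            else:
                lt = np.log(tau1)
                ltp = lt + cv_step[0] * np.random.normal()
                tp = np.exp(ltp)
                cur = psi_ll(tau1, tau2, rho) - 0.5 * (tau1 / zc[0]) ** 2 + lt
                prop = psi_ll(tp, tau2, rho) - 0.5 * (tp / zc[0]) ** 2 + ltp
                if np.log(np.random.random()) < prop - cur:
                    tau1 = tp
                    cv_acc[0] += 1.0
                lt = np.log(tau2)
                ltp = lt + cv_step[1] * np.random.normal()
                tp = np.exp(ltp)
                cur = psi_ll(tau1, tau2, rho) - 0.5 * (tau2 / zc[1]) ** 2 + lt
                prop = psi_ll(tau1, tp, rho) - 0.5 * (tp / zc[1]) ** 2 + ltp
                if np.log(np.random.random()) < prop - cur:
                    tau2 = tp
                    cv_acc[1] += 1.0
                rp = rho + cv_step[2] * np.random.normal()
                if -1.0 < rp < 1.0:
                    if np.log(np.random.random()) < psi_ll(tau1, tau2, rp) - psi_ll(
                        tau1, tau2, rho
                    ):
                        rho = rp
                        cv_acc[2] += 1.0

        # -- 10. between-species covariance (sigma1, sigma2, kappa) -------
        if K == 0 or fix_mu_s:
            sig1 = np.abs(np.random.normal()) * c1
            sig2 = np.abs(np.random.normal()) * c2
            kappa = 2.0 * np.random.random() - 1.0
        else:
            lt = np.log(sig1)
            ltp = lt + cv_step[3] * np.random.normal()
            tp = np.exp(ltp)
            cur = sigma_ll(sig1, sig2, kappa) - 0.5 * (sig1 / c1) ** 2 + lt
            prop = sigma_ll(tp, sig2, kappa) - 0.5 * (tp / c1) ** 2 + ltp
            if np.log(np.random.random()) < prop - cur:
                sig1 = tp
                cv_acc[3] += 1.0
            lt = np.log(sig2)
            ltp = lt + cv_step[4] * np.random.normal()
            tp = np.exp(ltp)
            cur = sigma_ll(sig1, sig2, kappa) - 0.5 * (sig2 / c2) ** 2 + lt
            prop = sigma_ll(sig1, tp, kappa) - 0.5 * (tp / c2) ** 2 + ltp
            if np.log(np.random.random()) < prop - cur:
                sig2 = tp
                cv_acc[4] += 1.0
            kp = kappa + cv_step[5] * np.random.normal()
            if -1.0 < kp < 1.0:
                if np.log(np.random.random()) < sigma_ll(sig1, sig2, kp) - sigma_ll(
                    sig1, sig2, kappa
                ):
                    kappa = kp
                    cv_acc[5] += 1.0

        # -- 11. between-subgroup covariance (tau3, tau4, eta) ------------
        nmem = 0
        for l in range(L):
            if zz[l] == K:
                nmem += 1
        if nmem == 0:
            tau3 = np.abs(np.random.normal()) * zc[2]
            tau4 = np.abs(np.random.normal()) * zc[3]
            eta = 2.0 * np.random.random() - 1.0
        else:
            lt = np.log(tau3)
            ltp = lt + cv_step[6] * np.random.normal()
            tp = np.exp(ltp)
            cur = phi_ll(tau3, tau4, eta) - 0.5 * (tau3 / zc[2]) ** 2 + lt
            prop = phi_ll(tp, tau4, eta) - 0.5 * (tp / zc[2]) ** 2 + ltp
            if np.log(np.random.random()) < prop - cur:
                tau3 = tp
                cv_acc[6] += 1.0
            lt = np.log(tau4)
            ltp = lt + cv_step[7] * np.random.normal()
            tp = np.exp(ltp)
            cur = phi_ll(tau3, tau4, eta) - 0.5 * (tau4 / zc[3]) ** 2 + lt
            prop = phi_ll(tau3, tp, eta) - 0.5 * (tp / zc[3]) ** 2 + ltp
            if np.log(np.random.random()) < prop - cur:
                tau4 = tp
                cv_acc[7] += 1.0
            ep_ = eta + cv_step[8] * np.random.normal()
            if -1.0 < ep_ < 1.0:
                if np.log(np.random.random()) < phi_ll(tau3, tau4, ep_) - phi_ll(
                    tau3, tau4, eta
                ):
                    eta = ep_
                    cv_acc[8] += 1.0

        # -- covariance accumulation (first half of burn-in) --------------
        if 50 <= it < half_burn:
            adapt_cnt += 1
            for i in range(M):
                th_m1[i] += theta[i, 0]
                th_m2[i] += theta[i, 1]
                th_c11[i] += theta[i, 0] * theta[i, 0]
                th_c12[i] += theta[i, 0] * theta[i, 1]
                th_c22[i] += theta[i, 1] * theta[i, 1]
            for l in range(L):
                ga_m1[l] += gamma[l, 0]
                ga_m2[l] += gamma[l, 1]
                ga_c11[l] += gamma[l, 0] * gamma[l, 0]
                ga_c12[l] += gamma[l, 0] * gamma[l, 1]
                ga_c22[l] += gamma[l, 1] * gamma[l, 1]

        # -- adaptation during burn-in ------------------------------------
        if it < n_burn and (it + 1) % _ADAPT_WINDOW == 0:
            for i in range(M):
                f = np.exp(1.2 * (th_acc[i] / _ADAPT_WINDOW - _ADAPT_TARGET))
                th_step[i] = min(10.0, max(1e-3, th_step[i] * f))
                th_acc[i] = 0.0
            for l in range(L):
                f = np.exp(1.2 * (ga_acc[l] / _ADAPT_WINDOW - _ADAPT_TARGET))
                ga_step[l] = min(10.0, max(1e-3, ga_step[l] * f))
                ga_acc[l] = 0.0
                f = np.exp(1.2 * (ga2_acc[l] / _ADAPT_WINDOW - _ADAPT_TARGET))
                ga2_step[l] = min(10.0, max(1e-3, ga2_step[l] * f))
                ga2_acc[l] = 0.0
                f = np.exp(1.2 * (ep_acc[l] / _ADAPT_WINDOW - _ADAPT_TARGET))
                ep_step[l] = min(10.0, max(1e-3, ep_step[l] * f))
                ep_acc[l] = 0.0
            for k in range(K):
                f = np.exp(1.2 * (de_acc[k] / _ADAPT_WINDOW - _ADAPT_TARGET))
                de_step[k] = min(10.0, max(1e-3, de_step[k] * f))
                de_acc[k] = 0.0
            for j in range(9):
                f = np.exp(1.2 * (cv_acc[j] / _ADAPT_WINDOW - _ADAPT_TARGET))
                cv_step[j] = min(10.0, max(1e-3, cv_step[j] * f))
                cv_acc[j] = 0.0

        # -- storage ------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0:
            col = 0
            for i in range(M):
                out[keep, col] = theta[i, 0]
                out[keep, col + 1] = theta[i, 1]
                col += 2
            for k in range(K):
                out[keep, col] = mu_s[k, 0]
                out[keep, col + 1] = mu_s[k, 1]
                col += 2
            out[keep, col] = m[0]
            out[keep, col + 1] = m[1]
            col += 2
            for l in range(L):
                out[keep, col] = gamma[l, 0]
                out[keep, col + 1] = gamma[l, 1]
                col += 2
            out[keep, col] = mu_h[0]
            out[keep, col + 1] = mu_h[1]
            col += 2
            for k in range(K):
                out[keep, col] = delta[k]
                col += 1
            for l in range(L):
                out[keep, col] = eps[l]
                col += 1
            out[keep, col] = tau1
            out[keep, col + 1] = tau2
            out[keep, col + 2] = tau3
            out[keep, col + 3] = tau4
            col += 4
            out[keep, col] = sig1
            out[keep, col + 1] = sig2
            col += 2
            out[keep, col] = rho
            out[keep, col + 1] = kappa
            out[keep, col + 2] = eta
            for l in range(L):
                zout[keep, l] = zz[l]
            keep += 1

    return keep
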