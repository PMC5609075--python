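"""Numba inner loops for the EM and Gibbs sweeps.

``Wt`` is the variant-major (m x n) centered genotype design so each
variant's column is a contiguous row.  Residuals are updated in place.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweep(Wt, wts, r, v, cls, active_idx, logP, tau, sigma_e2, C,
                u_cls, z_eff, counts):
    """One Gibbs sweep over active variants: sample class then effect.

    For each variant the class is drawn with probability proportional to
    P_k times the marginal likelihood of the residual under v ~ N(0, tau_k),
    then the effect from its conditional normal (exactly 0 for the spike).
    """
    K = tau.shape[0]
    n = r.shape[0]
    logw = np.empty(K)
    means = np.empty(K)
    variances = np.empty(K)
    for ii in range(active_idx.shape[0]):
        i = active_idx[ii]
        col = Wt[i]
        rhs = 0.0
        for j in range(n):
            rhs += col[j] * wts[j] * r[j]
        rhs += C[i] * v[i]
        maxl = -1.0e300
        for k in range(K):
            if tau[k] <= 0.0:
                means[k] = 0.0
                variances[k] = 0.0
                logw[k] = logP[k]
            else:
                Vk = 1.0 / (C[i] / sigma_e2 + 1.0 / tau[k])
                mk = Vk * rhs / sigma_e2
                means[k] = mk
                variances[k] = Vk
                logw[k] = logP[k] + 0.5 * np.log(Vk / tau[k]) + 0.5 * mk * mk / Vk
            if logw[k] > maxl:
                maxl = logw[k]
        tot = 0.0
        for k in range(K):
            logw[k] = np.exp(logw[k] - maxl)
            tot += logw[k]
        u = u_cls[ii] * tot
        ksel = K - 1
        acc = 0.0
        for k in range(K):
            acc += logw[k]
            if u <= acc:
                ksel = k
                break
        if tau[ksel] <= 0.0:
            v_new = 0.0
        else:
            v_new = means[ksel] + np.sqrt(variances[ksel]) * z_eff[ii]
        dv = v_new - v[i]
        if dv != 0.0:
            for j in range(n):
                r[j] -= col[j] * dv
        v[i] = v_new
        cls[i] = ksel
        counts[ksel] += 1


@njit(cache=True)
def em_sweep(Wt, wts, r, v, varv, active_idx, logP, tau, sigma_e2, C, resp):
    """Mean-field coordinate update of every active variant's mixture posterior.

    Writes class responsibilities into ``resp``, posterior means into ``v``
    and posterior variances into ``varv``; keeps the residual in sync with
    the posterior-mean effects.  Returns the variational objective terms
    contributed by the variant blocks: the Gaussian prior-plus-entropy term
    and the assignment entropy (the P-weighted class term is recomputed by
    the caller from ``resp``).
    """
    K = tau.shape[0]
    n = r.shape[0]
    q = np.empty(K)
    means = np.empty(K)
    variances = np.empty(K)
    pen_gauss = 0.0
    ent_class = 0.0
    for ii in range(active_idx.shape[0]):
        i = active_idx[ii]
        col = Wt[i]
        rhs = 0.0
        for j in range(n):
            rhs += col[j] * wts[j] * r[j]
        rhs += C[i] * v[i]
        maxl = -1.0e300
        for k in range(K):
            if tau[k] <= 0.0:
                means[k] = 0.0
                variances[k] = 0.0
                q[k] = logP[k]
            else:
                Vk = 1.0 / (C[i] / sigma_e2 + 1.0 / tau[k])
                mk = Vk * rhs / sigma_e2
                means[k] = mk
                variances[k] = Vk
                q[k] = logP[k] + 0.5 * np.log(Vk / tau[k]) + 0.5 * mk * mk / Vk
            if q[k] > maxl:
                maxl = q[k]
        tot = 0.0
        for k in range(K):
            q[k] = np.exp(q[k] - maxl)
            tot += q[k]
        v_new = 0.0
        ev2 = 0.0
        for k in range(K):
            q[k] /= tot
            resp[i, k] = q[k]
            if tau[k] > 0.0:
                v_new += q[k] * means[k]
                ev2 += q[k] * (means[k] * means[k] + variances[k])
                pen_gauss += q[k] * (0.5 * np.log(variances[k] / tau[k]) + 0.5
                                     - (means[k] * means[k] + variances[k])
                                     / (2.0 * tau[k]))
            if q[k] > 1e-300:
                ent_class -= q[k] * np.log(q[k])
        varv[i] = ev2 - v_new * v_new
        dv = v_new - v[i]
        if dv != 0.0:
            for j in range(n):
                r[j] -= col[j] * dv
        v[i] = v_new
    return pen_gauss, ent_class


@njit(cache=True)
def polygenic_sweep(Q, a, r, wts, rec_of, sigma_a2, sigma_e2, z):
    """Single-site Gibbs update of polygenic values using the A-inverse rows."""
    n_ped = a.shape[0]
    for p in range(n_ped):
        prec = Q[p, p] / sigma_a2
        num = 0.0
        rec = rec_of[p]
        if rec >= 0:
            prec += wts[rec] / sigma_e2
            num += wts[rec] * (r[rec] + a[p]) / sigma_e2
        dot = 0.0
        for j in range(n_ped):
            dot += Q[p, j] * a[j]
        dot -= Q[p, p] * a[p]
        num -= dot / sigma_a2
        mean = num / prec
        a_new = mean + z[p] / np.sqrt(prec)
        if rec >= 0:
            r[rec] -= a_new - a[p]
        a[p] = a_new
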