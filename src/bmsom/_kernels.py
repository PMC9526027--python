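"""Compiled inner loops for the marginalized likelihood and its gradient.

The cell likelihood is element-wise over species x site (x visit) and the
gradient with respect to the linear predictors has the closed form

    d cell_ll / d eta_ij    = P(Z=1 | y_ij.) - psi_ij
    d cell_ll / d zeta_ijk  = P(Z=1 | y_ij.) * (y_ijk - theta_ijk)

so everything reduces to one fused pass over the data array.  Cell weights
``W`` carry the clip mask (0/1); the data-augmented variant rescales the
returned gradients per species afterwards, which is exact because they are
linear in the weight.
"""
import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def _log1pexp(x):
    # log(1 + exp(x)) without overflow
    if x > 35.0:
        return x
    return np.log1p(np.exp(x))


@njit(cache=False, fastmath=True)
def cell_kernel_visit(eta, zeta, y, V, anyobs, W):
    """Likelihood + gradient pass, visit-varying detection.

    eta (S,J), zeta (S,J,K), y float (S,J,K), V bool (S,J,K),
    anyobs bool (S,J), W float (S,J) cell weights.
    Returns (weighted ll, raw cell ll (S,J), g_eta (S,J), g_zeta (S,J,K)).
    """
    S, J = eta.shape
    K = zeta.shape[2]
    ll = 0.0
    cell = np.zeros((S, J))
    g_eta = np.zeros((S, J))
    g_zeta = np.zeros((S, J, K))
    th_buf = np.empty(K)
    for i in range(S):
        for j in range(J):
            e = eta[i, j]
            # one exp serves log psi, log(1-psi) and psi itself
            if e > 0.0:
                ee = np.exp(-e)
                lp_psi = -np.log1p(ee)
                lp_1m = lp_psi - e
                psi = 1.0 / (1.0 + ee)
            else:
                ee = np.exp(e)
                lp_1m = -np.log1p(ee)
                lp_psi = lp_1m + e
                psi = ee / (1.0 + ee)
            det = 0.0
            for k in range(K):
                if V[i, j, k]:
                    z = zeta[i, j, k]
                    if z > 0.0:
                        ez = np.exp(-z)
                        lt = -np.log1p(ez)
                        l1t = lt - z
                        th_buf[k] = 1.0 / (1.0 + ez)
                    else:
                        ez = np.exp(z)
                        l1t = -np.log1p(ez)
                        lt = l1t + z
                        th_buf[k] = ez / (1.0 + ez)
                    if y[i, j, k] > 0.0:
                        det += lt
                    else:
                        det += l1t
            la = lp_psi + det
            if anyobs[i, j]:
                cl = la
                pA = 1.0
            else:
                if la > lp_1m:
                    cl = la + np.log1p(np.exp(lp_1m - la))
                else:
                    cl = lp_1m + np.log1p(np.exp(la - lp_1m))
                pA = np.exp(la - cl)
            cell[i, j] = cl
            w = W[i, j]
            ll += w * cl
            g_eta[i, j] = w * (pA - psi)
            coef = w * pA
            for k in range(K):
                if V[i, j, k]:
                    g_zeta[i, j, k] = coef * (y[i, j, k] - th_buf[k])
    return ll, cell, g_eta, g_zeta


@njit(cache=False, fastmath=True)
def cell_kernel_const(eta, zeta2, n1, n0, anyobs, W):
    """Fast path when detection probability is constant across visits.

    zeta2 (S,), n1/n0 (S,J) counts of detections / misses among live visits.
    Returns (weighted ll, raw cell ll, g_eta, g_zeta2 per species-site).
    """
    S, J = eta.shape
    ll = 0.0
    cell = np.zeros((S, J))
    g_eta = np.zeros((S, J))
    g_z = np.zeros((S, J))
    for i in range(S):
        z = zeta2[i]
        if z > 0.0:
            lt = -_log1pexp(-z)
            l1t = lt - z
        else:
            l1t = -_log1pexp(z)
            lt = l1t + z
        th = np.exp(lt)
        for j in range(J):
            e = eta[i, j]
            if e > 0.0:
                lp_psi = -_log1pexp(-e)
                lp_1m = lp_psi - e
            else:
                lp_1m = -_log1pexp(e)
                lp_psi = lp_1m + e
            psi = np.exp(lp_psi)
            la = lp_psi + n1[i, j] * lt + n0[i, j] * l1t
            if anyobs[i, j]:
                cl = la
                pA = 1.0
            else:
                if la > lp_1m:
                    cl = la + np.log1p(np.exp(lp_1m - la))
                else:
                    cl = lp_1m + np.log1p(np.exp(la - lp_1m))
                pA = np.exp(la - cl)
            cell[i, j] = cl
            w = W[i, j]
            ll += w * cl
            g_eta[i, j] = w * (pA - psi)
            g_z[i, j] = w * pA * (n1[i, j] - th * (n1[i, j] + n0[i, j]))
    return ll, cell, g_eta, g_z


@njit(cache=False, fastmath=True)
def fused_logp_grad(a, c, so, C, sd, W, y, V, anyobs, Wcell):
    """Fully fused likelihood + gradient for the non-augmented variants.

    a, c (S,) intercepts; so (T,S) per-species occupancy slopes with their
    expanded covariates C (T,S,J); sd (Td,S) detection slopes with visit
    covariates W (Td,J,K); Wcell (S,J) cell weights (clip mask).
    Returns (ll, cell, grad_a, grad_c, grad_so, grad_sd) where the slope
    gradients are per term and species.
    """
    T = so.shape[0]
    Td = sd.shape[0]
    S, J, K = y.shape
    cell = np.zeros((S, J))
    grad_a = np.zeros(S)
    grad_c = np.zeros(S)
    grad_so = np.zeros((T, S))
    grad_sd = np.zeros((Td, S))
    zeta = np.empty(K)
    th = np.empty(K)
    ll = 0.0
    for i in range(S):
        ai = a[i]
        ci = c[i]
        for j in range(J):
            e = ai
            for t in range(T):
                e += so[t, i] * C[t, i, j]
            if e > 0.0:
                ee = np.exp(-e)
                lp_psi = -np.log1p(ee)
                lp_1m = lp_psi - e
                psi = 1.0 / (1.0 + ee)
            else:
                ee = np.exp(e)
                lp_1m = -np.log1p(ee)
                lp_psi = lp_1m + e
                psi = ee / (1.0 + ee)
            det = 0.0
            for k in range(K):
                if V[i, j, k]:
                    z = ci
                    for t in range(Td):
                        z += sd[t, i] * W[t, j, k]
                    zeta[k] = z
                    if z > 0.0:
                        ez = np.exp(-z)
                        lt = -np.log1p(ez)
                        l1t = lt - z
                        th[k] = 1.0 / (1.0 + ez)
                    else:
                        ez = np.exp(z)
                        l1t = -np.log1p(ez)
                        lt = l1t + z
                        th[k] = ez / (1.0 + ez)
                    if y[i, j, k] > 0.0:
                        det += lt
                    else:
                        det += l1t
            la = lp_psi + det
            if anyobs[i, j]:
                cl = la
                pA = 1.0
            else:
                if la > lp_1m:
                    cl = la + np.log1p(np.exp(lp_1m - la))
                else:
                    cl = lp_1m + np.log1p(np.exp(la - lp_1m))
                pA = np.exp(la - cl)
            w = Wcell[i, j]
            cell[i, j] = cl
            ll += w * cl
            ge = w * (pA - psi)
            grad_a[i] += ge
            for t in range(T):
                grad_so[t, i] += ge * C[t, i, j]
            coef = w * pA
            for k in range(K):
                if V[i, j, k]:
                    gz = coef * (y[i, j, k] - th[k])
                    grad_c[i] += gz
                    for t in range(Td):
                        grad_sd[t, i] += gz * W[t, j, k]
    return ll, cell, grad_a, grad_c, grad_so, grad_sd
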