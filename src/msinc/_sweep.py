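"""Numba kernels for the collapsed Gibbs E-step.

The sampler state is held in flat preallocated arrays.  Each pixel i owns at
most s clusters (one per view), stored in slots 0..M[i]-1 of the second
axis; empty slots are kept exactly zero so a newly created cluster can take
slot M[i] without reallocation.  Per cluster we maintain

    b    = sum_{j in cluster} P_j' x_ij                 (l,)
    G    = sum_{j in cluster} P_j' P_j                  (l, l)
    quad = mu' Cinv mu  with  Cinv = G + r I,  mu = C b (scalar)
    logdetC = log|C| = -log|G + r I|

and globally Qsum = sum of all quad, so that B = beta + (xx_total - Qsum)/2.

All mixture arithmetic is done in the log domain; the B^A ratios are
computed as A_minus*log(B_minus) - A*log(B_m) since A is huge for real
images.  Cholesky factorizations of the l x l precision are hand-rolled
(l is 1-4 in practice) to keep the per-observation cost at a few dozen
flops.
"""

from math import exp, lgamma, log, sqrt  # noqa: F401  (lgamma used by model)

import numpy as np
from numba import njit


@njit(cache=False)
def _chol_solve(Ginv, bv, L, y, mu, l):
    """Cholesky-solve Ginv mu = bv; return (mu' bv, log|Ginv^-1|)."""
    for ii in range(l):
        for jj in range(ii + 1):
            ssum = Ginv[ii, jj]
            for kk in range(jj):
                ssum -= L[ii, kk] * L[jj, kk]
            if ii == jj:
                if ssum <= 0.0:
                    return np.nan, np.nan
                L[ii, ii] = sqrt(ssum)
            else:
                L[ii, jj] = ssum / L[jj, jj]
    for ii in range(l):
        ssum = bv[ii]
        for kk in range(ii):
            ssum -= L[ii, kk] * y[kk]
        y[ii] = ssum / L[ii, ii]
    for ii in range(l - 1, -1, -1):
        ssum = y[ii]
        for kk in range(ii + 1, l):
            ssum -= L[kk, ii] * mu[kk]
        mu[ii] = ssum / L[ii, ii]
    quad = 0.0
    logdet_cinv = 0.0
    for ii in range(l):
        quad += mu[ii] * bv[ii]
        logdet_cinv += 2.0 * log(L[ii, ii])
    return quad, -logdet_cinv


@njit(cache=False)
def _slot_stats(Gs, bs, r, l, Gn, bn, L, y, mu):
    """(quad, log|C|) of one cluster slot; adds the r I prior term."""
    for a in range(l):
        bn[a] = bs[a]
        for c in range(l):
            Gn[a, c] = Gs[a, c]
        Gn[a, a] += r
    return _chol_solve(Gn, bn, L, y, mu, l)


@njit(cache=False)
def _downdate_obs(i, j, S, N, M, b, G, quad, logdetC, PtP, PtX, Qsum, r,
                  Gn, bn, L, y, mu):
    """Remove observation (i, j) from its cluster; compact labels if it
    empties.  Returns Qsum with the (i, j) contribution removed."""
    l = b.shape[2]
    c = S[i, j]
    for a in range(l):
        b[i, c, a] -= PtX[j, a, i]
        for cc in range(l):
            G[i, c, a, cc] -= PtP[j, a, cc]
    N[i, c] -= 1
    Qsum -= quad[i, c]
    if N[i, c] == 0:
        last = M[i] - 1
        if last != c:
            N[i, c] = N[i, last]
            quad[i, c] = quad[i, last]
            logdetC[i, c] = logdetC[i, last]
            for a in range(l):
                b[i, c, a] = b[i, last, a]
                for cc in range(l):
                    G[i, c, a, cc] = G[i, last, a, cc]
            for jj in range(S.shape[1]):
                if S[i, jj] == last:
                    S[i, jj] = c
        N[i, last] = 0
        quad[i, last] = 0.0
        logdetC[i, last] = 0.0
        for a in range(l):
            b[i, last, a] = 0.0
            for cc in range(l):
                G[i, last, a, cc] = 0.0
        M[i] = last
    else:
        q, ld = _slot_stats(G[i, c], b[i, c], r, l, Gn, bn, L, y, mu)
        quad[i, c] = q
        logdetC[i, c] = ld
        Qsum += q
    return Qsum


@njit(cache=False)
def _eval_candidates(i, j, N, M, b, G, quad, logdetC, PtP, PtX, xxij,
                     xx_total, Qsum, A, A_minus, lgA, lgA_minus, r, gamma_,
                     beta_, Gn, bn, L, y, mu, logp, qn, ldn):
    """Unnormalized log-probabilities for assigning (i, j) to each existing
    cluster of pixel i (slots 0..M[i]-1) or a new one (slot M[i]).

    The CRP denominator (s - 1 + gamma), common to all candidates, is left
    out; an empty cluster's prior covariance I/r supplies the r^{l/2}
    prefactor of the new-cluster case through its log-determinant.
    Statistics for (i, j) must already be downdated.
    """
    l = b.shape[2]
    Mi = M[i]
    B_minus = beta_ + 0.5 * (xx_total - xxij - Qsum)
    base = A_minus * log(B_minus) + lgA - lgA_minus
    for m in range(Mi + 1):
        for a in range(l):
            bn[a] = b[i, m, a] + PtX[j, a, i]
            for c in range(l):
                Gn[a, c] = G[i, m, a, c] + PtP[j, a, c]
            Gn[a, a] += r
        q, ld = _chol_solve(Gn, bn, L, y, mu, l)
        qn[m] = q
        ldn[m] = ld
        if m < Mi:
            prior = log(float(N[i, m]))
            ld_old = logdetC[i, m]
            q_old = quad[i, m]
        else:
            prior = log(gamma_)
            ld_old = -l * log(r)
            q_old = 0.0
        B_m = beta_ + 0.5 * (xx_total - (Qsum - q_old + q))
        logp[m] = prior + base - A * log(B_m) + 0.5 * (ld - ld_old)
    return Mi


@njit(cache=False)
def gibbs_sweep(S, N, M, b, G, quad, logdetC, PtP, PtX, xx_obs, xx_total,
                Qsum, A, d_js, lgA, lgA_minus_arr, r, gamma_, beta_,
                uniforms):
    """One Gibbs sweep over all (pixel, view) pairs in row-major order.

    ``uniforms[i, j]`` drives the categorical draw for observation (i, j),
    so the sweep is a pure function of the state and the uniform matrix.
    Returns (Qsum, err_i, err_j); err_i >= 0 flags a non-finite
    log-probability at that observation.
    """
    n, s = S.shape
    l = b.shape[2]
    Gn = np.empty((l, l))
    bn = np.empty(l)
    L = np.empty((l, l))
    y = np.empty(l)
    mu = np.empty(l)
    logp = np.empty(s + 1)
    qn = np.empty(s + 1)
    ldn = np.empty(s + 1)
    for i in range(n):
        for j in range(s):
            Qsum = _downdate_obs(i, j, S, N, M, b, G, quad, logdetC,
                                 PtP, PtX, Qsum, r, Gn, bn, L, y, mu)
            Mi = _eval_candidates(
                i, j, N, M, b, G, quad, logdetC, PtP, PtX, xx_obs[i, j],
                xx_total, Qsum, A, A - 0.5 * d_js[j], lgA, lgA_minus_arr[j],
                r, gamma_, beta_, Gn, bn, L, y, mu, logp, qn, ldn)
            mx = -1.0e308
            for m in range(Mi + 1):
                if not np.isfinite(logp[m]):
                    return Qsum, i, j
                if logp[m] > mx:
                    mx = logp[m]
            tot = 0.0
            for m in range(Mi + 1):
                logp[m] = exp(logp[m] - mx)
                tot += logp[m]
            u = uniforms[i, j] * tot
            pick = Mi
            acc = 0.0
            for m in range(Mi + 1):
                acc += logp[m]
                if u <= acc:
                    pick = m
                    break
            if pick == M[i]:
                M[i] += 1
            S[i, j] = pick
            N[i, pick] += 1
            for a in range(l):
                b[i, pick, a] += PtX[j, a, i]
                for cc in range(l):
                    G[i, pick, a, cc] += PtP[j, a, cc]
            Qsum -= quad[i, pick]
            quad[i, pick] = qn[pick]
            logdetC[i, pick] = ldn[pick]
            Qsum += qn[pick]
    return Qsum, -1, -1
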