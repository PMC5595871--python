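"""Brute-force numerical oracles for the collapsed sampler.

These evaluate the un-collapsed model by nested numerical integration —
each latent scalar z by high-order Gauss-Legendre quadrature on a wide
window around its posterior mode, the precision sigma by adaptive
quadrature against its Gamma prior — and never touch the collapsed
statistics they are checking.  Restricted to tiny instances
(d_j = 1, l = 1)."""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)
_LOG_2PI = math.log(2.0 * math.pi)


def _cluster_integral(sigma: float, xs: np.ndarray, ps: np.ndarray, r: float) -> float:
    """integral over z of N(z; 0, 1/(sigma r)) prod_j N(x_j; p_j z, 1/sigma),
    by 160-node Gauss-Legendre on +-12 posterior standard deviations."""
    prec = sigma * (r + float(ps @ ps))
    mu = sigma * float(ps @ xs) / prec
    sd = 1.0 / math.sqrt(prec)
    half = 12.0 * sd
    z = mu + half * _GL_NODES
    log_f = 0.5 * (math.log(sigma * r) - _LOG_2PI) - 0.5 * sigma * r * z**2
    for x, p in zip(xs, ps):
        log_f += 0.5 * (math.log(sigma) - _LOG_2PI) - 0.5 * sigma * (x - p * z) ** 2
    return half * float(_GL_WEIGHTS @ np.exp(log_f))


def marginal_likelihood(
    X: np.ndarray, S: np.ndarray, P: np.ndarray,
    alpha: float, beta: float, r: float,
) -> float:
    """p(X | S, P) for the scalar-feature model (d_j = 1, l = 1).

    X is (n, s) observations, S is (n, s) integer assignments, P is (s,)
    projection scalars.  sigma is integrated numerically against its
    Gamma(alpha, beta) prior; every latent z by Gauss-Legendre."""
    X = np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=int)
    P = np.asarray(P, dtype=float)
    n, s = X.shape

    clusters = []
    for i in range(n):
        for m in np.unique(S[i]):
            members = np.flatnonzero(S[i] == m)
            clusters.append((X[i, members], P[members]))

    log_gamma_norm = alpha * math.log(beta) - math.lgamma(alpha)

    def integrand(sigma: float) -> float:
        if sigma <= 0.0:
            return 0.0
        val = math.exp(log_gamma_norm + (alpha - 1.0) * math.log(sigma) - beta * sigma)
        for xs, ps in clusters:
            val *= _cluster_integral(sigma, xs, ps, r)
        return val

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=0.0, epsrel=1e-11, limit=400,
    )
    return val


def assignment_probabilities(
    X: np.ndarray, S: np.ndarray, P: np.ndarray,
    i: int, j: int, alpha: float, beta: float, r: float, gamma: float,
) -> tuple[np.ndarray, list[int]]:
    """Normalized p(s_ij = m | X, S_-ij, P, ...) by brute force.

    Candidates are the distinct labels used by the other views of pixel i
    (in sorted order) plus one fresh label; returns (probabilities,
    candidate labels).  The exchangeable CRP prior factor is analytic; the
    likelihood factor is the numerically integrated marginal."""
    S = np.asarray(S, dtype=int).copy()
    n, s = S.shape
    others = [jj for jj in range(s) if jj != j]
    labels = sorted(int(v) for v in np.unique(S[i, others]))
    fresh = max(labels) + 1
    cands = labels + [fresh]

    probs = []
    for m in cands:
        if m == fresh:
            prior = gamma / (s - 1 + gamma)
        else:
            prior = np.sum(S[i, others] == m) / (s - 1 + gamma)
        S_try = S.copy()
        S_try[i, j] = m
        probs.append(prior * marginal_likelihood(X, S_try, P, alpha, beta, r))
    probs = np.asarray(probs)
    return probs / probs.sum(), cands
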