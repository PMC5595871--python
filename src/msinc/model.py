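"""Collapsed stochastic EM for the multi-view spectral-consistency model.

A pixel i is spectrally consistent when one latent vector z_i reconstructs
its features in every spectral slice j through slice-specific projections,
x_ij ~ N(P_j z_i, I/sigma).  Inconsistent pixels need several latent
vectors; which views share which vector is a per-pixel mixture whose
weights follow a Dirichlet process (stick-breaking, concentration gamma).
With conjugate priors sigma ~ Gamma(alpha, beta) and z ~ N(0, I/(sigma r)),
the latents, weights and sigma marginalize analytically, leaving a Gibbs
sampler over the assignment variables s_ij (E-step) alternated with a MAP
update of the projections P_j (M-step).

The per-pixel inconsistency score is

    psi_i = (1/T) sum_t 1[M_i(t) > 1],

the fraction of sampler iterations in which pixel i needed more than one
latent vector — a probability-like degeneration score in [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _sweep
from .features import FeatureMatrix

__all__ = [
    "Hyperparams",
    "ModelState",
    "InconsistencyMap",
    "init_state",
    "compute_A",
    "compute_B",
    "cluster_posterior",
    "estep_assignment_logprobs",
    "estep_sample",
    "mstep_update",
    "run_sem",
    "inconsistency_scores",
    "select_latent_dim",
]

logger = logging.getLogger("msinc")


@dataclass(frozen=True)
class Hyperparams:
    """Fixed scalars controlling the priors and the run length.

    gamma : Dirichlet-process concentration (larger -> new clusters easier).
    alpha, beta : shape and rate of the Gamma prior on the precision sigma.
    r : scale of the latent prior precision, z ~ N(0, I/(sigma r)).
    l : latent dimension.
    T : number of SEM iterations.
    burn_in : iterations dropped from the psi average (0 = use all).
    """

    gamma: float = 1.2
    alpha: float = 1.0
    beta: float = 1.0
    r: float = 1.0
    l: int = 2
    T: int = 400
    seed: int = 0
    burn_in: int = 0

    def __post_init__(self) -> None:
        if min(self.gamma, self.alpha, self.beta, self.r) <= 0:
            raise ValueError("gamma, alpha, beta, r must all be positive")
        if self.l < 1 or self.T < 1:
            raise ValueError("l and T must be >= 1")
        if not 0 <= self.burn_in < self.T:
            raise ValueError("burn_in must lie in [0, T)")


def compute_A(hp: Hyperparams, n: int, d_js: np.ndarray) -> float:
    """Posterior Gamma shape A = alpha + n * (sum_j d_j) / 2."""
    d_js = np.asarray(d_js)
    if n < 1 or np.any(d_js < 1):
        raise ValueError("need n >= 1 and all d_j >= 1")
    return float(hp.alpha + n * int(d_js.sum()) / 2.0)


@dataclass
class ModelState:
    """Everything the SEM loop mutates.

    ``S[i, j]`` is the (0-based, gap-free) cluster label of view j at pixel
    i; slots of the per-pixel arrays beyond ``M[i]`` are exactly zero.  The
    cached arrays (b, G, quad, logdetC, Qsum) are the collapsed cluster
    statistics maintained incrementally by the Gibbs kernel; tests compare
    them against from-scratch recomputation.
    """

    S: np.ndarray            # (n, s) int64 assignments
    N: np.ndarray            # (n, s) int64 cluster sizes
    M: np.ndarray            # (n,) int64 live-cluster counts
    b: np.ndarray            # (n, s, l) sum of P_j' x_ij per cluster
    G: np.ndarray            # (n, s, l, l) sum of P_j' P_j per cluster
    quad: np.ndarray         # (n, s) mu' Cinv mu per cluster
    logdetC: np.ndarray      # (n, s) log|C| per cluster
    Qsum: float              # sum of quad over all live clusters
    P: list[np.ndarray]      # per-view d_j x l projections
    A: float                 # Gamma posterior shape (constant in S, P)
    hp: Hyperparams
    PtP: np.ndarray = field(repr=False, default=None)   # (s, l, l)
    PtX: np.ndarray = field(repr=False, default=None)   # (s, l, n)
    xx_obs: np.ndarray = field(repr=False, default=None)  # (n, s) |x_ij|^2
    xx_total: float = 0.0

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def s(self) -> int:
        return self.S.shape[1]

    @property
    def B(self) -> float:
        """Posterior Gamma rate from the incrementally maintained Qsum."""
        val = self.hp.beta + 0.5 * (self.xx_total - self.Qsum)
        if val <= 0:
            raise RuntimeError("B <= 0: corrupted collapsed statistics")
        return float(val)

    # ---- construction -------------------------------------------------

    @classmethod
    def from_assignments(
        cls,
        X: FeatureMatrix,
        S: np.ndarray,
        P: list[np.ndarray],
        hp: Hyperparams,
    ) -> "ModelState":
        """Build a consistent state from assignments and projections."""
        S = np.ascontiguousarray(S, dtype=np.int64)
        n, s = S.shape
        if (n, s) != (X.n, X.s):
            raise ValueError("assignment shape must be (n, s)")
        l = hp.l
        state = cls(
            S=S,
            N=np.zeros((n, s), dtype=np.int64),
            M=np.zeros(n, dtype=np.int64),
            b=np.zeros((n, s, l)),
            G=np.zeros((n, s, l, l)),
            quad=np.zeros((n, s)),
            logdetC=np.zeros((n, s)),
            Qsum=0.0,
            P=[np.ascontiguousarray(Pj, dtype=np.float64) for Pj in P],
            A=compute_A(hp, n, X.d_js),
            hp=hp,
        )
        xx = np.empty((n, s))
        for j in range(s):
            xx[:, j] = np.einsum("di,di->i", X.block(j), X.block(j))
        state.xx_obs = xx
        state.xx_total = float(xx.sum())
        state.refresh_stats(X)
        return state

    def refresh_stats(self, X: FeatureMatrix) -> None:
        """Recompute all cached statistics from S and P (after an M-step,
        or to rebuild a state from scratch)."""
        n, s, l = self.n, self.s, self.hp.l
        self.PtP = np.empty((s, l, l))
        self.PtX = np.empty((s, l, n))
        for j in range(s):
            Pj = self.P[j]
            self.PtP[j] = Pj.T @ Pj
            self.PtX[j] = Pj.T @ X.block(j)

        self.N.fill(0)
        self.b.fill(0.0)
        self.G.fill(0.0)
        rows = np.arange(n)
        for j in range(s):
            lab = self.S[:, j]
            np.add.at(self.N, (rows, lab), 1)
            np.add.at(self.b, (rows, lab), self.PtX[j].T)
            np.add.at(self.G, (rows, lab), np.broadcast_to(self.PtP[j], (n, l, l)))
        self.M = (self.N > 0).sum(axis=1).astype(np.int64)
        lab_ok = np.all(
            (self.S >= 0) & (self.S < self.M[:, None])
        )
        if not lab_ok:
            raise ValueError("cluster labels must be 0..M_i-1 with no gaps")

        self.quad.fill(0.0)
        self.logdetC.fill(0.0)
        live = self.N > 0
        idx = np.nonzero(live)
        Cinv = self.G[idx] + self.hp.r * np.eye(l)
        mu = np.linalg.solve(Cinv, self.b[idx][..., None])[..., 0]
        self.quad[idx] = np.einsum("ka,ka->k", mu, self.b[idx])
        sign, ld = np.linalg.slogdet(Cinv)
        if np.any(sign <= 0):
            raise RuntimeError("non-SPD cluster precision")
        self.logdetC[idx] = -ld
        self.Qsum = float(self.quad.sum())


def init_state(X: FeatureMatrix, hp: Hyperparams) -> ModelState:
    """Single shared cluster per pixel; random Gaussian projections.

    Starting from one cluster encodes the prior belief that most pixels are
    spectrally consistent; P_j entries are i.i.d. N(0, 1/l) from the seeded
    generator.
    """
    if hp.l > int(X.d_js.min()):
        warnings.warn(
            f"latent dimension l={hp.l} exceeds the smallest view dimension "
            f"{int(X.d_js.min())}; the projection becomes overcomplete",
            stacklevel=2,
        )
    rng = np.random.default_rng(hp.seed)
    P = [
        rng.standard_normal((dj, hp.l)) / math.sqrt(hp.l)
        for dj in X.d_js
    ]
    S = np.zeros((X.n, X.s), dtype=np.int64)
    return ModelState.from_assignments(X, S, P, hp)


# ---- from-scratch reference computations (oracles for the kernel) ------


def cluster_posterior(
    X: FeatureMatrix, state: ModelState, i: int, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mu_im, C_im) of cluster m at pixel i, recomputed from the
    assignments and projections alone:

        Cinv = sum_{j: s_ij = m} P_j' P_j + r I,
        mu   = C  sum_{j: s_ij = m} P_j' x_ij,

    with the empty-cluster convention (0, I/r)."""
    l = state.hp.l
    members = np.flatnonzero(state.S[i] == m)
    Cinv = state.hp.r * np.eye(l)
    rhs = np.zeros(l)
    for j in members:
        Pj = state.P[j]
        Cinv += Pj.T @ Pj
        rhs += Pj.T @ X.block(j)[:, i]
    try:
        np.linalg.cholesky(Cinv)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - r > 0 forbids
        raise RuntimeError("cluster precision is not SPD") from exc
    C = np.linalg.inv(Cinv)
    return C @ rhs, C


def compute_B(X: FeatureMatrix, state: ModelState, hp: Hyperparams) -> float:
    """B = beta + (sum_ij x_ij' x_ij - sum_im mu' Cinv mu) / 2, recomputed
    from scratch via :func:`cluster_posterior` (the reference path; the
    sampler maintains the same quantity incrementally as ``state.B``)."""
    total = float(state.xx_total)
    quad = 0.0
    for i in range(state.n):
        for m in range(int(state.M[i])):
            mu, C = cluster_posterior(X, state, i, m)
            quad += float(mu @ np.linalg.solve(C, mu))
    B = hp.beta + 0.5 * (total - quad)
    if B <= 0:
        raise RuntimeError("B <= 0: corrupted state")
    return float(B)


# ---- E-step -------------------------------------------------------------


def _workspaces(l: int, s: int):
    return (
        np.empty((l, l)), np.empty(l), np.empty((l, l)), np.empty(l),
        np.empty(l), np.empty(s + 1), np.empty(s + 1), np.empty(s + 1),
    )


def estep_assignment_logprobs(
    X: FeatureMatrix, state: ModelState, hp: Hyperparams, i: int, j: int
) -> np.ndarray:
    """Unnormalized log-probabilities for s_ij over {existing clusters of
    pixel i} + {new cluster}, with observation (i, j) downdated.

    Returns a length M_i'+1 vector (M_i' = live clusters after removing
    (i, j)); the last entry is the new-cluster option.  The caller's state
    is not modified."""
    st = _copy_state(state)
    l, s = hp.l, state.s
    ws = _workspaces(l, s)
    Gn, bn, L, y, mu, logp, qn, ldn = ws
    Qsum = _sweep._downdate_obs(
        i, j, st.S, st.N, st.M, st.b, st.G, st.quad, st.logdetC,
        st.PtP, st.PtX, st.Qsum, hp.r, Gn, bn, L, y, mu,
    )
    A = state.A
    A_minus = A - 0.5 * float(X.d_js[j])
    Mi = _sweep._eval_candidates(
        i, j, st.N, st.M, st.b, st.G, st.quad, st.logdetC, st.PtP, st.PtX,
        float(st.xx_obs[i, j]), st.xx_total, Qsum, A, A_minus,
        math.lgamma(A), math.lgamma(A_minus), hp.r, hp.gamma, hp.beta,
        Gn, bn, L, y, mu, logp, qn, ldn,
    )
    # common CRP denominator, included for faithfulness to the prior factor
    out = logp[: Mi + 1] - math.log(state.s - 1 + hp.gamma)
    return np.array(out)


def _copy_state(state: ModelState) -> ModelState:
    return replace(
        state,
        S=state.S.copy(), N=state.N.copy(), M=state.M.copy(),
        b=state.b.copy(), G=state.G.copy(), quad=state.quad.copy(),
        logdetC=state.logdetC.copy(),
    )


def estep_sample(
    X: FeatureMatrix,
    state: ModelState,
    hp: Hyperparams,
    rng: np.random.Generator,
) -> ModelState:
    """One Gibbs sweep over all (i, j) in row-major order (in place).

    Each observation is downdated, a new assignment is drawn from the
    collapsed conditional, and the statistics are updated incrementally;
    empty clusters are removed with label compaction."""
    uniforms = rng.random((state.n, state.s))
    lgA = math.lgamma(state.A)
    A_minus = state.A - 0.5 * X.d_js.astype(np.float64)
    lgA_minus = np.array([math.lgamma(a) for a in A_minus])
    Qsum, err_i, err_j = _sweep.gibbs_sweep(
        state.S, state.N, state.M, state.b, state.G, state.quad,
        state.logdetC, state.PtP, state.PtX, state.xx_obs,
        state.xx_total, state.Qsum, state.A,
        X.d_js.astype(np.float64), lgA, lgA_minus,
        hp.r, hp.gamma, hp.beta, uniforms,
    )
    if err_i >= 0:
        raise FloatingPointError(
            f"non-finite assignment log-probability at pixel {err_i}, "
            f"spectrum {err_j}"
        )
    state.Qsum = float(Qsum)
    return state


# ---- M-step -------------------------------------------------------------


def mstep_update(
    X: FeatureMatrix, state: ModelState, hp: Hyperparams
) -> ModelState:
    """MAP update of every projection matrix at fixed assignments.

    With the latents and sigma marginalized, maximizing the expected
    complete-data log joint gives, per view j,

        P_j = (A/B) (sum_i x_ij mu_i') (sum_i C_i + (A/B) sum_i mu_i mu_i')^-1

    where (mu_i, C_i) is the posterior of the cluster currently owning
    (i, j).  All collapsed statistics are refreshed afterwards (they depend
    on P)."""
    n, s, l = state.n, state.s, hp.l
    A_over_B = state.A / state.B

    live = state.N > 0
    idx = np.nonzero(live)
    Cinv = state.G[idx] + hp.r * np.eye(l)
    mu_flat = np.linalg.solve(Cinv, state.b[idx][..., None])[..., 0]
    C_flat = np.linalg.inv(Cinv)
    mu_all = np.zeros((n, s, l))
    C_all = np.zeros((n, s, l, l))
    mu_all[idx] = mu_flat
    C_all[idx] = C_flat

    rows = np.arange(n)
    newP = []
    for j in range(s):
        own = state.S[:, j]
        Mu = mu_all[rows, own]             # (n, l)
        Csum = C_all[rows, own].sum(axis=0)
        numer = X.block(j) @ Mu            # (d_j, l)
        denom = Csum + A_over_B * (Mu.T @ Mu)
        try:
            np.linalg.cholesky(denom)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"non-SPD M-step normal matrix for view {j}") from exc
        newP.append(A_over_B * np.linalg.solve(denom, numer.T).T)
    state.P = newP
    state.refresh_stats(X)
    return state


# ---- driver -------------------------------------------------------------


#: warm-start cap: M-step iterations fitting the all-consistent model
WARM_START_MSTEPS = 30
WARM_START_TOL = 1e-6


def _warm_start(X: FeatureMatrix, state: ModelState, hp: Hyperparams) -> int:
    """Fit the projections to the single-cluster init by iterated M-steps.

    The random initial P carries no information, so the first Gibbs sweeps
    against it split pixels essentially at random; with an unlucky draw the
    sampler can be absorbed into an everything-split state that later
    M-steps entrench.  Warm-starting P as the MAP fit of the all-consistent
    model (the mixture-model analogue of one-component initialization)
    starts the sampler from the best consistent explanation of the data,
    matching the assumption that most pixels are normal."""
    for k in range(WARM_START_MSTEPS):
        P_old = [p.copy() for p in state.P]
        mstep_update(X, state, hp)
        delta = max(
            np.max(np.abs(p - q)) / (np.max(np.abs(q)) + 1e-12)
            for p, q in zip(state.P, P_old)
        )
        if delta < WARM_START_TOL:
            break
    return k + 1


def run_sem(
    X: FeatureMatrix, hp: Hyperparams, warm_start: bool = True
) -> tuple[ModelState, np.ndarray]:
    """Run the full collapsed SEM: init, then T iterations of one Gibbs
    sweep followed by the projection update.

    Returns the final state and a (T, n) boolean trace of the per-iteration
    indicators 1[M_i > 1] from which psi is averaged.  Deterministic for a
    given seed."""
    state = init_state(X, hp)
    if warm_start:
        k = _warm_start(X, state, hp)
        logger.info("warm start: %d M-step iterations", k)
    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 1]))
    trace = np.zeros((hp.T, X.n), dtype=bool)
    log_every = max(1, hp.T // 10)
    for t in range(hp.T):
        try:
            estep_sample(X, state, hp, rng)
            mstep_update(X, state, hp)
        except Exception as exc:
            raise RuntimeError(f"SEM failed at iteration {t}: {exc}") from exc
        trace[t] = state.M > 1
        if (t + 1) % log_every == 0:
            logger.info(
                "iter %d/%d: mean M=%.3f max M=%d multi=%.3f B=%.6g",
                t + 1, hp.T, state.M.mean(), state.M.max(),
                trace[t].mean(), state.B,
            )
    return state, trace


@dataclass
class InconsistencyMap:
    """Per-pixel spectral-inconsistency scores psi in [0, 1]."""

    psi: np.ndarray
    trace_length: int
    grid_shape: tuple[int, int] | None = None
    pixel_index: np.ndarray | None = None

    def to_grid(self, fill: float = 0.0) -> np.ndarray:
        """Fold the per-pixel scores back onto the image grid."""
        if self.grid_shape is None:
            raise ValueError("no grid shape recorded")
        out = np.full(int(np.prod(self.grid_shape)), fill)
        idx = (
            self.pixel_index
            if self.pixel_index is not None
            else np.arange(out.size)
        )
        out[idx] = self.psi
        return out.reshape(self.grid_shape)


def inconsistency_scores(
    trace: np.ndarray,
    burn_in: int = 0,
    grid_shape: tuple[int, int] | None = None,
    pixel_index: np.ndarray | None = None,
) -> InconsistencyMap:
    """psi_i = fraction of (post burn-in) iterations with M_i > 1.

    The default burn_in=0 averages over all iterations."""
    trace = np.asarray(trace, dtype=bool)
    if burn_in < 0 or burn_in >= trace.shape[0]:
        raise ValueError("burn_in must lie in [0, T)")
    eff = trace[burn_in:]
    return InconsistencyMap(
        psi=eff.mean(axis=0),
        trace_length=eff.shape[0],
        grid_shape=grid_shape,
        pixel_index=pixel_index,
    )


def select_latent_dim(
    X: FeatureMatrix,
    labels: np.ndarray,
    candidate_ls: list[int],
    hp: Hyperparams,
) -> int:
    """Pick the latent dimension by validation against labeled pixels.

    Runs the full SEM for every candidate l, scores psi against the labels
    with the best-threshold accuracy, and returns the smallest l attaining
    the maximum accuracy (ties broken toward smaller l)."""
    from .evaluation import best_accuracy

    if not candidate_ls:
        raise ValueError("candidate_ls must be non-empty")
    best_l, best_acc = None, -np.inf
    for cand in sorted(candidate_ls):
        _, trace = run_sem(X, replace(hp, l=int(cand)))
        psi = inconsistency_scores(trace, hp.burn_in).psi
        _, acc = best_accuracy(psi, labels)
        logger.info("l=%d: best accuracy %.4f", cand, acc)
        if acc > best_acc:
            best_l, best_acc = int(cand), acc
    return best_l
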