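"""Shared fixtures and builders for tiny model instances."""

from __future__ import annotations

import numpy as np
import pytest

from msinc import FeatureMatrix, Hyperparams
from msinc.model import ModelState


def random_gapfree_assignments(
    rng: np.random.Generator, n: int, s: int, max_clusters: int = 2
) -> np.ndarray:
    """Random per-pixel assignments with gap-free 0..M_i-1 labels."""
    S = np.zeros((n, s), dtype=np.int64)
    for i in range(n):
        while True:
            a = rng.integers(0, min(max_clusters, s), size=s)
            u = np.unique(a)
            if (u == np.arange(len(u))).all():
                S[i] = a
                break
    return S


def scalar_instance(
    rng: np.random.Generator,
    n: int | None = None,
    s: int | None = None,
    hp: Hyperparams | None = None,
):
    """A tiny d_j = 1, l = 1 instance with random gap-free assignments.

    Returns (X, S, P, fm, state, hp) where X is (n, s) scalar observations
    and P the (s,) projection scalars."""
    if n is None:
        n = int(rng.integers(2, 4))
    if s is None:
        s = int(rng.integers(2, 4))
    if hp is None:
        hp = Hyperparams(l=1, gamma=1.2, alpha=1.0, beta=1.0, r=1.0, T=1, seed=0)
    X = rng.normal(0.0, 1.0, size=(n, s))
    P = rng.normal(0.0, 1.0, size=s)
    S = random_gapfree_assignments(rng, n, s)
    fm = FeatureMatrix(
        values=X.T.copy(), block_bounds=[(j, j + 1) for j in range(s)]
    )
    state = ModelState.from_assignments(
        fm, S, [P[j].reshape(1, 1) for j in range(s)], hp
    )
    return X, S, P, fm, state, hp


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170912)
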