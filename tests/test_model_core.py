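"""Collapsed statistics, initialization, and the inconsistency score."""

import numpy as np
import pytest

from msinc import (
    FeatureMatrix,
    Hyperparams,
    cluster_posterior,
    compute_A,
    compute_B,
    inconsistency_scores,
    init_state,
)
from msinc.model import ModelState


def make_fm(X_ns: np.ndarray) -> FeatureMatrix:
    """(n, s) scalar observations -> FeatureMatrix with d_j = 1."""
    n, s = X_ns.shape
    return FeatureMatrix(
        values=X_ns.T.copy(), block_bounds=[(j, j + 1) for j in range(s)]
    )


class TestHyperparams:
    @pytest.mark.parametrize(
        "kw", [{"gamma": 0}, {"alpha": -1}, {"beta": 0}, {"r": 0},
               {"l": 0}, {"T": 0}, {"burn_in": 5, "T": 5}]
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            Hyperparams(**kw)

    def test_defaults_match_reference_settings(self):
        hp = Hyperparams()
        assert (hp.gamma, hp.alpha, hp.beta, hp.T) == (1.2, 1.0, 1.0, 400)


class TestComputeA:
    @pytest.mark.parametrize(
        "alpha,n,d_js,expected",
        [
            (1.0, 1, [1], 1.5),
            (1.0, 2, [3, 3], 7.0),
            (2.0, 10, [98] * 11, 5392.0),
        ],
    )
    def test_values(self, alpha, n, d_js, expected):
        hp = Hyperparams(alpha=alpha, l=1)
        assert compute_A(hp, n, np.array(d_js)) == expected


class TestClusterPosterior:
    def test_empty_cluster_prior(self):
        hp = Hyperparams(l=2, r=2.0)
        fm = make_fm(np.zeros((1, 2)))
        st = ModelState.from_assignments(
            fm, np.zeros((1, 2), dtype=np.int64),
            [np.zeros((1, 2)), np.zeros((1, 2))], hp,
        )
        mu, C = cluster_posterior(fm, st, 0, 5)  # label with no members
        assert np.allclose(mu, 0)
        assert np.allclose(C, np.eye(2) / 2.0)

    def test_single_member_scalar(self):
        hp = Hyperparams(l=1, r=1.0)
        fm = make_fm(np.array([[2.0, 0.0]]))
        st = ModelState.from_assignments(
            fm, np.array([[0, 1]], dtype=np.int64),
            [np.ones((1, 1)), np.ones((1, 1))], hp,
        )
        mu, C = cluster_posterior(fm, st, 0, 0)
        # Cinv = P'P + r = 2, mu = C P'x = 2/2 = 1
        assert np.allclose(C, 0.5)
        assert np.allclose(mu, 1.0)

    def test_two_identical_members_double_the_numerator(self):
        hp = Hyperparams(l=1, r=1.0)
        fm = make_fm(np.array([[2.0, 2.0]]))
        st = ModelState.from_assignments(
            fm, np.array([[0, 0]], dtype=np.int64),
            [np.ones((1, 1)), np.ones((1, 1))], hp,
        )
        mu, C = cluster_posterior(fm, st, 0, 0)
        # Cinv = 2 P'P + r = 3, mu = (2 + 2)/3
        assert np.allclose(C, 1 / 3)
        assert np.allclose(mu, 4 / 3)


class TestComputeB:
    def test_all_zero_data_gives_beta(self, rng):
        hp = Hyperparams(l=1, beta=1.5)
        fm = make_fm(np.zeros((3, 2)))
        st = ModelState.from_assignments(
            fm, np.zeros((3, 2), dtype=np.int64),
            [rng.normal(size=(1, 1)) for _ in range(2)], hp,
        )
        assert compute_B(fm, st, hp) == pytest.approx(1.5)
        assert st.B == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "x,P,expected",
        [(2.0, 0.0, 3.0), (2.0, 1.0, 2.0)],  # hand-evaluated scalar cases
    )
    def test_scalar_cases(self, x, P, expected):
        hp = Hyperparams(l=1, beta=1.0, r=1.0)
        fm = FeatureMatrix(values=np.array([[x]]), block_bounds=[(0, 1)])
        st = ModelState.from_assignments(
            fm, np.zeros((1, 1), dtype=np.int64), [np.array([[P]])], hp
        )
        assert compute_B(fm, st, hp) == pytest.approx(expected)


class TestInitState:
    def test_single_cluster_contract(self, rng):
        fm = make_fm(rng.normal(size=(5, 3)))
        st = init_state(fm, Hyperparams(l=1, seed=4))
        assert (st.M == 1).all()
        assert (st.N[:, 0] == 3).all()
        assert (st.S == 0).all()

    def test_A_value(self, rng):
        # n=2, s=2, d_j=3, alpha=1 -> A = 1 + 2*6/2 = 7
        X = rng.normal(size=(6, 2))
        fm = FeatureMatrix(values=X, block_bounds=[(0, 3), (3, 6)])
        st = init_state(fm, Hyperparams(l=1, seed=0))
        assert st.A == 7.0

    def test_seeded_projections_bitwise_identical(self, rng):
        fm = make_fm(rng.normal(size=(4, 2)))
        a = init_state(fm, Hyperparams(l=1, seed=9))
        b = init_state(fm, Hyperparams(l=1, seed=9))
        for pa, pb in zip(a.P, b.P):
            assert np.array_equal(pa, pb)

    def test_overcomplete_latent_warns(self, rng):
        fm = make_fm(rng.normal(size=(4, 2)))
        with pytest.warns(UserWarning, match="overcomplete"):
            init_state(fm, Hyperparams(l=3, seed=0))


class TestInconsistencyScores:
    def test_counting(self):
        trace = np.zeros((400, 3), dtype=bool)
        trace[:, 1] = True        # always multi
        trace[:100, 2] = True     # 100 of 400
        imap = inconsistency_scores(trace)
        assert imap.psi[0] == 0.0
        assert imap.psi[1] == 1.0
        assert imap.psi[2] == 0.25
        assert imap.trace_length == 400

    def test_burn_in_window(self):
        trace = np.zeros((10, 1), dtype=bool)
        trace[:5, 0] = True
        assert inconsistency_scores(trace, burn_in=5).psi[0] == 0.0
        with pytest.raises(ValueError):
            inconsistency_scores(trace, burn_in=10)

    def test_grid_folding(self):
        trace = np.ones((4, 2), dtype=bool)
        imap = inconsistency_scores(
            trace, grid_shape=(2, 2), pixel_index=np.array([0, 3])
        )
        grid = imap.to_grid()
        assert grid[0, 0] == 1.0 and grid[1, 1] == 1.0
        assert grid[0, 1] == 0.0 and grid[1, 0] == 0.0
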