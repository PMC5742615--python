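"""Unit tests for the kernel, GP predictive, priors and count bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import norm

from gphsmm import (
    BOS,
    BookkeepingError,
    KernelHyperparams,
    ModelState,
    Segment,
    add_segment,
    gp_predict,
    gram_matrix,
    kernel_eval,
    length_log_prior,
    remove_segment,
    segment_log_emission,
    transition_log_prob,
)

H_UNIT = KernelHyperparams(theta0=1.0, theta1=1.0, theta2=0.0, theta3=0.0, beta=1.0)


class TestKernel:
    @pytest.mark.parametrize(
        "ip,iq,expected",
        [
            (3, 3, 1.0),                 # zero distance
            (0, 2, math.exp(-2.0)),      # exp(-4/2)
            (1, 3, math.exp(-2.0)),
        ],
    )
    def test_values(self, ip, iq, expected):
        assert kernel_eval(ip, iq, H_UNIT) == pytest.approx(expected, abs=1e-12)

    def test_bias_and_linear_terms(self):
        h = KernelHyperparams(theta0=2.0, theta1=0.5, theta2=0.3, theta3=0.1)
        ip, iq = 2, 5
        expected = 2.0 * math.exp(-0.25 * 9) + 0.3 + 0.1 * 10
        assert kernel_eval(ip, iq, h) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 50), st.integers(0, 50))
    def test_symmetry(self, ip, iq):
        h = KernelHyperparams(theta0=1.3, theta1=0.7, theta2=0.2, theta3=0.05)
        assert kernel_eval(ip, iq, h) == kernel_eval(iq, ip, h)


class TestGram:
    def test_single_step(self):
        assert gram_matrix([1], H_UNIT) == pytest.approx(np.array([[2.0]]))

    def test_two_steps_with_noise(self):
        h = KernelHyperparams(beta=10.0)
        C = gram_matrix([1, 2], h)
        e = math.exp(-0.5)
        np.testing.assert_allclose(C, [[1.1, e], [e, 1.1]], atol=1e-12)

    def test_exactly_symmetric(self):
        h = KernelHyperparams(theta0=1.5, theta1=0.3, theta2=0.1, theta3=0.02)
        C = gram_matrix(np.arange(1, 9), h)
        assert np.array_equal(C, C.T)


class TestGPPredict:
    def test_empty_class_prior_predictive(self):
        from gphsmm import GPClassData

        gp = GPClassData(0, n_dims=1)
        h = KernelHyperparams(beta=4.0)
        mean, var = gp_predict(5, 0, gp, h)
        assert mean == 0.0
        assert var == pytest.approx(kernel_eval(5, 5, h) + 0.25)

    def test_single_point_interpolates_in_low_noise_limit(self):
        from gphsmm import GPClassData

        h = KernelHyperparams(beta=1e12)
        gp = GPClassData(0, n_dims=1)
        gp.add_block(np.array([[3.0], [5.0]]))  # steps 1, 2 -> use step 2
        mean, _ = gp_predict(2, 0, gp, h)
        assert mean == pytest.approx(5.0, abs=1e-6)

    @pytest.mark.parametrize("istar", [1, 2, 3, 7])
    def test_matches_direct_inversion_oracle(self, istar):
        """Two-point predictive equals the closed-form matrix inversion."""
        from gphsmm import GPClassData

        h = KernelHyperparams(theta0=1.2, theta1=0.8, theta2=0.1, theta3=0.0,
                              beta=5.0)
        x = np.array([[0.7], [-1.1]])
        gp = GPClassData(0, n_dims=1)
        gp.add_block(x)  # steps 1, 2
        steps = np.array([1.0, 2.0])
        C = gram_matrix(steps, h)
        Cinv = np.linalg.inv(C)
        kvec = np.array([kernel_eval(s, istar, h) for s in steps])
        want_mean = kvec @ Cinv @ x[:, 0]
        want_var = kernel_eval(istar, istar, h) - kvec @ Cinv @ kvec + 1.0 / h.beta
        mean, var = gp_predict(istar, 0, gp, h)
        assert mean == pytest.approx(want_mean, abs=1e-10)
        assert var == pytest.approx(want_var, abs=1e-10)

    def test_variance_strictly_positive(self):
        from gphsmm import GPClassData

        h = KernelHyperparams(beta=100.0)
        gp = GPClassData(0, n_dims=1)
        gp.add_block(np.linspace(-1, 1, 12)[:, None])
        for istar in range(1, 15):
            _, var = gp_predict(istar, 0, gp, h)
            assert var > 0


class TestSegmentEmission:
    def test_single_frame_single_dim_is_one_log_density(self):
        from gphsmm import GPClassData

        h = KernelHyperparams()
        gp = GPClassData(0, n_dims=1)
        gp.add_block(np.array([[0.4], [0.6]]))
        x = np.array([[0.5]])
        mean, var = gp_predict(1, 0, gp, h)
        want = norm.logpdf(0.5, mean, math.sqrt(var))
        assert segment_log_emission(x, gp, h) == pytest.approx(want, abs=1e-12)

    def test_term_by_term_oracle(self):
        """k=3, D=2 emission equals the sum of its 6 Gaussian log densities."""
        from gphsmm import GPClassData

        rng = np.random.default_rng(11)
        h = KernelHyperparams(beta=8.0)
        gp = GPClassData(0, n_dims=2)
        gp.add_block(rng.standard_normal((4, 2)))
        gp.add_block(rng.standard_normal((2, 2)))
        seg = rng.standard_normal((3, 2))
        want = 0.0
        for j in range(1, 4):
            for d in range(2):
                mean, var = gp_predict(j, d, gp, h)
                want += norm.logpdf(seg[j - 1, d], mean, math.sqrt(var))
        assert segment_log_emission(seg, gp, h) == pytest.approx(want, abs=1e-10)

    def test_dimensions_factorize(self):
        """Multivariate emission is the sum of independent per-dimension runs."""
        from gphsmm import GPClassData

        rng = np.random.default_rng(3)
        h = KernelHyperparams()
        block = rng.standard_normal((5, 3))
        seg = rng.standard_normal((4, 3))
        gp = GPClassData(0, n_dims=3)
        gp.add_block(block)
        total = segment_log_emission(seg, gp, h)
        by_dim = 0.0
        for d in range(3):
            gpd = GPClassData(0, n_dims=1)
            gpd.add_block(block[:, [d]])
            by_dim += segment_log_emission(seg[:, [d]], gpd, h)
        assert total == pytest.approx(by_dim, abs=1e-10)


class TestLengthPrior:
    def test_poisson_logpmf_value(self):
        assert length_log_prior(1, 1.0, K=10) == pytest.approx(-1.0, abs=1e-12)

    def test_renormalized_mass_is_one(self):
        lps = [
            length_log_prior(k, 15.0, K=40, renormalize=True, min_len=5)
            for k in range(5, 41)
        ]
        assert logsumexp(lps) == pytest.approx(0.0, abs=1e-12)

    def test_mode_at_floor_lambda(self):
        # integer lambda ties the Poisson mode between lambda-1 and lambda
        lps = {k: length_log_prior(k, 15.0, K=40, min_len=2) for k in range(2, 41)}
        assert lps[15] == pytest.approx(max(lps.values()), abs=1e-12)
        assert max(lps, key=lps.get) in (14, 15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            length_log_prior(1, 15.0, K=40, min_len=2)
        with pytest.raises(ValueError):
            length_log_prior(41, 15.0, K=40, min_len=2)


class TestTransition:
    def test_uniform_when_unseen(self):
        m = ModelState(C=8, K=10, n_dims=1)
        assert transition_log_prob(0, 3, m) == pytest.approx(math.log(1 / 8))
        assert transition_log_prob(BOS, 5, m) == pytest.approx(math.log(1 / 8))

    def test_smoothed_counts(self):
        m = ModelState(C=2, K=10, n_dims=1)
        m.n_trans[0] = [3, 2]  # 5 outgoing transitions from class 0
        m.n_class[0] = 5
        assert transition_log_prob(0, 0, m) == pytest.approx(math.log(4 / 7))

    @given(st.lists(st.integers(0, 20), min_size=9, max_size=9),
           st.lists(st.integers(0, 20), min_size=3, max_size=3))
    @settings(max_examples=30, deadline=None)
    def test_rows_normalize(self, trans_flat, start):
        m = ModelState(C=3, K=10, alpha_smooth=0.7, n_dims=1)
        m.n_trans[:] = np.array(trans_flat).reshape(3, 3)
        m.n_class[:] = m.n_trans.sum(axis=1)
        m.n_start[:] = start
        for c_prev in [BOS, 0, 1, 2]:
            total = logsumexp([transition_log_prob(c_prev, c, m) for c in range(3)])
            assert total == pytest.approx(0.0, abs=1e-12)
        # matrix form agrees with the scalar form
        M = m.log_transition_matrix()
        for cp in range(3):
            for c in range(3):
                assert M[cp, c] == pytest.approx(transition_log_prob(cp, c, m))


class TestBookkeeping:
    def _setup(self):
        rng = np.random.default_rng(5)
        m = ModelState(C=3, K=10, min_len=2, n_dims=2)
        frames = rng.standard_normal((6, 2))
        seg = Segment("s", 0, 6, class_id=1)
        return m, seg, frames

    def test_add_then_remove_is_identity(self):
        m, seg, frames = self._setup()
        before = ModelState(C=3, K=10, min_len=2, n_dims=2)
        add_segment(m, seg, frames, prev_class=BOS)
        assert m.n_class[1] == 1 and m.gp[1].n_pairs == 6
        remove_segment(m, seg, frames, prev_class=BOS)
        assert m.equals(before)

    def test_transition_counts(self):
        m, seg, frames = self._setup()
        add_segment(m, seg, frames, prev_class=2)
        assert m.n_trans[2, 1] == 1 and m.n_start.sum() == 0

    def test_remove_absent_segment_raises(self):
        m, seg, frames = self._setup()
        add_segment(m, seg, frames, prev_class=BOS)
        remove_segment(m, seg, frames, prev_class=BOS)
        with pytest.raises(BookkeepingError):
            remove_segment(m, seg, frames, prev_class=BOS)

    def test_remove_only_segment_empties_class(self):
        m, seg, frames = self._setup()
        add_segment(m, seg, frames, prev_class=BOS)
        remove_segment(m, seg, frames, prev_class=BOS)
        assert m.gp[1].n_pairs == 0 and m.n_class[1] == 0
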