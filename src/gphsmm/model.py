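"""Probability components of the GP-HSMM.

The model has C latent classes. Each class c owns a Gaussian-process
regression dataset: the frames of every segment currently assigned to c,
indexed by their within-segment time step i = 1..k. A candidate segment is
scored as the product, over frames and dimensions, of the class GP's
Gaussian predictive density at that step; dimensions are treated as
independent GPs sharing one set of time steps (and hence one Gram matrix).
Segment lengths carry a Poisson prior with mean ``lambda_len``, truncated
to [min_len, K], and class-to-class transitions follow an additively
smoothed Markov chain estimated from the current segment assignments.

All densities are computed and combined in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import poisson

from .errors import BookkeepingError, NumericalDegeneracyError
from .types import Segment

__all__ = [
    "BOS",
    "KernelHyperparams",
    "GPClassData",
    "ModelState",
    "kernel_eval",
    "gram_matrix",
    "gp_predict",
    "segment_log_emission",
    "length_log_prior",
    "transition_log_prob",
    "add_segment",
    "remove_segment",
]

#: Virtual begin-of-sequence predecessor for a sequence's first segment.
BOS: int = -1

_LOG_2PI = math.log(2.0 * math.pi)

# Diagonal jitter schedule tried when the Gram matrix fails to factorize.
_JITTERS = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)


@dataclass(frozen=True)
class KernelHyperparams:
    """Hyperparameters of the kernel and the observation noise.

    ``k(ip, iq) = theta0 * exp(-theta1 * (ip - iq)^2 / 2) + theta2
    + theta3 * ip * iq`` and observations carry Gaussian noise with
    precision ``beta`` (variance 1/beta), added on the Gram diagonal.
    ``theta1`` is an inverse squared length-scale; 1 leaves the classic
    exponent ``-||ip - iq||^2 / 2`` untouched.
    """

    theta0: float = 1.0
    theta1: float = 1.0
    theta2: float = 0.0
    theta3: float = 0.0
    beta: float = 10.0

    def __post_init__(self) -> None:
        if self.theta0 <= 0 or self.theta1 <= 0 or self.beta <= 0:
            raise ValueError("theta0, theta1 and beta must be strictly positive")
        if self.theta2 < 0:
            raise ValueError("theta2 must be non-negative")


def kernel_eval(ip, iq, h: KernelHyperparams):
    """Evaluate the kernel at time steps ``ip``, ``iq`` (scalar or array)."""
    ip = np.asarray(ip, dtype=float)
    iq = np.asarray(iq, dtype=float)
    sq = (ip - iq) ** 2
    # theta3 * (ip * iq): grouping keeps the kernel bit-exactly symmetric
    val = h.theta0 * np.exp(-0.5 * h.theta1 * sq) + h.theta2 + h.theta3 * (ip * iq)
    return val if val.ndim else float(val)


def _kernel_cross(rows: np.ndarray, cols: np.ndarray, h: KernelHyperparams) -> np.ndarray:
    return kernel_eval(rows[:, None], cols[None, :], h)


def gram_matrix(steps, h: KernelHyperparams) -> np.ndarray:
    """Regularized Gram matrix: kernel values plus 1/beta on the diagonal."""
    steps = np.asarray(steps, dtype=float)
    if steps.size == 0:
        raise ValueError("gram_matrix requires at least one time step")
    C = _kernel_cross(steps, steps, h)
    C[np.diag_indices_from(C)] += 1.0 / h.beta
    return C


def _cholesky_with_jitter(C: np.ndarray, context: str):
    """Cholesky-factorize ``C``, escalating diagonal jitter on failure."""
    n = C.shape[0]
    for jitter in _JITTERS:
        try:
            return cho_factor(C + jitter * np.eye(n) if jitter else C, lower=True)
        except np.linalg.LinAlgError:
            continue
    raise NumericalDegeneracyError(
        f"Gram matrix for {context} is numerically degenerate even after "
        f"diagonal jitter up to {_JITTERS[-1]:g}"
    )


class GPClassData:
    """Training data and cached Gram factorization of one class's GP.

    Segments are stored as blocks of frames; all dimensions share one set
    of within-segment time steps 1..k per block, hence one Gram matrix and
    one Cholesky factorization serve every dimension. The cache is rebuilt
    lazily after any add/remove.
    """

    def __init__(self, class_id: int, n_dims: int, pair_cap: int | None = None,
                 cap_seed: int = 0):
        self.class_id = class_id
        self.n_dims = n_dims
        self.pair_cap = pair_cap
        self.cap_seed = cap_seed
        self._blocks: list[np.ndarray] = []  # each (k, D)
        self.dirty = True
        self._chol = None
        self._z: np.ndarray | None = None       # C^{-1} X, shape (n, D)
        self._steps: np.ndarray | None = None   # pooled steps, shape (n,)
        self._X: np.ndarray | None = None       # pooled targets, shape (n, D)

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self._blocks)

    @property
    def n_pairs(self) -> int:
        return sum(b.shape[0] for b in self._blocks)

    def add_block(self, frames: np.ndarray) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 2 or frames.shape[1] != self.n_dims:
            raise ValueError(
                f"class {self.class_id}: block must be (k, {self.n_dims})"
            )
        self._blocks.append(frames.copy())
        self.dirty = True

    def remove_block(self, frames: np.ndarray) -> None:
        frames = np.asarray(frames, dtype=float)
        for idx, blk in enumerate(self._blocks):
            if blk.shape == frames.shape and np.array_equal(blk, frames):
                del self._blocks[idx]
                self.dirty = True
                return
        raise BookkeepingError(
            f"class {self.class_id}: attempted to remove a segment block "
            f"of shape {frames.shape} that is not stored"
        )

    def steps(self) -> np.ndarray:
        """Pooled within-segment time steps of all stored blocks."""
        if not self._blocks:
            return np.empty(0, dtype=float)
        return np.concatenate(
            [np.arange(1, b.shape[0] + 1, dtype=float) for b in self._blocks]
        )

    # -- GP regression -------------------------------------------------
    def _rebuild(self, h: KernelHyperparams) -> None:
        steps = self.steps()
        X = (
            np.concatenate(self._blocks, axis=0)
            if self._blocks
            else np.empty((0, self.n_dims))
        )
        if self.pair_cap is not None and steps.size > self.pair_cap:
            rng = np.random.default_rng((self.cap_seed, self.class_id))
            keep = np.sort(rng.choice(steps.size, self.pair_cap, replace=False))
            steps, X = steps[keep], X[keep]
        self._steps, self._X = steps, X
        if steps.size:
            C = gram_matrix(steps, h)
            self._chol = _cholesky_with_jitter(
                C, f"class {self.class_id} (all {self.n_dims} dimensions)"
            )
            self._z = cho_solve(self._chol, X)
        else:
            self._chol = None
            self._z = None
        self.dirty = False

    def predict(self, istar: float, d: int, h: KernelHyperparams) -> tuple[float, float]:
        """GP predictive mean and variance at step ``istar`` for dimension ``d``."""
        if self.dirty:
            self._rebuild(h)
        c_star = kernel_eval(istar, istar, h) + 1.0 / h.beta
        if self._steps is None or self._steps.size == 0:
            return 0.0, float(c_star)
        kvec = kernel_eval(self._steps, istar, h)
        mean = float(kvec @ self._z[:, d])
        var = float(c_star - kvec @ cho_solve(self._chol, kvec))
        return mean, max(var, 1e-12)

    def predict_grid(self, K: int, h: KernelHyperparams) -> tuple[np.ndarray, np.ndarray]:
        """Predictive means and variances at steps 1..K for every dimension.

        Returns ``(mu, var)``: ``mu`` has shape (K+1, D) and ``var`` shape
        (K+1,), both with row 0 unused so that row j is step j. The
        variance is shared across dimensions because the steps are.
        """
        if self.dirty:
            self._rebuild(h)
        qs = np.arange(1, K + 1, dtype=float)
        c_star = kernel_eval(qs, qs, h) + 1.0 / h.beta
        mu = np.zeros((K + 1, self.n_dims))
        var = np.empty(K + 1)
        var[0] = np.nan
        if self._steps is None or self._steps.size == 0:
            var[1:] = c_star
            return mu, var
        Kq = _kernel_cross(self._steps, qs, h)  # (n, K)
        mu[1:] = Kq.T @ self._z
        var[1:] = np.maximum(c_star - np.sum(Kq * cho_solve(self._chol, Kq), axis=0),
                             1e-12)
        return mu, var


@dataclass
class ModelState:
    """Mutable sufficient statistics and hyperparameters of the sampler.

    ``n_class[c]`` counts segments currently assigned to class c,
    ``n_trans[c', c]`` transitions between consecutive segments, and
    ``n_start[c]`` segments that open a sequence (the begin-of-sequence
    predecessor gets its own smoothed categorical rather than sharing rows
    with real classes).
    """

    C: int
    K: int
    min_len: int = 2
    lambda_len: float = 15.0
    alpha_smooth: float = 1.0
    renormalize_len: bool = False
    kernel: KernelHyperparams = field(default_factory=KernelHyperparams)
    n_dims: int = 1
    pair_cap: int | None = None
    cap_seed: int = 0
    gp: list[GPClassData] = field(default_factory=list)
    n_class: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_trans: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_start: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.C < 1 or self.K < 1 or self.min_len < 1 or self.min_len > self.K:
            raise ValueError("need C >= 1 and 1 <= min_len <= K")
        if self.lambda_len <= 0 or self.alpha_smooth <= 0:
            raise ValueError("lambda_len and alpha_smooth must be positive")
        if not self.gp:
            self.gp = [
                GPClassData(c, self.n_dims, self.pair_cap, self.cap_seed)
                for c in range(self.C)
            ]
        if self.n_class is None:
            self.n_class = np.zeros(self.C, dtype=int)
        if self.n_trans is None:
            self.n_trans = np.zeros((self.C, self.C), dtype=int)
        if self.n_start is None:
            self.n_start = np.zeros(self.C, dtype=int)

    # convenience for tests: full-state equality
    def equals(self, other: "ModelState") -> bool:
        if (self.C, self.K, self.min_len) != (other.C, other.K, other.min_len):
            return False
        if not (
            np.array_equal(self.n_class, other.n_class)
            and np.array_equal(self.n_trans, other.n_trans)
            and np.array_equal(self.n_start, other.n_start)
        ):
            return False
        for g1, g2 in zip(self.gp, other.gp):
            if len(g1._blocks) != len(g2._blocks):
                return False
            for b1, b2 in zip(sorted(g1._blocks, key=_block_key),
                              sorted(g2._blocks, key=_block_key)):
                if not np.array_equal(b1, b2):
                    return False
        return True

    def log_transition_matrix(self) -> np.ndarray:
        """(C, C) matrix of log p(c | c') with rows indexed by c'.

        The denominator counts transitions out of c' (row sums of
        ``n_trans``) rather than segments of class c', so every row is an
        exactly normalized smoothed categorical; the two counts differ
        only by segments that close a sequence.
        """
        num = self.n_trans + self.alpha_smooth
        den = self.n_trans.sum(axis=1)[:, None] + self.C * self.alpha_smooth
        return np.log(num) - np.log(den)

    def log_start_probs(self) -> np.ndarray:
        num = self.n_start + self.alpha_smooth
        den = self.n_start.sum() + self.C * self.alpha_smooth
        return np.log(num) - np.log(den)

    def log_length_prior(self) -> np.ndarray:
        """Vector over k = 0..K (entries below min_len are -inf)."""
        out = np.full(self.K + 1, -np.inf)
        ks = np.arange(self.min_len, self.K + 1)
        out[ks] = poisson.logpmf(ks, self.lambda_len)
        if self.renormalize_len:
            out[ks] -= logsumexp(out[ks])
        return out


def _block_key(b: np.ndarray) -> tuple:
    return (b.shape[0], tuple(b.ravel()[:4]))


# ---------------------------------------------------------------------------
# Functional operation surface
# ---------------------------------------------------------------------------

def gp_predict(istar: int, d: int, gp: GPClassData,
               h: KernelHyperparams) -> tuple[float, float]:
    """Predictive Gaussian (mean, variance) of dimension ``d`` at step ``istar``.

    Standard GP regression with noisy targets: mean k^T C^{-1} x, variance
    k(i,i) - k^T C^{-1} k + 1/beta. With no training pairs this is the
    prior predictive N(0, k(i,i) + 1/beta).
    """
    return gp.predict(istar, d, h)


def segment_log_emission(seg_frames: np.ndarray, gp: GPClassData,
                         h: KernelHyperparams) -> float:
    """Log probability of a candidate segment under one class's GP.

    Sum over within-segment steps j = 1..k and dimensions d of the log
    Gaussian predictive density of frame j, dimension d.
    """
    seg_frames = np.atleast_2d(np.asarray(seg_frames, dtype=float))
    k, D = seg_frames.shape
    mu, var = gp.predict_grid(k, h)
    resid = seg_frames - mu[1:]
    ll = -0.5 * (_LOG_2PI + np.log(var[1:, None]) + resid**2 / var[1:, None])
    return float(ll.sum())


def length_log_prior(k: int, lambda_len: float, K: int,
                     renormalize: bool = False, min_len: int = 1) -> float:
    """Log Poisson pmf of segment length ``k``, truncated to [min_len, K]."""
    if not (min_len <= k <= K):
        raise ValueError(f"segment length {k} outside [{min_len}, {K}]")
    lp = float(poisson.logpmf(k, lambda_len))
    if renormalize:
        ks = np.arange(min_len, K + 1)
        lp -= float(logsumexp(poisson.logpmf(ks, lambda_len)))
    return lp


def transition_log_prob(c_prev: int, c: int, m: ModelState) -> float:
    """Smoothed Markov transition log p(c | c'); ``c_prev=BOS`` for openers."""
    if not 0 <= c < m.C:
        raise ValueError(f"class {c} outside [0, {m.C})")
    a = m.alpha_smooth
    if c_prev == BOS:
        return math.log(m.n_start[c] + a) - math.log(m.n_start.sum() + m.C * a)
    return math.log(m.n_trans[c_prev, c] + a) - math.log(
        m.n_trans[c_prev].sum() + m.C * a
    )


def add_segment(m: ModelState, seg: Segment, frames: np.ndarray,
                prev_class: int = BOS) -> ModelState:
    """Fold one segment into the sufficient statistics (in place)."""
    c = seg.class_id
    m.gp[c].add_block(np.atleast_2d(frames))
    m.n_class[c] += 1
    if prev_class == BOS:
        m.n_start[c] += 1
    else:
        m.n_trans[prev_class, c] += 1
    return m


def remove_segment(m: ModelState, seg: Segment, frames: np.ndarray,
                   prev_class: int = BOS) -> ModelState:
    """Exact inverse of :func:`add_segment`; errors if the segment is absent."""
    c = seg.class_id
    if prev_class == BOS:
        if m.n_start[c] < 1:
            raise BookkeepingError(f"n_start[{c}] would go negative")
    elif m.n_trans[prev_class, c] < 1:
        raise BookkeepingError(f"n_trans[{prev_class},{c}] would go negative")
    if m.n_class[c] < 1:
        raise BookkeepingError(f"n_class[{c}] would go negative")
    m.gp[c].remove_block(np.atleast_2d(frames))  # raises if absent
    m.n_class[c] -= 1
    if prev_class == BOS:
        m.n_start[c] -= 1
    else:
        m.n_trans[prev_class, c] -= 1
    return m
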