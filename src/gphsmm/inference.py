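"""Forward filtering–backward sampling and the blocked Gibbs sampler.

``forward_filter`` fills the semi-Markov lattice

    alpha[t][k][c] = P(s_{t-k:t} | class c GP) * P_len(k)
                     * sum_{k', c'} p(c | c') * alpha[t-k][k'][c'],

the probability that the k frames ending at t form one segment of class c,
marginalized over everything before it. ``backward_sample`` then draws an
exact joint posterior sample of the segmentation by walking the lattice
from t = T back to 0. ``blocked_gibbs`` alternates this resampling over
sequences with updates of the per-class GP datasets and transition counts.

Everything is log-space; ``enumerate_posterior`` is a brute-force oracle
for tiny instances used to validate the lattice and the sampler.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import InfeasibleSegmentationError
from .model import BOS, ModelState, add_segment, remove_segment
from .types import Segment, Segmentation, Trajectory

__all__ = [
    "ForwardLattice",
    "GibbsConfig",
    "forward_filter",
    "backward_sample",
    "enumerate_posterior",
    "PosteriorTable",
    "blocked_gibbs",
]


@dataclass
class ForwardLattice:
    """Log forward probabilities plus the per-class emission lattice.

    ``log_alpha[t, k, c]`` is log alpha[t][k][c]; infeasible cells
    (t - k < 0, k outside [min_len, K]) are -inf. ``log_emission[c, t, k]``
    holds the segment emission term alone so sampled segmentations can be
    scored without recomputation.
    """

    log_alpha: np.ndarray       # (T+1, K+1, C)
    log_emission: np.ndarray    # (C, T+1, K+1)
    log_len: np.ndarray         # (K+1,)
    T: int
    K: int
    C: int

    def log_total(self) -> float:
        """Log of the summed lattice mass at t = T (the partition function)."""
        return float(logsumexp(self.log_alpha[self.T]))


def _emission_lattice(frames: np.ndarray, m: ModelState, K: int) -> np.ndarray:
    """log P(s_{t-k:t} | X_c) for every (c, t, k); -inf where infeasible.

    Built from per-step predictive log densities L[j, tau] (within-segment
    step j scoring frame tau) accumulated along diagonals, so scores for
    lengths k and k+1 share work.
    """
    T, D = frames.shape
    C = m.C
    em = np.full((C, T + 1, K + 1), -np.inf)
    log2pi = np.log(2.0 * np.pi)
    for c in range(C):
        mu, var = m.gp[c].predict_grid(K, m.kernel)  # (K+1, D), (K+1,)
        # L[j, tau]: log density of frame tau under step j, summed over dims
        resid = frames[None, :, :] - mu[1:, None, :]          # (K, T, D)
        L = -0.5 * (
            D * log2pi
            + D * np.log(var[1:, None])
            + (resid**2).sum(axis=2) / var[1:, None]
        )  # (K, T); row j-1 is step j
        acc = np.full((T + 1, K + 1), -np.inf)
        if K >= 1:
            acc[1:, 1] = L[0, :]
        for k in range(2, K + 1):
            acc[k:, k] = acc[k - 1 : T, k - 1] + L[k - 1, k - 1 :]
        em[c] = acc
    return em


def forward_filter(traj: Trajectory, m: ModelState) -> ForwardLattice:
    """Dynamic-programming pass computing all log alpha[t][k][c]."""
    T = traj.n_frames
    if T < m.min_len:
        raise ValueError(
            f"sequence {traj.id!r} has {T} frames, below min_len={m.min_len}"
        )
    K = min(m.K, T)
    C = m.C
    em = _emission_lattice(traj.frames, m, K)
    log_len = m.log_length_prior()
    log_trans = m.log_transition_matrix()       # (C, C), rows c'
    log_start = m.log_start_probs()             # (C,)

    log_alpha = np.full((T + 1, m.K + 1, C), -np.inf)
    # A[t, c] = logsumexp_k log_alpha[t, k, c]; B[t, c] = logsumexp_{c'}
    # (A[t, c'] + log p(c|c')) -- the marginalized history entering at t.
    A = np.full((T + 1, C), -np.inf)
    B = np.full((T + 1, C), -np.inf)
    for t in range(1, T + 1):
        kmax = min(K, t)
        for k in range(m.min_len, kmax + 1):
            prev = log_start if t == k else B[t - k]
            log_alpha[t, k, :] = em[:, t, k] + log_len[k] + prev
        A[t] = logsumexp(log_alpha[t], axis=0)
        B[t] = logsumexp(A[t][:, None] + log_trans, axis=0)
    return ForwardLattice(log_alpha, em, log_len, T, m.K, C)


def backward_sample(
    lat: ForwardLattice,
    m: ModelState,
    rng: np.random.Generator,
    sequence_id: str = "seq",
    literal: bool = False,
) -> Segmentation:
    """Draw one segmentation from the posterior encoded by the lattice.

    At t = T the draw is (k, c) ~ alpha[T][k][c]. At interior t the weight
    is multiplied by p(c_next | c), the transition into the segment already
    drawn to the right, which makes the walk an exact joint posterior
    sample; ``literal=True`` drops that factor and samples from
    alpha[t][k][c] alone.
    """
    log_trans = m.log_transition_matrix()
    t = lat.T
    out: list[tuple[int, int]] = []  # (k, c) right-to-left
    c_next: int | None = None
    while t > 0:
        w = lat.log_alpha[t].copy()  # (K+1, C)
        if c_next is not None and not literal:
            w += log_trans[:, c_next][None, :]
        flat = w.ravel()
        mx = flat.max()
        if not np.isfinite(mx):
            raise InfeasibleSegmentationError(
                f"no feasible segment ending at t={t} for {sequence_id!r} "
                f"under min_len={m.min_len}, K={m.K}"
            )
        p = np.exp(flat - mx)
        p /= p.sum()
        idx = rng.choice(flat.size, p=p)
        k, c = divmod(idx, lat.log_alpha.shape[2])
        out.append((int(k), int(c)))
        c_next = int(c)
        t -= int(k)
    lengths = [k for k, _ in reversed(out)]
    classes = [c for _, c in reversed(out)]
    return Segmentation.from_lengths(sequence_id, lengths, classes)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class PosteriorTable:
    """Exhaustive posterior over (segmentation, classes) for a tiny instance."""

    probs: dict[Segmentation, float]
    log_total: float

    def __getitem__(self, seg: Segmentation) -> float:
        return self.probs[seg]


def _compositions(T: int, min_len: int, K: int):
    """All orderings of segment lengths in [min_len, K] summing to T."""
    if T == 0:
        yield ()
        return
    for k in range(min_len, min(K, T) + 1):
        if T - k == 0 or T - k >= min_len:
            for rest in _compositions(T - k, min_len, K):
                yield (k,) + rest


def _count_outcomes(T: int, min_len: int, K: int, C: int) -> int:
    n_comp = np.zeros(T + 1, dtype=object)
    n_comp[0] = 1
    for t in range(1, T + 1):
        n_comp[t] = sum(
            n_comp[t - k] * C for k in range(min_len, min(K, t) + 1)
        )
    return int(n_comp[T])


def score_segmentation(lat: ForwardLattice, m: ModelState,
                       seg: Segmentation) -> float:
    """Unnormalized log joint of one (segmentation, classes) outcome."""
    log_trans = m.log_transition_matrix()
    log_start = m.log_start_probs()
    total = 0.0
    prev: int | None = None
    for s in seg:
        k = s.length
        total += lat.log_emission[s.class_id, s.end, k] + lat.log_len[k]
        total += log_start[s.class_id] if prev is None else log_trans[prev, s.class_id]
        prev = s.class_id
    return total


def enumerate_posterior(
    traj: Trajectory, m: ModelState, max_outcomes: int = 10**6
) -> PosteriorTable:
    """Exhaustively score every feasible (segmentation, classes) outcome.

    Only for tiny instances; refuses when the outcome count exceeds
    ``max_outcomes``. The normalizing constant it computes must agree with
    ``forward_filter(...).log_total()``.
    """
    T = traj.n_frames
    n = _count_outcomes(T, m.min_len, m.K, m.C)
    if n == 0:
        raise InfeasibleSegmentationError(
            f"no composition of T={T} with lengths in [{m.min_len}, {m.K}]"
        )
    if n > max_outcomes:
        raise ValueError(f"{n} outcomes exceed the enumeration bound {max_outcomes}")
    lat = forward_filter(traj, m)  # reuse emission lattice for scoring
    scores: list[float] = []
    outcomes: list[Segmentation] = []
    for lengths in _compositions(T, m.min_len, min(m.K, T)):
        for classes in itertools.product(range(m.C), repeat=len(lengths)):
            seg = Segmentation.from_lengths(traj.id, lengths, classes)
            outcomes.append(seg)
            scores.append(score_segmentation(lat, m, seg))
    scores_arr = np.array(scores)
    log_total = float(logsumexp(scores_arr))
    probs = np.exp(scores_arr - log_total)
    return PosteriorTable(dict(zip(outcomes, probs)), log_total)


# ---------------------------------------------------------------------------
# Blocked Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class GibbsConfig:
    """Run settings for :func:`blocked_gibbs`.

    ``n_restarts`` runs that many independent chains (seeds spawned
    deterministically from ``seed``) and keeps the one with the highest
    final joint log probability — the usual defence against the strong
    multimodality of unsupervised segmentation posteriors, analogous to
    ``n_init`` in k-means or Gaussian-mixture fitting. Selection uses
    only the model's own joint probability, never any ground truth.
    """

    n_iter: int = 10
    seed: int = 0
    n_restarts: int = 5
    shuffle_sequences: bool = False
    literal_backward: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.n_restarts < 1:
            raise ValueError("n_iter and n_restarts must be >= 1")


def _random_lengths(T: int, min_len: int, K: int,
                    rng: np.random.Generator) -> list[int]:
    """Random initial division of T frames into parts within [min_len, K].

    Lengths are drawn uniformly on [min_len, K] left to right; a draw
    that would strand an uncompletable remainder is absorbed (remainder
    taken whole when it fits) or redrawn. Falls back to a constrained
    composition sampler in the rare corner where redrawing stalls.
    """
    if T < min_len:
        raise InfeasibleSegmentationError(
            f"T={T} admits no segmentation with lengths in [{min_len}, {K}]"
        )
    lengths: list[int] = []
    rem = T
    for _ in range(10 * T):
        if rem == 0:
            return lengths
        k = int(rng.integers(min_len, K + 1))
        if rem - k < min_len and rem - k != 0:
            if rem <= K:
                k = rem  # absorb the tail into one final segment
            else:
                continue  # redraw; tail would be uncompletable
        lengths.append(k)
        rem -= k
    # constrained fallback: fix a feasible segment count, then sample parts
    j_min = int(np.ceil(T / K))
    j_max = T // min_len
    if j_max < j_min:
        raise InfeasibleSegmentationError(
            f"T={T} admits no segmentation with lengths in [{min_len}, {K}]"
        )
    J = int(rng.integers(j_min, j_max + 1))
    lengths, rem = [], T
    for j in range(J, 0, -1):
        lo = max(min_len, rem - (j - 1) * K)
        hi = min(K, rem - (j - 1) * min_len)
        k = int(rng.integers(lo, hi + 1))
        lengths.append(k)
        rem -= k
    return lengths


def _remove_segmentation(m: ModelState, traj: Trajectory, seg: Segmentation) -> None:
    prev = BOS
    for s in seg:
        remove_segment(m, s, traj.frames[s.start : s.end], prev)
        prev = s.class_id


def _add_segmentation(m: ModelState, traj: Trajectory, seg: Segmentation) -> None:
    prev = BOS
    for s in seg:
        add_segment(m, s, traj.frames[s.start : s.end], prev)
        prev = s.class_id


def blocked_gibbs(
    corpus: list[Trajectory],
    m0: ModelState,
    cfg: GibbsConfig,
) -> tuple[ModelState, list[Segmentation], dict]:
    """Alternate exact per-sequence resampling with parameter updates.

    Initialization divides every sequence randomly (uniform feasible
    lengths, uniform classes). Each iteration then visits every sequence,
    removes its segments and counts from the model, reruns forward
    filtering against the remaining data, draws a fresh segmentation by
    backward sampling, and folds it back in. With ``cfg.n_restarts > 1``
    this whole procedure runs as several independent chains and the one
    with the highest final joint log probability wins.

    Returns the (best) final model state, the final per-sequence
    segmentations, and a trace with the per-iteration joint log
    probability (each sequence scored against the model holding it out,
    summed) plus the final joint of every restart.
    """
    if not corpus:
        raise ValueError("corpus must contain at least one trajectory")
    if cfg.n_restarts == 1:
        return _gibbs_chain(corpus, m0, cfg, cfg.seed)
    chain_seeds = [
        int(child.generate_state(1)[0] % (2**31))
        for child in np.random.SeedSequence(cfg.seed).spawn(cfg.n_restarts)
    ]
    best: tuple[ModelState, list[Segmentation], dict] | None = None
    finals: list[float] = []
    for cs in chain_seeds:
        result = _gibbs_chain(corpus, copy.deepcopy(m0), cfg, cs)
        finals.append(result[2]["joint_log_prob"][-1])
        if best is None or finals[-1] > best[2]["joint_log_prob"][-1]:
            best = result
    assert best is not None
    best[2]["restart_final_joint"] = finals
    return best


def _gibbs_chain(
    corpus: list[Trajectory],
    m: ModelState,
    cfg: GibbsConfig,
    seed: int,
) -> tuple[ModelState, list[Segmentation], dict]:
    rng = np.random.default_rng(seed)

    segs: list[Segmentation] = []
    for traj in corpus:
        lengths = _random_lengths(traj.n_frames, m.min_len, m.K, rng)
        classes = rng.integers(0, m.C, size=len(lengths)).tolist()
        seg = Segmentation.from_lengths(traj.id, lengths, classes)
        _add_segmentation(m, traj, seg)
        segs.append(seg)

    trace: dict = {"joint_log_prob": [], "class_occupancy": []}
    order = np.arange(len(corpus))
    for it in range(cfg.n_iter):
        if cfg.shuffle_sequences:
            order = rng.permutation(len(corpus))
        joint = 0.0
        for n in order:
            traj = corpus[n]
            try:
                _remove_segmentation(m, traj, segs[n])
                lat = forward_filter(traj, m)
                new_seg = backward_sample(
                    lat, m, rng, traj.id, literal=cfg.literal_backward
                )
            except Exception as exc:
                raise type(exc)(
                    f"[sequence {traj.id!r}, iteration {it}] {exc}"
                ) from exc
            joint += score_segmentation(lat, m, new_seg)
            _add_segmentation(m, traj, new_seg)
            segs[n] = new_seg
        trace["joint_log_prob"].append(joint)
        trace["class_occupancy"].append(m.n_class.copy())
    return m, segs, trace
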