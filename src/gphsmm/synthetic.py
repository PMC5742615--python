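"""Synthetic corpora drawn from the model's own generative process.

A corpus is built by chaining classes through a Markov transition matrix,
drawing each segment's length from a Poisson truncated to [min_len, K],
rendering the class's smooth primitive template over within-segment steps
1..k, and adding independent Gaussian observation noise. Ground-truth
segmentations come along for free, which makes parameter-recovery
experiments and metric tests self-contained.

The default primitive family is per-class, per-dimension sinusoids with
class-specific amplitude, period and phase — smooth, GP-representable
curves loosely analogous to cyclic exercise motions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigError
from .types import Segmentation, Trajectory

__all__ = [
    "PrimitiveSpec",
    "SynthConfig",
    "sinusoid_primitives",
    "generate_corpus",
    "truncated_poisson_mean",
    "downsample",
]


@dataclass(frozen=True)
class PrimitiveSpec:
    """One class's trajectory template plus its observation noise level.

    ``template(i, d)`` must return the noiseless value at within-segment
    step i (1-based) and dimension d, for any i in [1, K].
    """

    class_id: int
    template: Callable[[int, int], float]
    noise_sd: float = 0.0

    def render(self, k: int, n_dims: int) -> np.ndarray:
        steps = np.arange(1, k + 1)
        return np.array(
            [[float(self.template(int(i), d)) for d in range(n_dims)] for i in steps]
        )


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give the standard recovery benchmark."""

    C: int = 3
    D: int = 2
    trans: np.ndarray = None  # type: ignore[assignment]
    start_probs: np.ndarray = None  # type: ignore[assignment]
    lambda_len: float = 15.0
    min_len: int = 5
    K: int = 40
    n_sequences: int = 4
    segments_per_sequence: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        trans = self.trans
        if trans is None:
            # mildly sticky-free uniform-ish default: uniform off chance
            trans = np.full((self.C, self.C), 1.0 / self.C)
        trans = np.asarray(trans, dtype=float)
        if trans.shape != (self.C, self.C):
            raise ConfigError(f"trans must be {self.C}x{self.C}, got {trans.shape}")
        if np.any(trans < 0) or not np.allclose(trans.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigError("trans rows must be non-negative and sum to 1")
        object.__setattr__(self, "trans", trans)
        sp = self.start_probs
        if sp is None:
            sp = np.full(self.C, 1.0 / self.C)
        sp = np.asarray(sp, dtype=float)
        if sp.shape != (self.C,) or np.any(sp < 0) or not np.isclose(
            sp.sum(), 1.0, atol=1e-12
        ):
            raise ConfigError("start_probs must be a length-C simplex vector")
        object.__setattr__(self, "start_probs", sp)
        if not (1 <= self.min_len <= self.K):
            raise ConfigError("need 1 <= min_len <= K")
        if self.lambda_len <= 0:
            raise ConfigError("lambda_len must be positive")


def sinusoid_primitives(
    cfg: SynthConfig,
    amplitude_range: tuple[float, float] = (0.8, 1.2),
    period_range: tuple[float, float] = (10.0, 40.0),
    noise_fraction: float = 0.1,
) -> list[PrimitiveSpec]:
    """Default per-class sinusoid templates, parameters drawn once from the seed.

    x(i, d) = a_{c,d} sin(2 pi i / T_{c,d} + phi_{c,d}), with amplitudes,
    periods and phases drawn independently per class and dimension;
    ``noise_fraction`` sets noise_sd as a fraction of the class's mean
    amplitude (10% by default).
    """
    rng = np.random.default_rng((cfg.seed, 0x5117))
    specs = []
    for c in range(cfg.C):
        a = rng.uniform(*amplitude_range, size=cfg.D)
        period = rng.uniform(*period_range, size=cfg.D)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=cfg.D)

        def template(i: int, d: int, a=a, period=period, phase=phase) -> float:
            return float(a[d] * np.sin(2.0 * np.pi * i / period[d] + phase[d]))

        specs.append(
            PrimitiveSpec(c, template, noise_sd=noise_fraction * float(a.mean()))
        )
    return specs


def _truncated_poisson(rng: np.random.Generator, lam: float, lo: int, hi: int) -> int:
    """Rejection draw from Poisson(lam) restricted to [lo, hi]."""
    for _ in range(100_000):
        k = int(rng.poisson(lam))
        if lo <= k <= hi:
            return k
    raise ConfigError(
        f"Poisson({lam}) effectively puts no mass on [{lo}, {hi}]"
    )


def truncated_poisson_mean(lam: float, lo: int, hi: int) -> float:
    """Mean of Poisson(lam) truncated to [lo, hi], by direct summation."""
    from scipy.stats import poisson

    ks = np.arange(lo, hi + 1)
    pm = poisson.pmf(ks, lam)
    return float(np.sum(ks * pm) / np.sum(pm))


def generate_corpus(
    specs: list[PrimitiveSpec], cfg: SynthConfig
) -> tuple[list[Trajectory], list[Segmentation]]:
    """Sample a labeled corpus: trajectories plus exact ground truth.

    Fully deterministic given ``cfg.seed``.
    """
    if len(specs) != cfg.C:
        raise ConfigError(f"need {cfg.C} primitive specs, got {len(specs)}")
    by_class = {s.class_id: s for s in specs}
    rng = np.random.default_rng(cfg.seed)
    trajectories: list[Trajectory] = []
    truths: list[Segmentation] = []
    for n in range(cfg.n_sequences):
        classes: list[int] = []
        lengths: list[int] = []
        chunks: list[np.ndarray] = []
        for j in range(cfg.segments_per_sequence):
            if j == 0:
                c = int(rng.choice(cfg.C, p=cfg.start_probs))
            else:
                c = int(rng.choice(cfg.C, p=cfg.trans[classes[-1]]))
            k = _truncated_poisson(rng, cfg.lambda_len, cfg.min_len, cfg.K)
            clean = by_class[c].render(k, cfg.D)
            noise = rng.normal(0.0, by_class[c].noise_sd, size=clean.shape)
            classes.append(c)
            lengths.append(k)
            chunks.append(clean + noise)
        sid = f"synth-{n}"
        trajectories.append(Trajectory(np.vstack(chunks), id=sid))
        truths.append(Segmentation.from_lengths(sid, lengths, classes))
    return trajectories, truths


def downsample(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th frame starting at frame 0.

    The new length is ceil(T / factor) and the frame rate is divided by
    the factor (e.g. 120 fps downsampled by 30 becomes 4 fps).
    """
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return traj
    return Trajectory(
        traj.frames[::factor],
        id=traj.id,
        frame_rate=None if traj.frame_rate is None else traj.frame_rate / factor,
        dim_names=traj.dim_names,
    )
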