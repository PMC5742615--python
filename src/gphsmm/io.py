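"""File formats and run configuration.

Trajectories are plain CSV, one row per frame, one column per dimension,
with an optional single header row of dimension names. Segmentations are
TSV with columns ``sequence_id  start  end  class`` (0-based, half-open,
sorted by start). Run configuration is a single YAML file; every field
has an explicit default so a resolved config can be dumped verbatim into
the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError
from .types import Segment, Segmentation, Trajectory

__all__ = [
    "RunConfig",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_segmentation_tsv",
    "write_segmentation_tsv",
    "standardize",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# Trajectory CSV
# ---------------------------------------------------------------------------

def read_trajectory_csv(path: str | Path, id: str | None = None) -> Trajectory:
    """Read a T x D trajectory from CSV, auto-detecting a header row."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"{path}: empty file")

    def _is_numeric_row(line: str) -> bool:
        for tok in line.strip().split(","):
            try:
                float(tok)
            except ValueError:
                return False
        return True

    header = None if _is_numeric_row(first) else 0
    try:
        df = pd.read_csv(path, header=header, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric or ragged rows ({exc})") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + (2 if header == 0 else 1)
        raise FormatError(f"{path}: missing or non-numeric cell near row {row}")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: header only, no data rows")
    names = tuple(str(c) for c in df.columns) if header == 0 else None
    return Trajectory(df.to_numpy(), id=id or path.stem, dim_names=names)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame(traj.frames, columns=traj.dim_names)
    df.to_csv(path, index=False, header=traj.dim_names is not None,
              float_format="%.12g")


# ---------------------------------------------------------------------------
# Segmentation TSV
# ---------------------------------------------------------------------------

_SEG_COLS = ["sequence_id", "start", "end", "class"]


def write_segmentation_tsv(segs: Segmentation | list[Segmentation],
                           path: str | Path) -> None:
    if isinstance(segs, Segmentation):
        segs = [segs]
    rows = [
        (s.sequence_id, s.start, s.end, s.class_id)
        for seg in segs
        for s in sorted(seg, key=lambda s: s.start)
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_segmentation_tsv(path: str | Path) -> list[Segmentation]:
    """Read one or more segmentations; contiguity is validated per sequence."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty segmentation file") from exc
    if list(df.columns) != _SEG_COLS:
        raise FormatError(
            f"{path}: expected columns {_SEG_COLS}, got {list(df.columns)}"
        )
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no segments")
    out = []
    for sid, grp in df.groupby("sequence_id", sort=False):
        grp = grp.sort_values("start")
        segs = [
            Segment(str(sid), int(r.start), int(r.end), int(r["class"]))
            for _, r in grp.iterrows()
        ]
        try:
            out.append(Segmentation(tuple(segs)))
        except ValueError as exc:
            raise FormatError(f"{path}: sequence {sid!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(trajs: list[Trajectory]) -> tuple[list[Trajectory], dict]:
    """Per-dimension z-scoring over the pooled corpus.

    Returns the transformed trajectories and the (mean, sd) metadata
    needed to invert the transform. Dimensions with zero variance are
    left unscaled.
    """
    pooled = np.vstack([t.frames for t in trajs])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    out = [
        Trajectory((t.frames - mean) / sd, id=t.id, frame_rate=t.frame_rate,
                   dim_names=t.dim_names)
        for t in trajs
    ]
    return out, {"mean": mean.tolist(), "sd": sd.tolist()}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated run settings; one YAML file, every knob explicit."""

    # model
    n_classes: int = 8
    max_len: int = 30
    min_len: int = 2
    lambda_len: float = 15.0
    alpha_smooth: float = 1.0
    theta0: float = 1.0
    theta1: float = 1.0
    theta2: float = 0.0
    theta3: float = 0.0
    beta: float = 10.0
    renormalize_len: bool = False
    pair_cap: int | None = None
    # inference
    n_iter: int = 10
    seed: int = 0
    n_restarts: int = 5
    shuffle_sequences: bool = False
    literal_backward: bool = False
    # io
    standardize: bool = False
    downsample_factor: int = 1
    # eval
    tolerance: int = 4

    def __post_init__(self) -> None:
        checks = [
            (self.n_classes >= 1, "n_classes must be >= 1"),
            (1 <= self.min_len <= self.max_len, "need 1 <= min_len <= max_len"),
            (self.lambda_len > 0, "lambda_len must be positive"),
            (self.alpha_smooth > 0, "alpha_smooth must be positive"),
            (self.theta0 > 0 and self.theta1 > 0, "theta0/theta1 must be positive"),
            (self.beta > 0, "beta must be positive"),
            (self.n_iter >= 1, "n_iter must be >= 1"),
            (self.n_restarts >= 1, "n_restarts must be >= 1"),
            (self.downsample_factor >= 1, "downsample_factor must be >= 1"),
            (self.tolerance >= 0, "tolerance must be >= 0"),
            (self.pair_cap is None or self.pair_cap >= 1,
             "pair_cap must be >= 1 when set"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except (TypeError, ValueError, ConfigError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def build_model_state(self, n_dims: int):
        from .model import KernelHyperparams, ModelState

        return ModelState(
            C=self.n_classes,
            K=self.max_len,
            min_len=self.min_len,
            lambda_len=self.lambda_len,
            alpha_smooth=self.alpha_smooth,
            renormalize_len=self.renormalize_len,
            kernel=KernelHyperparams(
                self.theta0, self.theta1, self.theta2, self.theta3, self.beta
            ),
            n_dims=n_dims,
            pair_cap=self.pair_cap,
            cap_seed=self.seed,
        )


def write_manifest(out_dir: str | Path, config: dict, seed: int,
                   extra: dict | None = None) -> Path:
    """Record everything needed to reproduce a run exactly."""
    import gphsmm

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "gphsmm": gphsmm.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
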