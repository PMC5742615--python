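import numpy as np
import pytest

from gphsmm import ModelState, Trajectory


@pytest.fixture
def tiny_model() -> ModelState:
    """Two-class model with small fixed GP training sets (K=4, min_len=1).

    Class 0 is trained near level 0, class 1 near level 1, so the two
    emission distributions are distinct but overlapping; counts are kept
    consistent with the stored segments.
    """
    rng = np.random.default_rng(7)
    m = ModelState(C=2, K=4, min_len=1, lambda_len=2.5, n_dims=1)
    for c, level in enumerate((0.0, 1.0)):
        m.gp[c].add_block(level + 0.1 * rng.standard_normal((3, 1)))
        m.n_class[c] += 1
        m.n_start[c] += 1
    return m


@pytest.fixture
def tiny_trajectory() -> Trajectory:
    """Eight noisy frames, one dimension."""
    rng = np.random.default_rng(7)
    return Trajectory(rng.standard_normal((8, 1)), id="tiny")
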