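from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_square_loop(z: float = 0.0) -> np.ndarray:
    """Unit square loop in the z-plane, used for hand-geometry piercing tests."""
    return np.array(
        [[0.0, 0.0, z], [1.0, 0.0, z], [1.0, 1.0, z], [0.0, 1.0, z]]
    )


def regular_polygon(n: int, circumradius: float, z: float = 0.0) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.stack(
        [circumradius * np.cos(th), circumradius * np.sin(th), np.full(n, z)], axis=1
    )


# synthetic PDB fixtures (plain-text, generated at test time) live in the
# package so the analysis drivers can reuse them
from lassokit.synthetic import (  # noqa: E402,F401
    threaded_lasso_ca_trace,
    write_synthetic_lasso_pdb,
)
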