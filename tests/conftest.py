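"""Shared fixtures.

The expensive end-to-end runs (90-frame two-bar simulations plus the full
inverse pipeline) are session-scoped and shared across tests; small unit
fixtures are built per test.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import correlate

import specklekin as sk


@pytest.fixture(scope="session")
def two_bar():
    return sk.two_bar_object()


@pytest.fixture(scope="session")
def two_bar_autocorr(two_bar):
    """Brute-force O (x) O oracle for the standard two-bar object."""
    return correlate(two_bar.values, two_bar.values, mode="full")


def embed_autocorr(oo: np.ndarray, radius: int) -> np.ndarray:
    """Centre-embed a full correlation field into a (2R+1)^2 lag grid."""
    out = np.zeros((2 * radius + 1, 2 * radius + 1))
    cy, cx = oo.shape[0] // 2, oo.shape[1] // 2
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            y, x = cy + dy, cx + dx
            if 0 <= y < oo.shape[0] and 0 <= x < oo.shape[1]:
                out[dy + radius, dx + radius] = oo[y, x]
    return out


@pytest.fixture(scope="session")
def narrowband_cfg():
    return sk.RunConfig(seed=1)


@pytest.fixture(scope="session")
def narrowband_stack(narrowband_cfg):
    stack, medium, obj, path = sk.simulate(narrowband_cfg)
    return stack


@pytest.fixture(scope="session")
def narrowband_run(narrowband_cfg, narrowband_stack):
    """Full inverse pipeline on the noiseless narrowband two-bar sequence."""
    return sk.reconstruct_stack(narrowband_stack, narrowband_cfg)


@pytest.fixture(scope="session")
def broadband_cfg():
    return sk.RunConfig(seed=1, n_bands=8)


@pytest.fixture(scope="session")
def broadband_stack(broadband_cfg):
    stack, medium, obj, path = sk.simulate(broadband_cfg)
    return stack


@pytest.fixture(scope="session")
def broadband_run(broadband_cfg, broadband_stack):
    return sk.reconstruct_stack(broadband_stack, broadband_cfg)


@pytest.fixture()
def small_medium():
    """Cheap 64x64 narrowband medium for unit tests."""
    return sk.make_medium(
        seed=11, out_shape=(64, 64), grain_size=4, halo_sigma=6, diffuse_fraction=0.5
    )


def truth_displacements(stack) -> dict:
    """Map (i, j) -> true displacement from simulation metadata."""
    t = stack.truth_offsets
    return {
        (i, j): (t[j][0] - t[i][0], t[j][1] - t[i][1])
        for i in range(len(t))
        for j in range(len(t))
    }
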