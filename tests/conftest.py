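from __future__ import annotations

import numpy as np
import pytest

from exoalign.profiles import ProfileMatrix, normalize_per_region
from exoalign.synthgen import SyntheticTruth, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, K: int, L: int, rate: float = 3.0) -> ProfileMatrix:
    """Random normalized profile with Poisson counts."""
    values = rng.poisson(rate, size=(2 * K, L)).astype(float)
    p = ProfileMatrix(values, [f"e{k}" for k in range(K)], ["r0"])
    return normalize_per_region(p)


def two_block_truth(**overrides) -> SyntheticTruth:
    """Standard two-block layout used across the multi-alignment tests."""
    params = dict(
        experiments=["A", "B", "C"],
        n_regions=12,
        window=280,
        site_offsets=[55, 70, 110],
        site_blocks=[0, 0, 1],
        strengths=[[0.6, 0.25, 0.15], [0.1, 0.2, 0.7], [0.35, 0.35, 0.3]],
        tags_per_region=2000,
        spacer_range=(5, 40),
        jitter=20,
        seed=7,
        shared_noise=True,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest shared-noise synthetic dataset with spacers and jitter."""
    truth = two_block_truth()
    libs, ctrl, regions, record = generate(truth)
    return libs, ctrl, regions, record
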