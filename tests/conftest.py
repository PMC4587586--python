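"""Shared fixtures: small synthetic series and fast training options."""

from __future__ import annotations

import numpy as np
import pytest

from resicast import TimeSeries, gen_composite, normalize_minmax
from resicast.mlp import TrainOptions


@pytest.fixture(scope="session")
def fast_opts() -> TrainOptions:
    """Training options scaled down for test speed."""
    return TrainOptions(max_iterations=150)


@pytest.fixture(scope="session")
def composite_norm() -> TimeSeries:
    """One normalized composite series used by several chain tests."""
    bundle = gen_composite(600, seed=5)
    norm, _ = normalize_minmax(bundle.series)
    return norm


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
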