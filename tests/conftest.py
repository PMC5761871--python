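"""Shared fixtures: small phantoms, reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from lungquant import (
    CtPhantomSpec,
    HePhantomSpec,
    generate_ct_phantom,
    generate_he_phantom,
    segment_lung,
)


@pytest.fixture(scope="session")
def ct_phantom():
    """A default healthy-lung CT phantom (lesion-free), with its truth."""
    return generate_ct_phantom(CtPhantomSpec(rng_seed=7))


@pytest.fixture(scope="session")
def segmented_ct_phantom(ct_phantom):
    volume, truth = ct_phantom
    return volume, truth, segment_lung(volume, truth.trachea_seed)


@pytest.fixture(scope="session")
def he_phantom():
    """A clean (noiseless) H&E phantom with two empty-vessel lumens."""
    return generate_he_phantom(HePhantomSpec(noise_sd=0.0, n_vessels=2, rng_seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
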