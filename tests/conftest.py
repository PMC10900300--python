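"""Shared fixtures: small random structures and planted-correction datasets.

Everything is generated programmatically with fixed seeds; session-scoped
fixtures cache the more expensive datasets across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import deltakern as dk
from deltakern import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rep_small():
    """Compact descriptor config used throughout the unit tests."""
    return dk.RepresentationConfig(n_radial=8, n_angular=6)


@pytest.fixture(scope="session")
def molecules():
    """Forty random relaxed clusters of 4-7 atoms."""
    return fx.generate_molecules(40, (4, 7), seed=11)


@pytest.fixture(scope="session")
def planted_dataset(molecules, rep_small):
    """Noise-free labelled ensemble with an in-class planted correction."""
    correction = fx.draw_planted_correction(
        molecules, rep_small, n_bumps_per_element=2, amplitude_sd=2.5,
        width=3.0, seed=5,
    )
    labelled = fx.label_with_planted_delta(
        molecules, fx.MorseClusterPotential(), correction, seed=7,
        rep_config=rep_small,
    )
    return labelled, correction


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rigid_motion(rng):
    def apply(structure, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        R = random_rotation(local)
        t = local.normal(scale=5.0, size=3)
        return dk.Structure(
            structure.elements, structure.coords @ R.T + t, dict(structure.tags)
        )

    return apply
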