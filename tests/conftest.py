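"""Shared fixtures: montages, leadfields, and small helper constructors.

Heavy objects (the 64-channel leadfield) are session-scoped; toy data is
built per test from seeded generators.
"""

from __future__ import annotations

import numpy as np
import pytest

from beamadapt.head_model import HeadShells, build_montage, compute_leadfield, make_source_grid
from beamadapt.model_core import EpochSet


@pytest.fixture(scope="session")
def montage64():
    return build_montage(64)


@pytest.fixture(scope="session")
def montage32():
    return build_montage(32)


@pytest.fixture(scope="session")
def leadfield64(montage64):
    return compute_leadfield(montage64, make_source_grid(), HeadShells())


def make_epochs(
    rng: np.random.Generator,
    n_epochs: int,
    n_channels: int,
    n_samples: int = 200,
    fs: float = 200.0,
    sigma: np.ndarray | None = None,
    label: str = "low",
    band: str = "broadband",
) -> EpochSet:
    """Gaussian epochs with channel covariance ``sigma`` (default identity)."""
    if sigma is None:
        x = rng.standard_normal((n_epochs, n_channels, n_samples))
    else:
        chol = np.linalg.cholesky(sigma)
        x = np.einsum("cd,eds->ecs", chol, rng.standard_normal((n_epochs, n_channels, n_samples)))
    return EpochSet(
        x,
        np.array([label] * n_epochs),
        np.arange(n_epochs),
        band,
        fs,
        n_samples / fs,
    )


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T + n * np.eye(n))
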