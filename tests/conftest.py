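"""Shared fixtures: small meshes, coarse solver settings, cached sweeps."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from subwave.dielectrics import MaterialSet
from subwave.fem import sweep_scenario
from subwave.geometry import HeadModelConfig, ScenarioGeometry, ScenarioParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: coarse-but-physical settings used by unit tests (fast; a few seconds each)
FAST_FREQS = np.linspace(0.8e9, 1.6e9, 4)
FAST_EPW = 6


@pytest.fixture(scope="session")
def materials() -> MaterialSet:
    return MaterialSet()


@pytest.fixture(scope="session")
def head_config() -> HeadModelConfig:
    return HeadModelConfig()


@pytest.fixture(scope="session")
def nobleed_sweep(head_config, materials):
    """Cached coarse sweep of the symmetric no-bleeding scenario."""
    geom = ScenarioGeometry(ScenarioParams(), head_config)
    return sweep_scenario(
        geom, FAST_FREQS, materials, elements_per_wavelength=FAST_EPW
    )


@pytest.fixture(scope="session")
def lesion_sweep(head_config, materials):
    """Cached coarse sweep of a thick right-side lesion at position 1."""
    geom = ScenarioGeometry(
        ScenarioParams(bleeding_thickness=0.025, position_index=1), head_config
    )
    return sweep_scenario(
        geom, FAST_FREQS, materials, elements_per_wavelength=FAST_EPW
    )


def make_separable_dataset(
    n_classes: int = 6,
    n_per_class: int = 20,
    dim: int = 64,
    subspace_dim: int = 3,
    noise: float = 0.01,
    seed: int = 7,
):
    """Synthetic complex data with well-separated class subspaces.

    Bases are drawn from disjoint coordinate blocks (pairwise principal
    angles of 90 degrees) and observations carry ~20 dB SNR noise.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    block = dim // n_classes
    assert block >= subspace_dim
    for c in range(n_classes):
        basis = np.zeros((dim, subspace_dim), dtype=complex)
        raw = rng.standard_normal((block, subspace_dim)) + 1j * rng.standard_normal(
            (block, subspace_dim)
        )
        q, _ = np.linalg.qr(raw)
        basis[c * block : (c + 1) * block] = q[:, :subspace_dim]
        coeff = rng.standard_normal((n_per_class, subspace_dim)) + 1j * rng.standard_normal(
            (n_per_class, subspace_dim)
        )
        obs = coeff @ basis.T
        obs += noise * (
            rng.standard_normal((n_per_class, dim))
            + 1j * rng.standard_normal((n_per_class, dim))
        )
        X.append(obs)
        y.extend([c] * n_per_class)
    return np.vstack(X), np.asarray(y)


class ArrayDataset:
    """Minimal in-memory stand-in implementing the LabeledDataset protocol."""

    def __init__(self, X, y, groups=None, class_names=None):
        self.X = np.asarray(X, dtype=complex)
        self.y = np.asarray(y, dtype=int)
        self.groups = (
            np.asarray(groups, dtype=int) if groups is not None else np.arange(len(y))
        )
        self.class_names = (
            list(class_names)
            if class_names is not None
            else [f"class{c}" for c in np.unique(self.y)]
        )
        self.n_classes = len(self.class_names)

    def __len__(self):
        return len(self.X)

    def class_counts(self):
        return np.bincount(self.y, minlength=self.n_classes)

    def subset(self, idx):
        idx = np.asarray(idx)
        return ArrayDataset(self.X[idx], self.y[idx], self.groups[idx], self.class_names)
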