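"""Shared fixtures: synthetic specimens at the reference (wild-type and
mutant-like) parameter sets, plus a reduced-size variant for multi-seed
sweeps."""

from __future__ import annotations

import numpy as np
import pytest

from notomorph import synthgen
from notomorph.config import SynthConfig, mutant_config, wildtype_config


def small_config(seed: int = 0, mutant: bool = False) -> SynthConfig:
    """A short notochord (12 cells, 240 µm) for fast multi-seed sweeps;
    same geometry rules as the full-size defaults."""
    make = mutant_config if mutant else wildtype_config
    cfg = make(
        seed=seed,
        notochord_length=240.0,
        notochord_radius=30.0,
        n_cells=12,
    )
    cfg.volume_profile.baseline = 15000.0
    cfg.volume_profile.amplitude = 3000.0
    cfg.volume_profile.period = 97.0
    return cfg


@pytest.fixture(scope="session")
def wt_sample():
    """Full-size wild-type-like specimen (40 intact cells, noiseless)."""
    return synthgen.build_notochord_volume(wildtype_config(seed=0))


@pytest.fixture(scope="session")
def mutant_sample():
    """Full-size mutant-like specimen (fragmented, randomized, central
    nuclei)."""
    return synthgen.build_notochord_volume(mutant_config(seed=0))


@pytest.fixture(scope="session")
def wt_noisy_sample():
    """Wild-type specimen under the degraded imaging model: blur σ = 1
    voxel (1 µm in dv/lr), noise σ = 5% of the dynamic range."""
    cfg = wildtype_config(seed=0)
    cfg.imaging.blur_sigma = 1.0
    cfg.imaging.noise_sigma = 10.0  # membrane intensity is 200
    return synthgen.build_notochord_volume(cfg)


@pytest.fixture(scope="session")
def small_wt_sample():
    return synthgen.build_notochord_volume(small_config(seed=0))


def digitized_ball(radius: float, spacing: float) -> np.ndarray:
    """Boolean ball mask of physical ``radius`` at isotropic spacing."""
    n = int(2 * radius / spacing) + 5
    c = n // 2
    idx = (np.indices((n, n, n)) - c) * spacing
    return (idx ** 2).sum(axis=0) <= radius * radius


def digitized_spheroid(a: float, b: float, spacing: float = 1.0) -> np.ndarray:
    """Boolean spheroid mask with semi-axes (a, b, b) voxels-scale."""
    na = 2 * int(np.ceil(a / spacing)) + 9
    nb = 2 * int(np.ceil(b / spacing)) + 9
    ii = np.indices((na, nb, nb)).astype(float)
    ii[0] = (ii[0] - na // 2) * spacing
    ii[1] = (ii[1] - nb // 2) * spacing
    ii[2] = (ii[2] - nb // 2) * spacing
    return (ii[0] / a) ** 2 + (ii[1] / b) ** 2 + (ii[2] / b) ** 2 <= 1.0
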