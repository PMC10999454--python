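"""Shared fixtures: scenario runs are memoised per session because the
heavier simulations (10^6 photons) are reused by several tests."""
from __future__ import annotations

import numpy as np
import pytest

from ppgmc.photon_transport import run_scenario
from ppgmc.tissue_model import FingerModel, ScenarioConfig


@pytest.fixture(scope="session")
def run_cache():
    """Memoised run_scenario: identical configs are simulated once."""
    cache = {}

    def get(config: ScenarioConfig, **kwargs):
        key = (config, tuple(sorted((k, repr(v)) for k, v in kwargs.items())))
        if key not in cache:
            cache[key] = run_scenario(config, **kwargs)
        return cache[key]

    return get


def make_slab(mua: float, mus: float, g: float = 0.0, d: float = 1.0,
              n_tissue: float = 1.0) -> FingerModel:
    """Single-layer synthetic slab for analytic oracles (no bone, matched n
    by default).  The dummy bone region is unreachable (muscle_layer=-1)."""
    return FingerModel(
        region_names=["slab", "bone"],
        z_edges=np.array([0.0, d]),
        mua=np.array([mua, mua]),
        mus=np.array([mus, mus]),
        g=np.array([g, g]),
        n_tissue=n_tissue,
        n_ambient=1.0,
        muscle_layer=-1,
        bone_region=1,
        bone_center_z=d / 2,
        bone_radius=d / 10,
    )


def slab_config(n_photons=100_000, seed=7, mode="transmittance", **kw) -> ScenarioConfig:
    defaults = dict(
        wavelength=660,
        skin_type="light",
        phase="diastole",
        mode=mode,
        n_photons=n_photons,
        seed=seed,
        detector_radius=1e6,
        lateral_kill_radius=1e9,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)
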