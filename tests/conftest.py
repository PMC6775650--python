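import dataclasses

import numpy as np
import pytest

from drscascade import study_procedures as sp
from drscascade import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """A reduced study: 8 patients, default class imbalance and noise."""
    return sd.SimConfig(n_patients=8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sd.Dataset:
    return sd.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset) -> sp.PipelineResult:
    """Cross-validated run shared by metric and procedure tests."""
    return sp.run_pipeline(small_dataset, k=5, repeats=2, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def noise_free_config(**overrides) -> sd.SimConfig:
    """Config with all randomness in the spectra switched off."""
    models = {
        name: sd.TissueClassModel(
            name,
            property_means=model.property_means,
            property_sds=dataclasses.replace(
                model.property_sds,
                scatter_amplitude=1e-12,
                scatter_power=0.0,
                blood_fraction=0.0,
                oxygen_saturation=0.0,
                water_fraction=0.0,
                fat_fraction=0.0,
            ),
        )
        for name, model in sd.DEFAULT_TISSUE_MODELS.items()
    }
    defaults = dict(n_patients=2, noise_sd=0.0, tissue_models=models, seed=5)
    defaults.update(overrides)
    return sd.SimConfig(**defaults)
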