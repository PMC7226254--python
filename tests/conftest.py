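import numpy as np
import pandas as pd
import pytest

from collatscreen.config import (
    EffectClass,
    FieldImageSpec,
    SimulationConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_spec():
    """Rendering spec with constant background and constant cell intensity."""
    return FieldImageSpec(background_sd=0.0, cell_intensity_sd=0.0)


@pytest.fixture
def small_config():
    """A miniature screen: 20 compounds with every effect class represented."""
    return SimulationConfig(
        n_compounds=20,
        class_proportions={
            EffectClass.btk_inhibitor: 0.25,
            EffectClass.pi3k_inhibitor: 0.15,
            EffectClass.cytotoxic: 0.25,
            EffectClass.collateral_sensitive: 0.10,
            EffectClass.inert: 0.25,
        },
        rng_seed=7,
    )


def vehicle_only_layout(n_wells: int, line: str = "E41K") -> pd.DataFrame:
    """A flat layout of vehicle wells, for noise-model checks."""
    return pd.DataFrame(
        {
            "plate_id": "QC1",
            "well": [f"W{i}" for i in range(n_wells)],
            "compound_id": "",
            "dose_nM": 0.0,
            "line": line,
            "replicate": 1,
            "role": "vehicle",
        }
    )
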