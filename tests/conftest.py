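import numpy as np
import pytest

from tmsdkit.pipeline import PipelineConfig, build_labeled_dataset, simulate_study
from tmsdkit.structure import default_energy_model
from tmsdkit.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def model():
    return default_energy_model()


@pytest.fixture(scope="session")
def study300():
    """Planted end-to-end study: 300 systems, deterministic class structure.

    Label noise is zero so the rate class is a function of the features;
    the only stochasticity is the ~1% fluorescence read noise.
    """
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(n_systems=300, seed=20240, noise_sd_log10k=0.0),
        out_dir="unused",
        replicates=1,
    )
    systems, features_df, ensembles, rates_df = simulate_study(cfg)
    ds = build_labeled_dataset(features_df, rates_df)
    return {
        "systems": systems,
        "features": features_df,
        "rates": rates_df,
        "dataset": ds,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Quick planted dataset for unit-level ML tests (n=120, mild noise)."""
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(n_systems=120, seed=99, noise_sd_log10k=0.1),
        out_dir="unused",
        replicates=1,
    )
    _, features_df, _, rates_df = simulate_study(cfg)
    return build_labeled_dataset(features_df, rates_df)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
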