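import numpy as np
import pandas as pd
import pytest

from crossomic.containers import MultiOmicDataset, OmicTable, ScaleState
from crossomic.simulate import ModuleSpec, SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_dataset() -> MultiOmicDataset:
    """12 samples, two small omics, a label-correlated pair of features."""
    rng = np.random.default_rng(42)
    n = 12
    samples = [f"s{i}" for i in range(n)]
    labels = pd.Series([0] * 6 + [1] * 6, index=samples, name="label")
    signal = labels.to_numpy() * 2.0 + rng.normal(0, 0.3, n)
    t = pd.DataFrame(
        {
            "T:sig": np.exp(signal),
            "T:noise1": np.exp(rng.normal(0, 1, n)),
            "T:noise2": np.exp(rng.normal(0, 1, n)),
        },
        index=samples,
    )
    m = pd.DataFrame(
        {
            "M:sig": np.exp(signal + rng.normal(0, 0.2, n)),
            "M:noise1": np.exp(rng.normal(0, 1, n)),
        },
        index=samples,
    )
    return MultiOmicDataset(
        omics=[
            OmicTable("T", t, ScaleState.RAW),
            OmicTable("M", m, ScaleState.RAW),
        ],
        labels=labels,
        dataset_id="tiny",
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Small planted-module dataset for mid-weight integration tests."""
    spec = SyntheticSpec(
        n_samples=80,
        n_features={"T": 40, "P": 40, "M": 25},
        modules=[ModuleSpec({"T": 3, "P": 3, "M": 3}, alpha=2.0, beta=1.0, sigma=0.5)],
        seed=7,
    )
    return generate_dataset(spec)
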