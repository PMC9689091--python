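import numpy as np
import pandas as pd
import pytest

import metaboga as mg


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 4-stage cohort (8/stage, 30 features) with the default
    planted layout, plus its ground truth."""
    spec = mg.SyntheticSpec(n_per_group=8, n_features=30, seed=123)
    table, truth = mg.generate_dataset(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def planted_pair():
    """A 40 x 20 two-stage dataset with 2 strongly planted features (0, 1)."""
    planted = {("Control", "T2DM"): {0: 2.0, 1: 2.0}}
    spec = mg.SyntheticSpec(
        n_per_group=20,
        n_features=20,
        stages=("Control", "T2DM"),
        planted_map=planted,
        noise_sd=0.3,
        dilution_range=(1.0, 1.0),
        seed=7,
    )
    table, truth = mg.generate_dataset(spec)
    data = mg.pair_dataset(table, "Control", "T2DM")
    return data, truth


@pytest.fixture
def toy_table():
    """A tiny hand-built table: 3 samples x 4 features."""
    frame = pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 4.0, 6.0, 8.0],
                [1.5, 3.0, 4.5, 6.0],
            ]
        ),
        index=pd.Index(["a", "b", "c"], name="sample_id"),
        columns=["M1", "M2 (x:y)", "M3", "M4"],
    )
    stages = pd.Series(["Control", "T2DM", "Control"], index=frame.index)
    return mg.FeatureTable(frame, stages)
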