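import numpy as np
import pandas as pd
import pytest

from neurotf import synthetic_data as sd
from neurotf.pipeline import run_multiomic_pipeline


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SyntheticConfig(n_tf=50, guides_per_tf=4, n_ntc=100, n_essential=5,
                              depth=200_000, seed=1)


@pytest.fixture(scope="session")
def small_screen(small_cfg):
    manifest = sd.generate_library(small_cfg)
    truth = sd.make_screen_truth(small_cfg)
    counts = sd.simulate_screen(manifest, truth, small_cfg)
    return manifest, truth, counts


@pytest.fixture(scope="session")
def hierarchy_cfg():
    return sd.SyntheticConfig(n_tf=20, timepoints=("ESC", "12h", "D1", "D4"), seed=3)


@pytest.fixture(scope="session")
def hierarchy_truth(hierarchy_cfg):
    return sd.plant_hierarchy(hierarchy_cfg, n_a=3, targets_per_a=2,
                              n_repressed=1, n_c=2)


@pytest.fixture(scope="session")
def hierarchy_run(hierarchy_cfg, hierarchy_truth):
    return run_multiomic_pipeline(hierarchy_truth, hierarchy_cfg)


def make_archetype_fc(seed: int, n_per: int = 10, noise_sd: float = 0.1):
    """Well-separated planted temporal archetypes for clustering tests."""
    tps = ["ESC", "12h", "D1", "D2", "D4", "D7"]
    shapes = {
        "early-up": [0, 2, 2, 2, 2, 2],
        "late-up": [0, 0, 0, 0.2, 2, 2],
        "up-then-down": [0, 2, 2, 1, 0.3, 0.1],
        "flat": [0, 0, 0, 0, 0, 0],
    }
    rng = np.random.default_rng(seed)
    rows, names, labels = [], [], []
    for pattern, base in shapes.items():
        for i in range(n_per):
            rows.append(np.asarray(base, dtype=float)
                        + rng.normal(0.0, noise_sd, len(tps)))
            names.append(f"{pattern}_{i}")
            labels.append(pattern)
    fc = pd.DataFrame(rows, index=names, columns=tps)
    return fc, pd.Series(labels, index=names)
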