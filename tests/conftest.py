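import numpy as np
import pandas as pd
import pytest

from methaging import BetaMatrix, DetectionPMatrix, SampleSheet
from methaging.simulate import SimulationConfig, generate_cohort, generate_toy_clock


@pytest.fixture
def small_beta():
    """3 probes x 2 samples, hand-picked values."""
    return BetaMatrix(pd.DataFrame(
        [[0.10, 0.20], [0.50, 0.60], [0.90, 0.80]],
        index=["cg1", "cg2", "cg3"], columns=["s1", "s2"],
    ))


@pytest.fixture
def tiny_sheet():
    return SampleSheet(pd.DataFrame(
        {"group": ["PDN", "PDN", "PLDN", "PLDN", "CTRL", "CTRL"],
         "age": [55.0, 61.0, 58.0, 70.0, 49.0, 66.0],
         "sex": [0, 1, 1, 0, 0, 1]},
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    ))


@pytest.fixture
def small_cohort():
    """Seeded synthetic cohort of n = 22 with the default injected offsets."""
    cfg = SimulationConfig(
        n_per_group={"PDN": 8, "PLDN": 8, "CTRL": 6},
        n_cpgs=20, seed=7,
    )
    beta, detp, sheet, truth = generate_cohort(cfg)
    return cfg, beta, detp, sheet, truth


@pytest.fixture
def default_cfg():
    return SimulationConfig(seed=11)


def make_detp(beta: BetaMatrix, value: float = 0.0) -> DetectionPMatrix:
    return DetectionPMatrix(pd.DataFrame(
        np.full(beta.shape, value), index=beta.probe_ids, columns=beta.sample_ids,
    ))
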