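import logging

import numpy as np
import pytest

from xenoquant.simulate import demo_inputs, generate_batch
from xenoquant.types import AnalyteSpec, TruthRecord

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def demo():
    """Demo panel, truths and longitudinal profiles."""
    panel, truths, profiles = demo_inputs()
    return {"panel": panel, "truths": truths, "profiles": profiles}


@pytest.fixture(scope="session")
def noiseless():
    """Demo panel with all noise switched off (identity conditions)."""
    panel, truths, _ = demo_inputs()
    clean = [
        TruthRecord(**{**t.model_dump(), "noise_cv": 0.0, "noise_floor": 0.0})
        for t in truths
    ]
    return panel, clean


@pytest.fixture()
def single_analyte():
    """One-analyte panel with a known truth, for fast Monte-Carlo loops."""
    spec = AnalyteSpec(name="probe", chemical_class="industrial",
                       calibration_matrix="milk")
    truth = TruthRecord(analyte="probe", matrix="milk", true_slope=1000.0,
                        sse_true=0.8, recovery_true=0.87, noise_floor=1.6,
                        noise_cv=0.05)
    return spec, truth


@pytest.fixture(scope="session")
def batch_seed7(demo):
    df, manifest = generate_batch(demo["panel"], demo["truths"],
                                  {"unknowns": 5}, seed=7)
    return df, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
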