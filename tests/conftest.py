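import numpy as np
import pytest

from chromosurvey.simulate import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def small_world():
    """Two 200 kb arms — enough structure for every stage, fast to build."""
    cfg = SimulationConfig(seed=3, arm_len={"S": 200_000, "L": 200_000},
                           n_hairpins=8)
    return simulate_survey(cfg)


@pytest.fixture(scope="session")
def small_labels(small_world):
    from chromosurvey.survey import run_classification
    labels, summary, truth = run_classification(small_world, "S")
    return labels, summary, truth


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
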