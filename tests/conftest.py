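import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from xchrom import StageDesign, make_expression_matrix, scenario_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix():
    """Hand-built 6-probe matrix with two replicates in three stages."""
    probes = ["x1", "x2", "a1", "a2", "a3", "d1"]
    arms = pd.Series(["X", "X", "2L", "3R", "2R", "4"], index=probes)
    rng = np.random.default_rng(0)
    cols = {
        f"{stage}:{rep}": rng.normal(8, 1, len(probes))
        for stage in ("premeiotic", "meiotic", "postmeiotic")
        for rep in (1, 2)
    }
    values = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"))
    return make_expression_matrix(values, arms)


@pytest.fixture
def tiny_design():
    """Small genome for fast simulation-based tests."""
    return StageDesign(
        genes_per_arm={"X": 400, "2L": 300, "2R": 300, "3L": 300, "3R": 300, "4": 20}
    )


@pytest.fixture
def noiseless_no_dc():
    return scenario_params("no_dc", noise_sd=0.0)
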