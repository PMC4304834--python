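import numpy as np
import pandas as pd
import pytest

from oxbscall import (
    BetaMatrix,
    GroupProfile,
    ProbeAnnotation,
    SampleSheet,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """3 probes x 4 samples (2 BS + 2 oxBS of one group)."""
    values = pd.DataFrame(
        {
            "g_BS_r1": [0.80, 0.50, 0.10],
            "g_BS_r2": [0.82, 0.52, 0.12],
            "g_oxBS_r1": [0.40, 0.50, 0.10],
            "g_oxBS_r2": [0.42, 0.48, 0.08],
        },
        index=pd.Index(["cg01", "cg02", "cg03"], name="probe_id"),
    )
    return BetaMatrix(values)


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["g_BS_r1", "g_BS_r2", "g_oxBS_r1", "g_oxBS_r2"],
                "group": ["g"] * 4,
                "treatment": ["BS", "BS", "oxBS", "oxBS"],
                "replicate": [1, 2, 1, 2],
            }
        )
    )


@pytest.fixture
def toy_annotation() -> ProbeAnnotation:
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": ["cg01", "cg02", "cg03", "cg04"],
                "chromosome": ["1", "chr2", "X", "7"],
                "feature": ["BODY", "BODY", "TSS200", "IGR"],
                "cgi_relation": ["ISLAND", "OPEN_SEA", "SHORE", "OPEN_SEA"],
            }
        )
    )


@pytest.fixture(scope="session")
def brain_sim():
    """A brain-like simulated dataset shared across read-only tests."""
    config = SimulationConfig(
        n_probes=8000,
        groups=(GroupProfile("brain1"),),
        replicates=2,
        noise_sd=0.03,
        seed=20240450,
    )
    return simulate_dataset(config)
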