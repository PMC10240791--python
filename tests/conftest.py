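import numpy as np
import pandas as pd
import pytest

from timedrivers.core_model import (
    CohortDataset,
    Consequence,
    DriverEntry,
    ExpressionMatrix,
    GeneCopyState,
    MutationCall,
    Role,
    SampleMeta,
    Tier,
)
from timedrivers.synthetic_cohort import SimConfig, simulate_cohort
from timedrivers.time_features import Feature


@pytest.fixture(scope="session")
def tiny_cohort() -> CohortDataset:
    """Hand-built 4-sample / 3-gene cohort with fully known contents."""
    samples = [
        SampleMeta("s1", "TYPE_A", 0.8, 2.0),
        SampleMeta("s2", "TYPE_A", 0.5, 2.0),
        SampleMeta("s3", "TYPE_B", 0.6, 3.0),
        SampleMeta("s4", "TYPE_B", 0.9, 2.0),
    ]
    mutations = [
        MutationCall("s1", "G1", Consequence.TRUNCATING, 30, 100),
        MutationCall("s2", "G2", Consequence.HOTSPOT, 20, 80),
        MutationCall("s3", "G1", Consequence.BENIGN_OTHER, 5, 60),
    ]
    copy_states = [
        GeneCopyState("s1", "G1", 2, 1.0),
        GeneCopyState("s2", "G3", 0, 0.9),
        GeneCopyState("s4", "G2", 5, 0.5),
    ]
    expr = ExpressionMatrix(pd.DataFrame(
        [[5.0, 2.0, 1.0, 8.0], [0.0, 3.0, 2.0, 10.0], [1.0, 0.2, 4.0, 0.5]],
        index=["G1", "G2", "G3"], columns=["s1", "s2", "s3", "s4"],
    ))
    drivers = [
        DriverEntry("G1", Role.TUMOUR_SUPPRESSOR, Tier.CANONICAL,
                    frozenset({"TYPE_A", "TYPE_B"})),
        DriverEntry("G2", Role.ONCOGENE, Tier.CANONICAL, frozenset({"TYPE_A"})),
        DriverEntry("G3", Role.UNCLASSIFIED, Tier.CANDIDATE, frozenset({"TYPE_B"})),
    ]
    return CohortDataset(samples, mutations, copy_states, expr, drivers)


@pytest.fixture(scope="session")
def planted_cohort():
    """Two-type cohort with one strong planted effect per orientation."""
    cfg = SimConfig(
        n_types=2,
        samples_per_type=120,
        planted_effects=[
            ("DRV_CANON_001", Feature.CYS, 1, 2.0),
            ("DRV_CAND_002", Feature.CPI, -1, 2.0),
        ],
        seed=11,
    )
    return simulate_cohort(cfg)
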