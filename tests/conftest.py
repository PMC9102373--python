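import numpy as np
import pandas as pd
import pytest

from ocumir.simulate import (
    MarkerSimConfig,
    SimulationConfig,
    simulate_ct_matrix,
    simulate_marker_expression,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-group profiling run with planted effects."""
    cfg = SimulationConfig(
        n_assays=60,
        group_sizes={"control": 8, "OSC": 10},
        de_fraction=0.2,
        effect_size_ct=3.0,
        contrasts=(("control", "OSC"),),
        seed=11,
    )
    return simulate_ct_matrix(cfg)


@pytest.fixture(scope="session")
def marker_cohorts():
    """Discovery and validation marker tables with the study's cohort sizes."""
    disc = simulate_marker_expression(
        MarkerSimConfig(seed=21, n_per_class={"OSC": 14, "SCCC": 18})
    )
    val = simulate_marker_expression(
        MarkerSimConfig(seed=22, n_per_class={"OSC": 11, "SCCC": 12})
    )
    return disc, val


@pytest.fixture
def tiny_ct():
    """A hand-sized CT matrix with one undetected entry."""
    return pd.DataFrame(
        [[20.0, 25.0, 30.0], [22.0, np.nan, 28.0]],
        index=pd.Index(["s1", "s2"], name="sample_id"),
        columns=["m1", "m2", "m3"],
    )
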