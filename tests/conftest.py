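import io

import numpy as np
import pytest

from playtrace import read_event_log
from playtrace.markov_model import TransitionMatrix
from playtrace.synthetic_data import SyntheticConfig, generate_cohort

# The worked telemetry example: eight timestamped events of one level-1 play.
TABLE3_CSV = """\
child_id,session,level,date,time,status
K1,1,1,7/10,09-20-19-775,Player starts the level
K1,1,1,7/10,09-20-26-482,Player consumes good food to generate shield
K1,1,1,7/10,09-20-28-956,Robot killed by good food shields
K1,1,1,7/10,09-21-10-714,Robot killed by bad food shots
K1,1,1,7/10,09-21-10-814,Player shoots bad food ammo
K1,1,1,7/10,09-21-10-894,Player shoots bad food ammo
K1,1,1,7/10,09-21-14-717,Player consumes good food to generate shield
K1,1,1,7/10,09-21-20-281,Player finishes the level
"""


@pytest.fixture
def table3_events():
    return read_event_log(io.StringIO(TABLE3_CSV))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by I/O and pipeline tests."""
    return generate_cohort(SyntheticConfig(n_children=40, levels_lambda=5.0, seed=7))


def balanced_chain() -> TransitionMatrix:
    """A known chain visiting every live state often.

    With balanced occupancy the per-cell recovery tolerances (0.03 at 500
    sequences, 0.02 at 2000) sit beyond 3 standard errors for every cell, so
    recovery checks probe estimator correctness rather than rare-state
    sampling noise.
    """
    p = np.zeros((7, 7))
    p[0, 1:6] = 0.2                  # S spreads uniformly over 1..5
    p[1:6, 1:6] = 0.19               # interior states mix evenly ...
    p[1:6, 6] = 0.05                 # ... and finish at rate 0.05
    return TransitionMatrix.from_probs(p)
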