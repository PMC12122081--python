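import io

import numpy as np
import pytest

from cccot import CohortSpec, build_edge_signal_matrix, generate_cohort, htd_cost
from cccot.stg import build_stg, regularized_transition

EDGE_TABLE = """sample,source,target,weight
s1,A,B,1.0
s1,B,C,2.0
s2,A,B,3.0
"""


@pytest.fixture
def edge_table_stream():
    return io.StringIO(EDGE_TABLE)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-group cohort (fast: ~20 STG vertices)."""
    spec = CohortSpec(n_cell_types=5, samples_per_group=5, edge_density=0.7,
                      effect_size=5.0, noise_sigma=0.1, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_geometry(small_cohort):
    """Signals and symmetrized hitting-time cost for the tiny cohort."""
    cohort, labels = small_cohort
    esm = build_edge_signal_matrix(cohort)
    line = build_stg(cohort)
    P = regularized_transition(line, alpha=0.05).P
    cost = htd_cost(P)
    return esm, cost, labels
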