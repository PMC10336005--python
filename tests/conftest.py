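import numpy as np
import pandas as pd
import pytest

from pcmassembly import DissociationConstants, derive_interaction_params


@pytest.fixture(scope="session")
def paper_k() -> DissociationConstants:
    """Dissociation constants fitted to the equilibrium AUC data."""
    return DissociationConstants(k8=370e-6, k16=3.0e-13)


@pytest.fixture(scope="session")
def paper_params(paper_k):
    return derive_interaction_params(paper_k)


def make_table(rows):
    """Localization table from (trace_id, t, x, y, z, photons) tuples."""
    return pd.DataFrame(
        rows, columns=["trace_id", "t_s", "x_nm", "y_nm", "z_nm", "photons"]
    )


@pytest.fixture
def simple_table():
    rows = []
    for tid, n in enumerate([3, 5, 7]):
        for i in range(n):
            rows.append((tid, 0.001 * i, float(i), float(-i), 0.5 * i, 100.0))
    return make_table(rows)
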