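import numpy as np
import pandas as pd
import pytest

import phenocomb as pc
from phenocomb.simgen import INTERNAL_TRAITS, ComponentTable


@pytest.fixture(scope="session")
def small_panel():
    return pc.simulate_genotypes(300, 400, n_chrom=4, seed=7)


@pytest.fixture(scope="session")
def arch():
    return pc.default_architecture()


def make_table(rows, excluded=None):
    """ComponentTable from a list of dicts (missing keys -> NaN)."""
    n = len(rows)
    df = pd.DataFrame(
        [{t: r.get(t, np.nan) for t in INTERNAL_TRAITS} for r in rows],
        columns=list(INTERNAL_TRAITS), dtype=np.float64,
    )
    return ComponentTable(
        individual_ids=np.array([f"I{i:06d}" for i in range(n)]),
        values=df,
        excluded=np.zeros(n, dtype=bool) if excluded is None else np.asarray(excluded, bool),
    )


@pytest.fixture
def toy_table():
    """Six individuals spanning every branch of the case/control rule for
    the definition {recurrence, impairment}."""
    rows = [
        dict(cardinal=1, recurrence=1, symptoms5=0, duration=0, impairment=1, persistence=0),  # case
        dict(cardinal=1, recurrence=0, symptoms5=1, duration=1, impairment=1, persistence=1),  # control (component 0)
        dict(cardinal=0, recurrence=1, symptoms5=1, duration=1, impairment=1, persistence=1),  # control (cardinal 0)
        dict(cardinal=1, impairment=1),                                                        # missing (recurrence NA)
        dict(cardinal=1, recurrence=1, symptoms5=1, duration=1, impairment=1, persistence=1),  # excluded case
        dict(cardinal=1, recurrence=0, symptoms5=0, duration=0, impairment=0, persistence=0),  # excluded control
    ]
    return make_table(rows, excluded=[0, 0, 0, 0, 1, 1])
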