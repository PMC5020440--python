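import numpy as np
import pandas as pd
import pytest

import ranknorms as rn


@pytest.fixture(scope="session")
def default_config() -> rn.CohortConfig:
    return rn.CohortConfig()


@pytest.fixture(scope="session")
def pool(default_config) -> pd.DataFrame:
    """One default 1,862-person synthetic pool, shared across tests."""
    return rn.generate_pool(default_config, seed=7)


@pytest.fixture(scope="session")
def judgements(pool) -> pd.DataFrame:
    """A 400-person rank-mechanism judgment subsample of the shared pool."""
    return rn.generate_judgements(pool, rn.DEFAULT_MECHANISMS, n_sub=400, seed=8)


@pytest.fixture(scope="session")
def analysis_frame(judgements) -> pd.DataFrame:
    return rn.build_analysis_frame(judgements)


def make_group(brac_values, gender="M", location=1) -> rn.ReferenceGroup:
    """A reference group directly from a vector of BrAC values."""
    brac = np.sort(np.asarray(brac_values, dtype=float))
    return rn.ReferenceGroup(
        gender=gender,
        location=location,
        member_ids=tuple(f"x{i}" for i in range(len(brac))),
        brac_sorted=brac,
        mean_brac=float(brac.mean()),
    )
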