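import pandas as pd
import pytest

from epiclock import BetaMatrix, SampleTable, fit_clock
from epiclock.synthetic_data import SimConfig, simulate_train_test


@pytest.fixture
def toy_betas() -> BetaMatrix:
    return BetaMatrix(
        pd.DataFrame(
            [[0.2, 0.4], [0.6, 0.8]],
            index=pd.Index(["cg001", "cg002"], name="probe_id"),
            columns=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


@pytest.fixture
def toy_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {"age": [25.0, 60.0], "tissue": ["blood", "blood"]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
    )


# A small but realistic cohort shared across tests that need a real fit;
# session-scoped because the elastic-net CV path is the slow part.
SMALL_CFG = SimConfig(
    n_samples=160, n_probes=300, n_causal=40, noise_sd=0.02, seed=3,
    n_datasets=2,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_train_test(SMALL_CFG, n_test=60)


@pytest.fixture(scope="session")
def small_clock(small_cohort):
    (tr_b, tr_s, _), _ = small_cohort
    return fit_clock(tr_b, tr_s, seed=3)
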