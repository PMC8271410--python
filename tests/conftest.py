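import numpy as np
import pandas as pd
import pytest

from pbde_synergy import io


@pytest.fixture(scope="session")
def table1():
    return io.read_score_table(io.fixture_path("table1_scores.csv"))


@pytest.fixture(scope="session")
def table1_printed_cs():
    df = pd.read_csv(io.fixture_path("table1_scores.csv")).set_index("molecule_id")
    return df["CS"]


@pytest.fixture(scope="session")
def table3():
    return io.read_predictions(io.fixture_path("table3_predictions.csv"))


@pytest.fixture(scope="session")
def table4():
    return io.read_env_profiles(io.fixture_path("table4_env.csv"))


@pytest.fixture(scope="session")
def table5_plant():
    return io.read_snr_ledger(io.fixture_path("table5_snr.csv"), "plant")


@pytest.fixture(scope="session")
def table5_microbe():
    return io.read_snr_ledger(io.fixture_path("table5_snr.csv"), "microbe")


@pytest.fixture(scope="session")
def table6():
    return io.read_responses(io.fixture_path("table6_responses.csv"))


@pytest.fixture(scope="session")
def table7():
    return io.read_interactions(io.fixture_path("table7_interactions.csv"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
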