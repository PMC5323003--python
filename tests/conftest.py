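import numpy as np
import pandas as pd
import pytest

import ehrkit as ek

#: medcodes of the simulated diabetes condition (see SimConfig defaults)
DIABETES_CODES = [273, 277, 293, 351, 257]


@pytest.fixture
def tv_test() -> pd.DataFrame:
    """Five-patient follow-up table exercising every episode-split scenario."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5],
            "start": [0] * 5,
            "end": [1000, 689, 1000, 874, 777],
            "event": [0, 1, 0, 1, 1],
            "drug_1": [np.nan, np.nan, np.nan, 340, 460],
            "drug_2": [np.nan, 234, 554, 123, np.nan],
            "drug_3_start": [110, 110, 111, 109, 110],
            "drug_3_stop": [400, 400, 400, 400, 400],
            "stage_1": [300, np.nan, np.nan, np.nan, np.nan],
            "stage_2": [450, np.nan, np.nan, np.nan, np.nan],
        }
    )


@pytest.fixture(scope="session")
def sim_tables() -> dict:
    """A small synthetic EHR world, fixed seed."""
    cfg = ek.SimConfig(n_practices=5, mean_patients_per_practice=40, seed=42)
    return ek.simulate_ehr(cfg, seed=42)


@pytest.fixture(scope="session")
def flat_dir(sim_tables, tmp_path_factory):
    """The synthetic world written out as raw flat files."""
    out = tmp_path_factory.mktemp("flat")
    ek.write_flat_files(sim_tables, out, prefix="ehr")
    return out


@pytest.fixture(scope="session")
def db_path(flat_dir, tmp_path_factory):
    """The synthetic world imported into a SQLite store."""
    path = tmp_path_factory.mktemp("db") / "ehr.sqlite"
    with ek.Database(path) as db:
        ek.import_flat_files(
            db,
            flat_dir,
            filetypes=["Clinical", "Consultation", "Patient", "Practice", "Referral"],
            regex="ehr",
        )
        ek.add_table_from_file(db, flat_dir / "ehr_Therapy.txt", "Therapy")
    return path


@pytest.fixture
def db(db_path):
    with ek.Database(db_path) as conn:
        yield conn
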