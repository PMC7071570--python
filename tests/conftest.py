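import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    from emrsmoke import PatternLexicon

    return PatternLexicon.default()


@pytest.fixture()
def small_tables(tmp_path):
    """A tiny, hand-written five-table extract written to CSV files."""
    base = tmp_path / "extract"
    base.mkdir()
    (base / "patients.csv").write_text(
        "patient_id,sex,birth_year,postal_code,emr_system,deceased,inactive\n"
        "p1,F,1950,T0L1K0,Wolf,false,false\n"
        "p2,M,1960,T2N4N1,MedAccess,false,false\n"
        "p3,F,1945,,Wolf,true,false\n"
        "p4,M,1970,T2N4N1,Telin,false,false\n"
    )
    (base / "encounters.csv").write_text(
        "patient_id,encounter_date\n"
        "p1,2017-03-01\n"
        "p1,2017-03-01\n"
        "p1,2018-01-15\n"
        "p2,2016-08-02\n"
        "p3,2017-05-05\n"
        "p4,2014-01-01\n"
    )
    (base / "measurements.csv").write_text(
        "patient_id,kind,value,measure_date\n"
        "p1,bmi,25.0,2015-01-01\n"
        "p1,bmi,40.0,2016-01-01\n"
        "p1,bmi,28.0,2017-01-01\n"
        "p2,bmi,71.0,2017-01-01\n"
        "p1,sbp,130,2017-06-01\n"
        "p1,dbp,80,2017-06-01\n"
        "p2,sbp,140,2016-09-01\n"
        "p2,dbp,90,2016-09-01\n"
    )
    (base / "conditions.csv").write_text(
        "patient_id,hypertension,diabetes,copd\n"
        "p1,true,false,false\n"
        "p2,true,true,false\n"
        "p3,true,false,true\n"
        "p4,true,false,false\n"
    )
    (base / "risk_factors.csv").write_text(
        "patient_id,entry_date,name_text,value_text,status_text\n"
        "p1,2015-06-01,Smoking,,current\n"
        "p1,2018-02-01,Smoking,quit 2017,past\n"
        "p2,2017-01-01,Smoking,10 packs/day,\n"
        "p4,2013-01-01,Smoking,,never\n"
    )
    return base


@pytest.fixture(scope="session")
def masked_cohort():
    """Synthetic 6k-patient cohort with ~40.8% MCAR-masked smoking."""
    from emrsmoke import SimulationScenario, inject_missingness, make_cohort_frame

    sc = SimulationScenario(n_patients=6000, seed=42)
    frame = make_cohort_frame(sc)
    masked, mask = inject_missingness(
        frame["smoking"], "mcar", {"p": 0.408}, np.random.default_rng(43)
    )
    out = frame.copy()
    out["smoking"] = masked
    return out, frame, mask
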