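import numpy as np
import pandas as pd
import pytest

from aspredict import synth
from aspredict.codes import male_signature


@pytest.fixture(scope="session")
def small_male_population():
    """40 male cases with the shipped signature, 1:10 matched control pool."""
    cfg = synth.SynthConfig(n_cases=40, controls_per_case=10, sex_ratio=1.0,
                            seed=11)
    patients, events = synth.generate_population(cfg, [male_signature()])
    return cfg, patients, events


def make_events(rows):
    """Hand-built event table from (patient_id, code, source, kind, date) rows."""
    df = pd.DataFrame(rows, columns=["patient_id", "code", "source", "kind",
                                     "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def make_patients(rows):
    """Hand-built demographics from (patient_id, sex, week_of_birth, reg_start,
    reg_end, true_status, diagnosis_date) rows."""
    df = pd.DataFrame(rows, columns=synth.PATIENT_COLUMNS)
    for col in ("week_of_birth", "reg_start", "reg_end", "diagnosis_date"):
        df[col] = pd.to_datetime(df[col])
    return df
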