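import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cadencelab.stream_model import PatientMeta


@pytest.fixture
def meta_hip() -> PatientMeta:
    return PatientMeta(
        patient_id="P1",
        joint="hip",
        surgery_type="total",
        surgery_date=dt.date(2023, 3, 1),
        age=62.0,
        gender="female",
        bmi=28.5,
        fjs_pre=10.0,
        fjs_3m=40.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_minute_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, iso_date, minute, steps) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "date", "minute_of_day", "steps"])


@pytest.fixture
def minute_csv(tmp_path):
    def _write(rows, name="minutes.csv"):
        path = tmp_path / name
        make_minute_frame(rows).to_csv(path, index=False)
        return path

    return _write
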