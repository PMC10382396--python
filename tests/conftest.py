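import datetime

import pytest
from hypothesis import HealthCheck, settings

from mcscore.types import CentreTestResult, MeasurementRecord, Sex

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")

A_DATE = datetime.date(2018, 3, 1)


@pytest.fixture
def make_result():
    """Factory for CentreTestResult with sensible filler fields."""

    def _make(centre_id="c1", trait_id="trait", effect_size=0.5, p_value=0.01,
              q_value=None, n_male=50, n_female=50, effect_se=0.2):
        return CentreTestResult(
            centre_id=centre_id, trait_id=trait_id, n_male=n_male,
            n_female=n_female, effect_size=effect_size, effect_se=effect_se,
            p_value=p_value, q_value=q_value,
        )

    return _make


@pytest.fixture
def make_record():
    """Factory for MeasurementRecord with sensible filler fields."""

    def _make(value, sex, centre_id="c1", trait_id="trait", specimen_id=None,
              body_weight=25.0, batch=A_DATE, strain="C57BL/6N"):
        if specimen_id is None:
            _make.counter += 1
            specimen_id = f"a{_make.counter:05d}"
        return MeasurementRecord(
            centre_id=centre_id, specimen_id=specimen_id,
            sex=sex if isinstance(sex, Sex) else Sex(sex),
            body_weight=body_weight, batch=batch, strain=strain,
            trait_id=trait_id, value=float(value),
        )

    _make.counter = 0
    return _make
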