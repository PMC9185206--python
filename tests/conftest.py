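import pytest

from iolray.biometry import BiometryRecord
from iolray.synthetic import default_iol_database


@pytest.fixture(scope="session")
def iol_db():
    return default_iol_database()


@pytest.fixture(scope="session")
def generic_iol(iol_db):
    return next(iter(iol_db.values()))


@pytest.fixture
def normal_eye_record():
    """A biometrically average cataract-surgery eye."""
    return BiometryRecord(patient_id="P001", eye="OD", al=23.5, acd=3.7,
                          lt=4.5, cct=540, k1=43.0, k2=43.0)
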