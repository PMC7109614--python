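import pytest

from copdflow.config import EngineConfig
from copdflow.differential import load_knowledge_base
from copdflow.process import default_model
from copdflow.screening import load_instrument
from copdflow.spirometry import ReferenceEquationSet
from copdflow.staging import IndexCutpoints


@pytest.fixture(scope="session")
def cfg() -> EngineConfig:
    return EngineConfig()


@pytest.fixture(scope="session")
def model(cfg):
    return default_model(cfg)


@pytest.fixture(scope="session")
def equations(cfg):
    return ReferenceEquationSet.from_csv(cfg.equations_path)


@pytest.fixture(scope="session")
def instrument(cfg):
    return load_instrument(cfg.instrument_path)


@pytest.fixture(scope="session")
def cutpoints(cfg):
    return IndexCutpoints.from_csv(cfg.cutpoints_path)


@pytest.fixture(scope="session")
def kb(cfg):
    return load_knowledge_base(cfg.knowledge_base_path, cfg.vocabulary_path)


@pytest.fixture
def patient_factory():
    from copdflow.records import PatientRecord

    def make(**kw):
        base = dict(
            patient_id="p1", age=60, sex="male", height_cm=175.0, weight_kg=80.0,
            ethnic_group="caucasian",
        )
        base.update(kw)
        return PatientRecord(**base)

    return make
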