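import pytest
from hypothesis import HealthCheck, settings

import seqevolve as sv

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def helix60():
    return sv.make_helix(60, 1)


@pytest.fixture(scope="session")
def library10():
    return sv.make_library(10, 1)


@pytest.fixture(scope="session")
def model60(helix60, library10):
    """Calibrated energy model for the 60-residue helix fixture."""
    structure, _ = helix60
    model = sv.build_energy_model(structure, library10)
    model.normalizers = sv.calibrate_normalizers(
        structure, model, n_random=100, rng=sv.make_rng(1))
    return model


@pytest.fixture(scope="session")
def ctx60(helix60, model60):
    return sv.StructureContext(helix60[0], model60)
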