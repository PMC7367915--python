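import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cliffscout.data_model import (
    ActivityClass,
    CompoundRecord,
    CurationConfig,
    PotencyMeasurement,
    curate,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def frame_to_class(frame: pd.DataFrame, min_class_size: int = 4):
    """Curate a generated activity table into (ActivityClass, structures)."""
    records = [
        CompoundRecord(
            compound_id=row.compound_id,
            smiles=row.smiles,
            measurements=[PotencyMeasurement(target_id=row.target_id, pki=float(row.pki))],
        )
        for row in frame.itertuples(index=False)
    ]
    result = curate(records, CurationConfig(min_class_size=min_class_size))
    assert len(result.classes) == 1
    return result.classes[0], result.structures


def detected_keys(acs):
    """(sorted id pair, n_sites) set for comparison with planted truth."""
    return {(*sorted((a.id_high, a.id_low)), a.n_sites) for a in acs}


@pytest.fixture(scope="session")
def recovery_data():
    from cliffscout.synthetic import preset

    frame, truth = preset("recovery", seed=11)
    cls, structures = frame_to_class(frame)
    return cls, structures, truth


@pytest.fixture(scope="session")
def quartet_data():
    from cliffscout.synthetic import preset

    frame, truth = preset("ds", seed=5)
    cls, structures = frame_to_class(frame)
    return cls, structures, truth


@pytest.fixture
def tiny_class():
    """Hand-sized class: shared ethylbenzene-amide scaffold, one steep pair."""
    rows = [
        ("a", "O=C(Nc1ccc(C)cc1)c1ccccc1", 9.1),
        ("b", "O=C(Nc1ccc(CC)cc1)c1ccccc1", 5.0),
        ("c", "O=C(Nc1ccc(OC)cc1)c1ccccc1", 8.9),
        ("d", "O=C(Nc1ccc(CCC)cc1)c1ccccc1", 8.7),
    ]
    frame = pd.DataFrame(
        [
            {"compound_id": cid, "smiles": smi, "target_id": "T1", "pki": pki}
            for cid, smi, pki in rows
        ]
    )
    return frame_to_class(frame)
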