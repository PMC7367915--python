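import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cliffscout.data_model import (
    CompoundRecord,
    CurationConfig,
    MeasurementType,
    PotencyMeasurement,
    curate,
    read_activity_table,
    to_pki,
)


def rec(cid, smiles, *measurements):
    return CompoundRecord(compound_id=cid, smiles=smiles, measurements=list(measurements))


def ki(pki=None, nm=None, target="T", mtype="Ki"):
    return PotencyMeasurement(target_id=target, measurement_type=mtype, pki=pki, value_nM=nm)


class TestToPki:
    @pytest.mark.parametrize("nm,expected", [(10.0, 8.0), (1000.0, 6.0), (1.0, 9.0)])
    def test_nm_conversion(self, nm, expected):
        assert to_pki(nm) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            to_pki(bad)

    @given(st.floats(min_value=1e-3, max_value=1e9), st.floats(min_value=1.01, max_value=10))
    def test_strictly_decreasing(self, nm, factor):
        assert to_pki(nm * factor) < to_pki(nm)


class TestMeasurement:
    def test_exactly_one_unit(self):
        with pytest.raises(ValueError):
            PotencyMeasurement(target_id="T", pki=8.0, value_nM=10.0)
        with pytest.raises(ValueError):
            PotencyMeasurement(target_id="T")

    def test_derived_pki(self):
        assert ki(nm=10.0).pki_value == pytest.approx(8.0)
        assert ki(pki=7.5).pki_value == 7.5


class TestCuration:
    def test_size_filter_empty(self):
        records = [rec(f"c{i}", "CCO"[: 2 + i % 2] + "O", ki(pki=7.0)) for i in range(3)]
        result = curate(records)  # default min size 100
        assert result.classes == []
        assert any(e["reason"] == "class_too_small" for e in result.log)

    def test_replicates_aggregated_by_mean(self):
        records = [rec("c1", "CCO", ki(pki=8.0), ki(pki=8.2))]
        result = curate(records, CurationConfig(min_class_size=1))
        assert result.classes[0].members == [("c1", pytest.approx(8.1))]

    def test_discordant_replicates_dropped(self):
        records = [
            rec("c1", "CCO", ki(pki=5.0), ki(pki=7.5)),
            rec("c2", "CCN", ki(pki=6.0)),
        ]
        result = curate(records, CurationConfig(min_class_size=1, spread_limit=1.0))
        assert result.classes[0].compound_ids == ["c2"]
        assert any(e["reason"] == "replicate_spread" for e in result.log)

    def test_kd_excluded_under_default_types(self):
        records = [
            rec("c1", "CCO", ki(pki=8.0, mtype="Kd")),
            rec("c2", "CCN", ki(pki=7.0)),
        ]
        result = curate(records, CurationConfig(min_class_size=1))
        assert result.classes[0].compound_ids == ["c2"]

    def test_unparseable_smiles_logged_not_silent(self):
        records = [rec("bad", "not_a_smiles", ki(pki=7.0)), rec("ok", "CCO", ki(pki=7.0))]
        result = curate(records, CurationConfig(min_class_size=1))
        assert result.classes[0].compound_ids == ["ok"]
        assert any(e["reason"] == "smiles_error" for e in result.log)

    def test_salt_stripped_to_parent(self):
        records = [rec("c1", "CC(=O)[O-].[Na+]", ki(pki=6.5))]
        result = curate(records, CurationConfig(min_class_size=1))
        assert result.structures["c1"] == "CC(=O)O"

    def test_every_record_accounted_for(self):
        records = [
            rec("c1", "CCO", ki(pki=8.0)),
            rec("c2", "xxx", ki(pki=8.0)),
            rec("c3", "CCN", ki(pki=5.0, mtype="Kd")),
            rec("c4", "CCC", ki(pki=4.0), ki(pki=8.0)),
            rec("c5", "CCCO", ki(pki=6.0)),
        ]
        result = curate(records, CurationConfig(min_class_size=1))
        retained = {cid for cls in result.classes for cid in cls.compound_ids}
        logged = {e["compound_id"] for e in result.log if "compound_id" in e}
        assert retained | logged == {"c1", "c2", "c3", "c4", "c5"}
        assert retained.isdisjoint({"c2", "c3", "c4"})

    def test_idempotent(self):
        records = [
            rec(f"c{i}", smi, ki(pki=5.0 + i))
            for i, smi in enumerate(["CCO", "CCN", "CCC", "CCCO"])
        ]
        once = curate(records, CurationConfig(min_class_size=1))
        again_records = [
            rec(cid, once.structures[cid], ki(pki=pki))
            for cls in once.classes
            for cid, pki in cls.members
        ]
        twice = curate(again_records, CurationConfig(min_class_size=1))
        assert [c.members for c in twice.classes] == [c.members for c in once.classes]


class TestTableIO:
    def test_round_trip_pki_and_nm(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "compound_id,smiles,target_id,standard_type,standard_value_nM,pki\n"
            "c1,CCO,T1,Ki,10.0,\n"
            "c2,CCN,T1,,,7.5\n"
        )
        records = {r.compound_id: r for r in read_activity_table(path)}
        assert records["c1"].measurements[0].pki_value == pytest.approx(8.0)
        assert records["c2"].measurements[0].pki_value == 7.5
        assert records["c2"].measurements[0].measurement_type is MeasurementType.KI

    def test_mixed_units_in_one_row_rejected(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text(
            "compound_id,smiles,target_id,standard_type,standard_value_nM,pki\n"
            "c1,CCO,T1,Ki,10.0,8.0\n"
        )
        with pytest.raises(ValueError, match="mixes"):
            read_activity_table(path)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "act.csv"
        path.write_text("compound_id,smiles,target_id,pki\n")
        with pytest.raises(ValueError, match="empty"):
            read_activity_table(path)
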