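import pandas as pd
import pytest

from conftest import detected_keys, frame_to_class

from cliffscout.cliffs import (
    ActivityCliff,
    class_profile,
    consensus,
    detect_chirality_cliffs,
    detect_g1,
    detect_g2,
    detect_g3,
    detect_iso_acs,
    detect_isomer_mmp_cliffs,
    fingerprint_qualifying_pairs,
    flag_privileged,
    summarize,
)
from cliffscout.mmp import PairConfig, pairs_for_class
from cliffscout.thresholds import constant_threshold


def make_class(rows, target="T1"):
    frame = pd.DataFrame(
        [
            {"compound_id": cid, "smiles": smi, "target_id": target, "pki": pki}
            for cid, smi, pki in rows
        ]
    )
    return frame_to_class(frame, min_class_size=1)


SCAFFOLD = "O=C(Nc1ccc({})cc1)c1ccccc1"


class TestDetectG1:
    @pytest.mark.parametrize(
        "pki_b,expect_ac",
        [(5.0, True), (7.2, False), (7.1, True)],  # deltas 4.1, 1.9, 2.0 (inclusive)
    )
    def test_mmp_constant_threshold(self, pki_b, expect_ac):
        cls, st = make_class(
            [("a", SCAFFOLD.format("C"), 9.1), ("b", SCAFFOLD.format("CC"), pki_b)]
        )
        acs = detect_g1(cls, st, criterion="mmp")
        assert bool(acs) == expect_ac
        if acs:
            assert acs[0].id_high == "a"
            assert acs[0].delta_pki == pytest.approx(9.1 - pki_b)
            assert acs[0].generation == "G1"

    def test_fingerprint_criterion(self):
        cls, st = make_class(
            [
                ("a", SCAFFOLD.format("C"), 9.5),
                ("b", SCAFFOLD.format("CC"), 5.0),
                ("far", "CCO", 5.0),
            ]
        )
        acs = detect_g1(cls, st, criterion="fp_ecfp4")
        assert detected_keys(acs) == {("a", "b", 0)}
        assert acs[0].tc > 0.55

    def test_unknown_criterion(self):
        cls, st = make_class([("a", "CCO", 5.0)])
        with pytest.raises(ValueError):
            detect_g1(cls, st, criterion="fp_daylight")


class TestDetectG2G3:
    def test_class_threshold_applied(self):
        cls, st = make_class(
            [("a", SCAFFOLD.format("C"), 8.5), ("b", SCAFFOLD.format("CC"), 7.0)]
        )
        low = constant_threshold(1.4, "T1")
        high = constant_threshold(2.2, "T1")
        assert len(detect_g2(cls, st, profile=low)) == 1
        assert detect_g2(cls, st, profile=high) == []

    def test_cat1_class_excluded(self, caplog):
        import logging

        rows = [
            (f"c{i}", SCAFFOLD.format("C" * (i + 1)), 7.0 + 0.01 * i) for i in range(6)
        ]
        cls, st = make_class(rows)
        profile = class_profile(cls, st, min_pairs=3)
        assert profile.excluded
        with caplog.at_level(logging.INFO):
            assert detect_g2(cls, st, profile=profile) == []
        assert "CAT1" in caplog.text

    def test_g3_records_site_counts(self, recovery_data):
        cls, st, truth = recovery_data
        acs = detect_g3(cls, st)
        by_sites = {1: 0, 2: 0}
        for ac in acs:
            by_sites[ac.n_sites] += 1
        planted_ss = sum(1 for p in truth.planted_acs if p["n_sites"] == 1)
        planted_ds = sum(1 for p in truth.planted_acs if p["n_sites"] == 2)
        assert by_sites == {1: planted_ss, 2: planted_ds}

    def test_g2_subset_of_g3(self, recovery_data):
        cls, st, _ = recovery_data
        profile = class_profile(cls, st)
        g2_keys = {a.key for a in detect_g2(cls, st, profile=profile)}
        g3_keys = {a.key for a in detect_g3(cls, st, profile=profile)}
        assert g2_keys <= g3_keys

    def test_every_cliff_meets_its_threshold(self, recovery_data):
        cls, st, _ = recovery_data
        profile = class_profile(cls, st)
        for ac in detect_g3(cls, st, profile=profile):
            assert ac.delta_pki >= profile.threshold
            assert ac.pair is not None and ac.pair.n_sites == ac.n_sites

    def test_raising_threshold_never_adds_cliffs(self, recovery_data):
        cls, st, _ = recovery_data
        pairs = pairs_for_class(cls, st, PairConfig(k_max=2, rules="retrosynthetic"))
        counts = [
            len(detect_g3(cls, st, profile=constant_threshold(t), qps=pairs))
            for t in (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestIsoAcs:
    def test_cresol_positional_isomers(self):
        cls, st = make_class(
            [
                ("ortho", "Cc1ccccc1O", 9.0),
                ("meta", "Cc1cccc(O)c1", 6.5),
            ]
        )
        acs = detect_iso_acs(cls, st)
        assert detected_keys(acs) == {("meta", "ortho", 1)}
        assert "iso" in acs[0].flags

    def test_different_substituent_not_iso(self):
        cls, st = make_class(
            [("a", "Cc1ccccc1O", 9.0), ("b", "CCc1ccccc1O", 6.0)]
        )
        assert detect_iso_acs(cls, st) == []

    def test_small_delta_not_a_cliff(self):
        cls, st = make_class(
            [("ortho", "Cc1ccccc1O", 7.0), ("meta", "Cc1cccc(O)c1", 6.5)]
        )
        assert detect_iso_acs(cls, st) == []


class TestIsomerMmpCliffs:
    def test_isomer_of_weak_compound_forms_additional_cliff(self):
        # mmp-cliff a/b plus a positional isomer of the weak partner b
        # (meta instead of para attachment: not itself an MMP of a)
        cls, st = make_class(
            [
                ("a", SCAFFOLD.format("C"), 9.2),
                ("b", SCAFFOLD.format("OCC"), 5.1),
                ("iso_b", "O=C(Nc1cccc(OCC)c1)c1ccccc1", 5.5),
            ]
        )
        mmp_acs = detect_g1(cls, st, criterion="mmp")
        assert detected_keys(mmp_acs) == {("a", "b", 1)}
        extra = detect_isomer_mmp_cliffs(mmp_acs, cls, st)
        assert detected_keys(extra) == {("a", "iso_b", 1)}
        assert "isomer_mmp" in extra[0].flags

    def test_no_isomer_present(self):
        cls, st = make_class(
            [("a", SCAFFOLD.format("C"), 9.2), ("b", SCAFFOLD.format("CC"), 5.1)]
        )
        acs = detect_g1(cls, st, criterion="mmp")
        assert detect_isomer_mmp_cliffs(acs, cls, st) == []

    def test_isomer_below_threshold_ignored(self):
        cls, st = make_class(
            [
                ("a", SCAFFOLD.format("C"), 9.2),
                ("b", SCAFFOLD.format("OCC"), 5.1),
                ("iso_b", "O=C(Nc1cccc(OCC)c1)c1ccccc1", 7.5),
            ]
        )
        acs = detect_g1(cls, st, criterion="mmp")
        assert detect_isomer_mmp_cliffs(acs, cls, st) == []


CHIRAL = "C[C{}](O)c1ccc(F)cc1"


class TestChiralityCliffs:
    def test_enantiomer_pair(self):
        cls, st = make_class(
            [("r", CHIRAL.format("@@H"), 8.8), ("s", CHIRAL.format("@H"), 6.5)]
        )
        acs = detect_chirality_cliffs(cls, st)
        assert detected_keys(acs) == {("r", "s", 1)}
        assert "chirality" in acs[0].flags

    def test_double_epimer_excluded(self):
        cls, st = make_class(
            [
                ("rr", "C[C@H](O)[C@H](N)c1ccccc1", 9.0),
                ("ss", "C[C@@H](O)[C@@H](N)c1ccccc1", 5.0),
            ]
        )
        assert detect_chirality_cliffs(cls, st) == []

    def test_single_epimer_of_two_centers_detected(self):
        cls, st = make_class(
            [
                ("rr", "C[C@H](O)[C@H](N)c1ccccc1", 9.0),
                ("rs", "C[C@H](O)[C@@H](N)c1ccccc1", 5.0),
            ]
        )
        assert len(detect_chirality_cliffs(cls, st)) == 1

    def test_achiral_and_unassigned_excluded(self):
        cls, st = make_class(
            [
                ("a", "CCO", 9.0),
                ("b", "CCN", 5.0),
                ("r", CHIRAL.format("@@H"), 8.8),
                ("flat", "CC(O)c1ccc(F)cc1", 5.0),  # undefined stereocenter
            ]
        )
        assert detect_chirality_cliffs(cls, st) == []


class TestFlagsAndConsensus:
    def test_privileged_flag_requires_pattern_in_both(self):
        cls, st = make_class(
            [
                ("a", SCAFFOLD.format("C"), 9.1),
                ("b", SCAFFOLD.format("CC"), 5.0),
                ("c", "Cc1ccccc1O", 9.3),
                ("d", "CCc1ccccc1O", 5.2),
            ]
        )
        acs = detect_g1(cls, st, criterion="mmp")
        flagged = flag_privileged(acs, ["[NX3]C(=O)c1ccccc1"], st)
        by_key = {a.key: a for a in flagged}
        assert "privileged_substructure" in by_key[("T1", "a", "b")].flags
        assert "privileged_substructure" not in by_key[("T1", "c", "d")].flags

    def test_empty_pattern_list_flags_nothing(self):
        cls, st = make_class(
            [("a", SCAFFOLD.format("C"), 9.1), ("b", SCAFFOLD.format("CC"), 5.0)]
        )
        acs = flag_privileged(detect_g1(cls, st, criterion="mmp"), [], st)
        assert all("privileged_substructure" not in a.flags for a in acs)

    def test_invalid_pattern_named(self):
        cls, st = make_class([("a", "CCO", 5.0)])
        with pytest.raises(ValueError, match="not_smarts"):
            flag_privileged([], ["not_smarts(("], st)

    def test_consensus_intersection(self):
        cls, st = make_class(
            [
                ("a", SCAFFOLD.format("C"), 9.5),
                ("b", SCAFFOLD.format("CC"), 5.0),
                ("c", SCAFFOLD.format("OC"), 9.4),
            ]
        )
        maccs = detect_g1(cls, st, criterion="fp_maccs")
        ecfp4 = detect_g1(cls, st, criterion="fp_ecfp4")
        mmp = detect_g1(cls, st, criterion="mmp")
        both = consensus([maccs, ecfp4, mmp])
        assert {a.key for a in both} == (
            {a.key for a in maccs} & {a.key for a in ecfp4} & {a.key for a in mmp}
        )
        assert all("consensus" in a.flags for a in both)
        assert consensus([mmp, mmp]) == [a.with_flags("consensus") for a in mmp]

    def test_consensus_needs_two_sets(self):
        with pytest.raises(ValueError):
            consensus([[]])


class TestSummaries:
    def test_percentages(self, recovery_data):
        cls, st, truth = recovery_data
        pairs = pairs_for_class(cls, st, PairConfig(k_max=2, rules="retrosynthetic"))
        acs = detect_g3(cls, st)
        s = summarize(acs, pairs, cls)
        assert s.n_ac == len(truth.planted_acs)
        assert s.n_ac <= s.n_qp
        assert s.pct_ac == pytest.approx(100 * s.n_ac / s.n_qp)
        assert s.n_ss_ac + s.n_ds_ac == s.n_ac
        assert 0 < s.pct_ac_compounds <= 100

    def test_zero_qp_gives_missing_percentage(self):
        cls, st = make_class([("a", "CCO", 5.0)])
        s = summarize([], 0, cls)
        assert s.pct_ac is None and s.n_ac == 0
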