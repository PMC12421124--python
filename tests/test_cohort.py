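"""Cohort I/O, index-nodule reduction and effective-size assessment."""

import pytest

from nodulestrat import (
    BTS_PROTOCOL,
    DIAMETER_PROTOCOL,
    NoduleRecord,
    ParticipantRecord,
    ProtocolConfig,
    effective_size,
    load_cohort,
    reduce_to_index,
    write_cohort,
)
from nodulestrat.errors import CohortValidationError, SchemaError


def nodule(nid="n1", vol=100.0, diam=6.0, **kw):
    reliable = vol is not None
    return NoduleRecord(
        nodule_id=nid,
        diameter_mm=diam,
        volume_mm3=vol,
        segmentation_reliable=reliable,
        **kw,
    )


def participant(pid="p1", nodules=(), cancer=False, **kw):
    malignant = [n.nodule_id for n in nodules if n.malignant]
    defaults = dict(
        age_years=65.0,
        sex="male",
        family_history_lung_cancer=False,
        emphysema=False,
    )
    defaults.update(kw)
    return ParticipantRecord(
        participant_id=pid,
        nodules=tuple(nodules),
        cancer_outcome=cancer,
        malignant_nodule_id=malignant[0] if malignant else None,
        **defaults,
    )


class TestDomainInvariants:
    def test_volume_absent_iff_segmentation_unreliable(self):
        with pytest.raises(CohortValidationError):
            NoduleRecord(nodule_id="x", diameter_mm=5.0, volume_mm3=None,
                         segmentation_reliable=True)
        with pytest.raises(CohortValidationError):
            NoduleRecord(nodule_id="x", diameter_mm=5.0, volume_mm3=50.0,
                         segmentation_reliable=False)

    def test_at_most_one_malignant_nodule(self):
        bad = [nodule("a", malignant=True), nodule("b", malignant=True)]
        with pytest.raises(CohortValidationError):
            participant(nodules=bad, cancer=True)

    def test_cancer_outcome_requires_malignant_reference(self):
        with pytest.raises(CohortValidationError):
            ParticipantRecord(
                participant_id="p",
                age_years=60,
                sex="female",
                family_history_lung_cancer=False,
                emphysema=False,
                nodules=(nodule(),),
                cancer_outcome=True,
                malignant_nodule_id=None,
            )


class TestIO:
    @pytest.mark.parametrize("layout", ["participant_rows", "nodule_rows"])
    def test_write_load_round_trip(self, tmp_path, layout):
        cohort = [
            participant("a", [nodule("a-n1", 120.0, 6.5)]),
            participant("b", [nodule("b-n1", None, 7.0)]),
            participant("c", []),
            participant("d", [nodule("d-n1", 500.0, 11.0, malignant=True)],
                        cancer=True, sex="female"),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path, layout=layout)
        assert load_cohort(path, layout) == cohort

    def test_nodule_rows_groups_by_participant(self, tmp_path):
        cohort = [
            participant("a", [nodule("a-n1", 50.0, 4.0), nodule("a-n2", 80.0, 5.0)])
        ]
        path = tmp_path / "c.csv"
        write_cohort(cohort, path, layout="nodule_rows")
        loaded = load_cohort(path, "nodule_rows")
        assert len(loaded) == 1
        assert len(loaded[0].nodules) == 2
        assert loaded == cohort

    def test_tab_delimited_accepted(self, tmp_path):
        cohort = [participant("a", [nodule("a-n1")])]
        path = tmp_path / "c.tsv"
        write_cohort(cohort, path, sep="\t")
        assert load_cohort(path) == cohort

    def test_empty_volume_with_unreliable_flag_parses_absent(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "participant_id,age_years,sex,family_history,emphysema,"
            "cancer_outcome,volume_mm3,diameter_mm,segmentation_reliable,"
            "spiculated,upper_lobe,perifissural,retronodule,malignant\n"
            "p1,64,male,false,false,false,,7.2,false,false,false,false,"
            "false,false\n"
        )
        (p,) = load_cohort(path)
        assert p.nodules[0].volume_mm3 is None
        assert not p.nodules[0].segmentation_reliable

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("participant_id,age_years,sex\np1,64,male\n")
        with pytest.raises(SchemaError, match="family_history"):
            load_cohort(path)

    def test_volume_with_unreliable_flag_is_row_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "participant_id,age_years,sex,family_history,emphysema,"
            "cancer_outcome,volume_mm3,diameter_mm,segmentation_reliable,"
            "spiculated,upper_lobe,perifissural,retronodule,malignant\n"
            "p1,64,male,false,false,false,55,7.2,false,,,,,\n"
        )
        with pytest.raises(CohortValidationError, match="line 2"):
            load_cohort(path)


class TestReduceToIndex:
    def test_largest_benign_selected(self):
        p = participant("a", [nodule("n1", 50.0, 4.0), nodule("n2", 120.0, 6.0)])
        (ip,) = reduce_to_index([p])
        assert ip.index_nodule.nodule_id == "n2"

    def test_malignant_overrides_size(self):
        p = participant(
            "a",
            [nodule("big", 500.0, 10.0), nodule("small", 90.0, 5.0, malignant=True)],
            cancer=True,
        )
        (ip,) = reduce_to_index([p])
        assert ip.index_nodule.nodule_id == "small"
        assert ip.outcome

    def test_benign_retronodule_never_selected(self):
        p = participant(
            "a",
            [nodule("seen", 100.0, 6.0),
             nodule("retro", 900.0, 12.0, is_retronodule=True)],
        )
        (ip,) = reduce_to_index([p])
        assert ip.index_nodule.nodule_id == "seen"

    def test_malignant_retronodule_participates(self):
        p = participant(
            "a",
            [nodule("seen", 100.0, 6.0),
             nodule("retro", 40.0, 3.5, is_retronodule=True, malignant=True)],
            cancer=True,
        )
        (ip,) = reduce_to_index([p])
        assert ip.index_nodule.nodule_id == "retro"

    def test_tie_break_is_deterministic_smallest_id(self):
        p = participant("a", [nodule("b", 100.0, 6.0), nodule("a", 100.0, 6.0)])
        (ip,) = reduce_to_index([p])
        assert ip.index_nodule.nodule_id == "a"

    def test_diameter_key_uses_diameter_first(self):
        p = participant("a", [nodule("v", 200.0, 5.0), nodule("d", 100.0, 9.0)])
        assert reduce_to_index([p], "volume")[0].index_nodule.nodule_id == "v"
        assert reduce_to_index([p], "diameter")[0].index_nodule.nodule_id == "d"

    def test_cardinality_preserved_and_partition(self, fixture_cohort,
                                                 indexed_fixture):
        assert len(indexed_fixture) == len(fixture_cohort)
        with_idx = sum(p.index_nodule is not None for p in indexed_fixture)
        without = sum(p.index_nodule is None for p in indexed_fixture)
        assert with_idx + without == len(fixture_cohort)


class TestEffectiveSize:
    def test_volume_below_rule_out(self):
        a = effective_size(nodule(vol=79.0, diam=5.5), BTS_PROTOCOL)
        assert a.mode == "volumetric" and a.rule_out_pass and not a.rule_in_pass

    def test_boundary_is_strict_for_rule_out_inclusive_for_rule_in(self):
        at_out = effective_size(nodule(vol=80.0), BTS_PROTOCOL)
        assert not at_out.rule_out_pass
        at_in = effective_size(nodule(vol=300.0), BTS_PROTOCOL)
        assert at_in.rule_in_pass

    def test_unreliable_segmentation_uses_fallback_diameters(self):
        n = nodule(vol=None, diam=7.0)
        a = effective_size(n, BTS_PROTOCOL)
        assert a.mode == "diameter_fallback"
        assert not a.rule_out_pass and not a.rule_in_pass
        assert effective_size(nodule(vol=None, diam=5.9), BTS_PROTOCOL).rule_out_pass
        assert effective_size(nodule(vol=None, diam=8.0), BTS_PROTOCOL).rule_in_pass

    def test_diameter_primary_mode_ignores_volume(self):
        a = effective_size(nodule(vol=500.0, diam=4.0), DIAMETER_PROTOCOL)
        assert a.unit == "mm" and a.rule_out_pass

    def test_total_over_fixture(self, fixture_cohort):
        # every nodule receives an assessment under every config
        for proto in (BTS_PROTOCOL, DIAMETER_PROTOCOL,
                      ProtocolConfig(rule_out_volume_mm3=100.0)):
            for p in fixture_cohort[:500]:
                for n in p.nodules:
                    a = effective_size(n, proto)
                    assert not (a.rule_out_pass and a.rule_in_pass)
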