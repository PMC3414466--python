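from __future__ import annotations

import pytest

from seamount_ebsa import (
    Observation,
    Quality,
    SeamountRecord,
    Status,
    Typology,
    case_study_fixtures,
    default_catalogs,
    fixture,
    max_weight_sum,
    slots,
    validate_record,
)


class TestDefaultCatalogs:
    def test_indicator_slot_structure(self):
        indicators, _, _ = default_catalogs()
        slot_list = slots(indicators)
        assert len(slot_list) == 10
        by_typ = {}
        for s in slot_list:
            by_typ.setdefault(s.typology, []).append(s)
        assert len(by_typ[Typology.BENTHIC]) == 4
        assert all(s.max_weight == 3 for s in by_typ[Typology.BENTHIC])
        assert sorted(s.max_weight for s in by_typ[Typology.BENTHOPELAGIC]) == [1, 2]
        pelagic = by_typ[Typology.PELAGIC]
        assert len(pelagic) == 2 and all(s.is_pair for s in pelagic)
        for s in pelagic:
            assert sorted(m.weight for m in s.members) == [1, 2]
        assert [s.max_weight for s in by_typ[Typology.HISTORICAL]] == [1]
        assert [s.max_weight for s in by_typ[Typology.GEOLOGICAL]] == [1]

    def test_max_weight_sum_is_21(self):
        assert max_weight_sum() == 21

    def test_threats_and_groups(self):
        _, threats, groups = default_catalogs()
        assert len(threats) == 9
        assert sum(t.kind == "mining" for t in threats) == 1
        assert len(groups) == 5

    def test_deterministic(self):
        assert default_catalogs() == default_catalogs()


class TestQualityWeights:
    @pytest.mark.parametrize(
        "grade,weight",
        [(Quality.HIGH, 0.0), (Quality.MEDIUM, 0.5), (Quality.LOW, 1.0)],
    )
    def test_weight_mapping(self, grade, weight):
        assert grade.weight == weight


class TestFixtures:
    def test_eight_fixtures_in_order(self):
        names = [r.name for r in case_study_fixtures()]
        assert names == ["Sedlo", "Condor", "Rosemary", "Anton Dohrn",
                         "Josephine", "Gorringe", "Bowie", "Cobb"]

    @pytest.mark.parametrize("name", [r.name for r in case_study_fixtures()])
    def test_every_fixture_validates(self, name):
        rep = validate_record(fixture(name))
        assert rep.errors == []

    def test_sedlo_cells(self):
        rec = fixture("Sedlo")
        assert rec.indicators["vents"] == Observation(Status.ABSENT, Quality.LOW)
        assert rec.indicators["cold_water_corals"] == Observation(
            Status.PRESENT, Quality.HIGH
        )
        assert rec.indicators["threatened_visiting_pelagics"] == Observation(
            Status.PRESENT, Quality.LOW
        )
        assert rec.indicators["naturalness"] == Observation(
            Status.PRESENT, Quality.HIGH
        )

    def test_rosemary_data_deficiencies(self):
        rec = fixture("Rosemary")
        assert rec.indicators["vents"].status is Status.DATA_DEFICIENT
        assert rec.indicators["sponge_aggregations"].status is Status.DATA_DEFICIENT
        # both members of the visiting-pelagics pair are data-deficient
        assert rec.indicators["threatened_visiting_pelagics"].status is \
            Status.DATA_DEFICIENT
        assert rec.indicators["visiting_pelagics"].status is Status.DATA_DEFICIENT

    def test_cobb_data_deficient_threats(self):
        rec = fixture("Cobb")
        for t in ("hook_and_line", "longline_pelagic", "purse_seine",
                  "mineral_extraction"):
            assert rec.threats[t].status is Status.DATA_DEFICIENT

    def test_sedlo_naturalness_warning(self):
        rep = validate_record(fixture("Sedlo"))
        assert len(rep.warnings) == 1
        assert "naturalness" in rep.warnings[0]


class TestValidation:
    def test_empty_record_has_19_missing_slots(self):
        rep = validate_record(SeamountRecord("empty"))
        assert len([e for e in rep.errors if "missing" in e]) == 19

    def test_both_pair_members_scored_is_one_error(self):
        rec = fixture("Sedlo")
        rec.indicators["air_breathing"] = Observation(Status.PRESENT, Quality.HIGH)
        rep = validate_record(rec)
        assert len(rep.errors) == 1
        assert "OR-pair" in rep.errors[0]

    def test_grade_on_data_deficient_is_error(self):
        rec = fixture("Condor")
        rec.threats["gillnet_bottom"] = Observation(
            Status.DATA_DEFICIENT, Quality.MEDIUM
        )
        rep = validate_record(rec)
        assert any("quality grade" in e for e in rep.errors)

    def test_scored_without_grade_is_error(self):
        rec = fixture("Condor")
        rec.indicators["macrophytes"] = Observation(Status.ABSENT)
        rep = validate_record(rec)
        assert any("lacks a quality grade" in e for e in rep.errors)

    def test_not_applicable_outside_pair_is_error(self):
        rec = fixture("Condor")
        rec.indicators["vents"] = Observation(Status.NOT_APPLICABLE)
        rep = validate_record(rec)
        assert any("not_applicable" in e for e in rep.errors)

    def test_unknown_ids_are_errors(self):
        rec = fixture("Condor")
        rec.indicators["kelp_forests"] = Observation(Status.PRESENT, Quality.HIGH)
        rep = validate_record(rec)
        assert any("unknown indicator" in e for e in rep.errors)
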