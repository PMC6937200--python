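"""Data structures, grouping rules, filters and tabular I/O."""

import csv
import math
import warnings
from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietstat as ds
from dietstat.errors import (
    ConfigurationError,
    LinkageError,
    NoDataError,
    ValidationError,
)


def _stomach(fish_id="f1", station="s1", length=35.0, items=(), stomach_w=10.0):
    return ds.StomachRecord(
        fish_id=fish_id,
        station_id=station,
        length=length,
        body_weight=400.0,
        stomach_weight=stomach_w,
        items=tuple(items),
    )


def _station(station_id="s1", year=2012):
    return ds.StationRecord(
        station_id=station_id,
        longitude=-22.0,
        latitude=63.0,
        datetime=datetime(year, 7, 15, 10, 30),
        year=year,
        week_number=29,
        bottom_depth=300.0,
        sst_0_50=10.0,
        sss_0_50=35.0,
        zooplankton_biomass=80.0,
        total_catch=1500.0,
    ).with_derived_labels()


class TestGroupingRules:
    @pytest.mark.parametrize(
        "length,expected",
        [(33, "S"), (25, "S"), (34, "M"), (36, "M"), (38, "M"), (39, "L"), (48, "L")],
    )
    def test_length_groups(self, length, expected):
        assert ds.assign_length_group(length) == expected

    def test_length_groups_partition_plausible_range(self):
        # every length a retained fish can have maps to exactly one label
        for length in np.arange(25.0, 50.0, 0.5):
            assert ds.assign_length_group(length) in {"S", "M", "L"}

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValidationError):
            ds.assign_length_group(0)

    @pytest.mark.parametrize(
        "hour,minute,expected",
        [(4, 30, "P1"), (5, 59, "P1"), (6, 0, "P2"), (12, 0, "P3"), (23, 59, "P4")],
    )
    def test_time_periods_are_halfopen_six_hour_blocks(self, hour, minute, expected):
        assert ds.assign_time_period(datetime(2012, 7, 1, hour, minute)) == expected

    @pytest.mark.parametrize(
        "depth,expected", [(100, "D1"), (200, "D1"), (201, "D2"), (700, "D3"), (1500, "D4")]
    )
    def test_shore_classes(self, depth, expected):
        assert ds.assign_shore_class(depth) == expected

    def test_area_assignment(self):
        assert ds.assign_area(-22.0, 63.0) == "SW"
        assert ds.assign_area(-10.0, 67.0) == "N"
        assert ds.assign_area(-17.0, 63.0) == "SE"
        # shared SW/W edge at 64 N: precedence order N > E > SE > SW > W
        assert ds.assign_area(-22.0, 64.0) == "SW"
        assert ds.assign_area(0.0, 0.0) == "unassigned"


class TestFultonK:
    def test_round_numbers(self):
        assert ds.fulton_k(1000, 10) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        assert ds.fulton_k(400, 36) == pytest.approx(100 * 400 / 46656, rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            ds.fulton_k(0, 36)


class TestSubsampleExpansion:
    def test_linear_scaling(self):
        item = ds.PreyItem("Calanus", "copepods", count=30, weight=0.1)
        out = ds.expand_subsample(item, total_volume=10, subsample_volume=2)
        assert out.count == pytest.approx(150)
        assert out.weight == pytest.approx(0.5)
        assert out.scale_factor == pytest.approx(5.0)

    def test_identity_when_whole_sample_counted(self):
        item = ds.PreyItem("Calanus", "copepods", count=30, weight=0.1)
        out = ds.expand_subsample(item, 2, 2)
        assert out.count == item.count and out.weight == item.weight

    def test_weight_scaling(self):
        item = ds.PreyItem("Oikopleura", "appendicularians", count=4, weight=0.04)
        assert ds.expand_subsample(item, 8, 1).weight == pytest.approx(0.32)

    @pytest.mark.parametrize("total,sub", [(0, 1), (2, 0), (1, 2)])
    def test_bad_volumes_rejected(self, total, sub):
        item = ds.PreyItem("x", "copepods", count=1, weight=0.1)
        with pytest.raises(ValidationError):
            ds.expand_subsample(item, total, sub)


class TestRecords:
    def test_parasite_only_stomach_is_empty(self):
        s = _stomach(items=[ds.PreyItem("Anisakis", "parasite", count=2, weight=0.3)])
        assert s.is_empty

    def test_prey_item_validation(self):
        with pytest.raises(ValidationError):
            ds.PreyItem("x", "copepods", count=-1, weight=0.1)
        with pytest.raises(ValidationError):
            ds.PreyItem("x", "not_a_group", count=1, weight=0.1)
        with pytest.raises(ValidationError):
            ds.PreyItem("x", "copepods", count=0, weight=0.0)

    def test_implausible_length_rejected(self):
        with pytest.raises(ValidationError):
            _stomach(length=70.0)


class TestModelFilters:
    def test_station_with_nine_stomachs_removed(self):
        stomachs = [_stomach(fish_id=f"f{i}") for i in range(9)]
        with pytest.raises(NoDataError):
            ds.apply_model_filters(stomachs, [_station()])

    def test_small_fish_then_sparse_station(self):
        # 10 stomachs, one fish of 24 cm: fish removed first, then the
        # station has only 9 left and is removed too
        stomachs = [_stomach(fish_id=f"a{i}") for i in range(9)]
        stomachs.append(_stomach(fish_id="small", length=24.0))
        keep = [
            _stomach(fish_id=f"b{i}", station="s2") for i in range(10)
        ]
        kept, kept_st, report = ds.apply_model_filters(
            stomachs + keep, [_station("s1"), _station("s2")]
        )
        assert report.n_fish_removed_small == 1
        assert report.n_stations_removed_sparse == 1
        assert {s.station_id for s in kept} == {"s2"}
        assert len(kept) == 10

    def test_identity_when_nothing_to_filter(self):
        stomachs = [_stomach(fish_id=f"f{i}") for i in range(10)]
        kept, _, report = ds.apply_model_filters(stomachs, [_station()])
        assert kept == stomachs
        assert report.n_fish_removed_small == 0

    def test_idempotence(self, small_survey):
        once = ds.apply_model_filters(small_survey.stomachs, small_survey.stations)
        twice = ds.apply_model_filters(once[0], once[1])
        assert [s.fish_id for s in twice[0]] == [s.fish_id for s in once[0]]

    def test_unknown_station_is_linkage_error(self):
        with pytest.raises(LinkageError):
            ds.apply_model_filters([_stomach(station="ghost")], [_station()])


class TestDietMatrix:
    def test_aggregation_row(self):
        s = _stomach(
            items=[
                ds.PreyItem("Calanus", "copepods", count=100, weight=2.0),
                ds.PreyItem("Ammodytes", "fish", count=1, weight=1.0),
            ]
        )
        m = ds.build_diet_matrix([s], [_station()])
        assert m.weight.loc["f1", "copepods"] == 2.0
        assert m.weight.loc["f1", "fish"] == 1.0

    def test_empty_stomach_keeps_zero_row(self):
        m = ds.build_diet_matrix([_stomach()], [_station()])
        assert m.n_stomachs == 1
        assert m.weight.to_numpy().sum() == 0.0

    def test_same_group_items_summed(self):
        s = _stomach(
            items=[
                ds.PreyItem("Calanus", "copepods", count=1, weight=0.5),
                ds.PreyItem("Oithona", "copepods", count=1, weight=0.5),
            ]
        )
        m = ds.build_diet_matrix([s], [_station()])
        assert m.weight.loc["f1", "copepods"] == pytest.approx(1.0)

    def test_weight_conservation(self, small_survey, diet_matrix):
        total_items = sum(
            it.weight for s in small_survey.stomachs for it in s.analysis_items
        )
        assert diet_matrix.weight.to_numpy().sum() == pytest.approx(
            total_items, rel=1e-9
        )

    def test_labels_carry_area_year_length_group(self, diet_matrix):
        assert set(diet_matrix.labels["area"]) <= set(ds.AREAS)
        assert set(diet_matrix.labels["length_group"]) <= {"S", "M", "L"}


class TestTabularIO:
    def test_round_trip(self, tmp_path, small_survey):
        sp = tmp_path / "stomachs.csv"
        tp = tmp_path / "stations.csv"
        ds.write_stomach_table(small_survey.stomachs, sp)
        ds.write_station_table(small_survey.stations, tp)
        stomachs = ds.read_stomach_table(sp)
        stations = ds.read_station_table(tp)
        assert stomachs == small_survey.stomachs
        assert stations == small_survey.stations

    def test_structural_grouping(self, tmp_path):
        path = tmp_path / "t.csv"
        rows = [
            ["f1", "s1", "35", "400", "10", "Calanus", "copepods", "5", "0.2", ""],
            ["f1", "s1", "35", "400", "10", "Ammodytes", "fish", "1", "2.0", "80"],
            ["f2", "s1", "33", "350", "8", "", "", "", "", ""],
        ]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(ds.data_model.STOMACH_COLUMNS)
            w.writerows(rows)
        records = ds.read_stomach_table(path)
        assert len(records) == 2
        assert len(records[0].items) == 2
        assert records[1].is_empty

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("fish_id,station_id\n")
        with pytest.raises(ConfigurationError):
            ds.read_stomach_table(path)

    def test_negative_weight_names_line(self, tmp_path):
        path = tmp_path / "t.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(ds.data_model.STOMACH_COLUMNS)
            w.writerow(["f1", "s1", "35", "400", "10", "X", "copepods", "1", "-0.5", ""])
        with pytest.raises(ValidationError, match="line 2"):
            ds.read_stomach_table(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "t.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["ID", "station_id", "length_cm", "body_weight_g",
                        "stomach_weight_g", "taxon", "prey_group", "prey_count",
                        "prey_weight_g", "prey_length_mm"])
            w.writerow(["f9", "s1", "35", "400", "10", "", "", "", "", ""])
        records = ds.read_stomach_table(path, dialect={"fish_id": "ID"})
        assert records[0].fish_id == "f9"


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=25.0, max_value=50.0, allow_nan=False))
def test_every_retained_length_gets_a_label(length):
    assert ds.assign_length_group(length) in {"S", "M", "L"}
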