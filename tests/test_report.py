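import numpy as np
import pytest

from vaeeg.core import BANDS
from vaeeg.report import (
    FixtureTable,
    all_ns_subjects,
    band_similarity,
    consistency,
    decide,
    load_fixture,
    load_subjects,
    reproduce_paper_aggregates,
    table4_band_similarity,
    topography_export,
)
from vaeeg.spectral import ChannelScores


@pytest.fixture(scope="module")
def table3():
    return load_fixture("table3")


@pytest.fixture(scope="module")
def table4():
    return load_fixture("table4")


def uniform_table(value, n_subjects=4):
    from vaeeg.stats import default_plan

    columns = default_plan().labels
    rows = [f"S{i:02d}" for i in range(n_subjects)]
    cells = {(r, c): value for r in rows for c in columns}
    return FixtureTable("synthetic", cells, {}, rows, columns)


class TestDecide:
    def test_boundary_p_is_non_significant(self):
        assert decide(0.05) == "ns"

    def test_just_below_boundary_is_significant(self):
        assert decide(0.049) == "sig"

    def test_p_one_is_non_significant(self):
        assert decide(1.0) == "ns"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            decide(1.5)

    def test_monotone_in_p(self):
        for p in np.linspace(0, 1, 21):
            if decide(p) == "ns":
                assert decide(min(p + 0.1, 1.0)) == "ns"


class TestFixtures:
    def test_table3_shape(self, table3):
        assert len(table3.row_ids) == 24
        assert len(table3.columns) == 9

    def test_table4_shape(self, table4):
        assert len(table4.row_ids) == 24
        assert table4.columns == ["raw", "delta", "theta", "alpha", "beta",
                                  "gamma"]

    def test_table2_has_23_rows_with_sparse_values(self):
        t2 = load_fixture("table2")
        assert len(t2.row_ids) == 23 and "Sub21" not in t2.row_ids
        printed = [v for v in t2.cells.values() if v is not None]
        assert len(printed) == 10

    def test_bold_markup_disagrees_with_numeric_rule_in_two_cells(
            self, table3):
        mismatches = [
            key for key, value in table3.cells.items()
            if table3.bold_mask[key] != (value >= 0.05)
        ]
        assert sorted(mismatches) == [("Sub01", "MA2 vs VA4"),
                                      ("Sub10", "MA2 vs VA3")]

    def test_subject_metadata_balanced_by_sex(self):
        subjects = load_subjects()
        assert len(subjects) == 24
        assert sum(s.sex == "M" for s in subjects) == 12
        assert sum(s.sex == "F" for s in subjects) == 12


class TestConsistency:
    def test_all_significant_table_has_zero_proportion(self):
        table = uniform_table(0.01)
        for scope in ("all-pairwise", "combined", "day1", "day2"):
            assert consistency(table, scope).numerator == 0

    def test_day_scopes_partition_the_pairwise_cells(self, table3):
        full = consistency(table3, "all-pairwise")
        d1 = consistency(table3, "day1")
        d2 = consistency(table3, "day2")
        assert d1.numerator + d2.numerator == full.numerator
        assert d1.denominator + d2.denominator == full.denominator

    def test_sex_scopes_partition_the_pairwise_cells(self, table3):
        full = consistency(table3, "all-pairwise")
        male = consistency(table3, "male")
        female = consistency(table3, "female")
        assert male.numerator + female.numerator == full.numerator
        assert male.denominator == female.denominator == 96

    def test_unknown_scope_rejected(self, table3):
        with pytest.raises(ValueError):
            consistency(table3, "weekend")

    def test_all_ns_subject_count_extremes(self):
        assert all_ns_subjects(uniform_table(0.0)) == 0
        assert all_ns_subjects(uniform_table(1.0, n_subjects=24)) == 24


class TestSimilarity:
    def test_identical_decision_maps_give_similarity_one(self):
        d = {"a": "ns", "b": "sig", "c": "ns"}
        assert band_similarity(d, dict(d)).similarity == 1.0

    def test_complementary_decision_maps_give_zero(self):
        raw = {"a": "ns", "b": "sig"}
        flipped = {"a": "sig", "b": "ns"}
        assert band_similarity(raw, flipped).similarity == 0.0

    def test_mismatched_subject_sets_rejected(self):
        with pytest.raises(ValueError):
            band_similarity({"a": "ns"}, {"b": "ns"})

    def test_similarity_invariant_under_label_swap(self, table4):
        res = table4_band_similarity(table4, "delta")
        swap = {"ns": "sig", "sig": "ns"}
        raw = {s: decide(v) for s, v in table4.column_values("raw").items()}
        dl = {s: decide(v) for s, v in table4.column_values("delta").items()}
        swapped = band_similarity({s: swap[d] for s, d in raw.items()},
                                  {s: swap[d] for s, d in dl.items()})
        assert swapped.similarity == res.similarity


class TestTopography:
    def montage_scores(self, values):
        from vaeeg.core import MONTAGE_16

        return ChannelScores(dict(zip(MONTAGE_16, values)), BANDS["raw"])

    def test_uniform_map_is_flat_in_decibels(self, tmp_path):
        from vaeeg.core import MONTAGE_16

        scores = self.montage_scores([4.0] * 16)
        frame = topography_export(scores, MONTAGE_16,
                                  path=tmp_path / "topo.csv")
        assert frame["S_m_dB"].nunique() == 1
        assert (tmp_path / "topo.csv").exists()

    def test_hot_channel_is_argmax_of_export(self):
        from vaeeg.core import MONTAGE_16

        values = [1.0] * 16
        values[MONTAGE_16.index("C3")] = 50.0
        frame = topography_export(self.montage_scores(values), MONTAGE_16)
        assert frame.loc[frame["S_m"].idxmax(), "channel"] == "C3"

    def test_missing_channel_rejected(self):
        scores = ChannelScores({"Fp1": 1.0}, BANDS["raw"])
        with pytest.raises(ValueError, match="missing"):
            topography_export(scores, ["Fp1", "Fp2"])

    def test_decade_scaling_shifts_decibels_by_ten(self):
        from vaeeg.core import MONTAGE_16

        f1 = topography_export(self.montage_scores([2.0] * 16), MONTAGE_16)
        f2 = topography_export(self.montage_scores([20.0] * 16), MONTAGE_16)
        np.testing.assert_allclose(f2["S_m_dB"] - f1["S_m_dB"], 10.0)


class TestReconciliation:
    def test_full_run_passes_all_recomputable_aggregates(self):
        checks = reproduce_paper_aggregates()
        assert checks and all(c.passed for c in checks)

    def test_perturbing_one_cell_across_threshold_is_local(self, table3):
        cells = dict(table3.cells)
        cells[("Sub04", "MA1 vs VA1")] = 0.01     # was 0.38, ns
        perturbed = FixtureTable("table3", cells, table3.bold_mask,
                                 table3.row_ids, table3.columns)
        checks = reproduce_paper_aggregates({"table3": perturbed})
        by_name = {c.name: c for c in checks}
        assert not by_name["pairwise_ns_percent"].passed
        assert not by_name["day1_ns_percent"].passed
        assert by_name["day2_ns_percent"].passed
        assert by_name["combined_ns_percent"].passed

    def test_empty_fixture_set_gives_empty_report(self):
        assert reproduce_paper_aggregates({}) == []
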