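"""Binarization, phenotype enumeration, filtering and lineage labels."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytofeat.errors import ConfigurationError
from cytofeat.fcs_io import ChannelMap
from cytofeat.phenotyping import (
    LineageRule,
    LineageRuleset,
    PhenotypeKey,
    PopulationTable,
    assign_population_ids,
    binarize,
    classify,
    enumerate_populations,
    filter_populations,
)
from cytofeat.thresholds import ThresholdEntry, ThresholdSet

from conftest import make_event_table

MARKERS = ("A", "B")


def _tset(**thresholds):
    return ThresholdSet(
        {m: ThresholdEntry(m, t, "manual") for m, t in thresholds.items()}
    )


@pytest.fixture
def ab_map():
    return ChannelMap.from_entries([("A", "A", "marker"), ("B", "B", "marker")])


class TestBinarize:
    def test_hand_example(self, ab_map):
        table = make_event_table(
            ab_map, {"A": np.array([1.0, 3.0, 1.0]), "B": np.array([5.0, 5.0, 9.0])}
        )
        bits = binarize(table, _tset(A=2.0, B=7.0))
        np.testing.assert_array_equal(bits, [[0, 0], [1, 0], [0, 1]])

    def test_value_at_threshold_is_negative(self, ab_map):
        table = make_event_table(ab_map, {"A": np.array([2.0]), "B": np.array([7.0])})
        bits = binarize(table, _tset(A=2.0, B=7.0))
        np.testing.assert_array_equal(bits, [[0, 0]])

    def test_thresholds_above_max_give_all_zero(self, ab_map):
        rng = np.random.default_rng(30)
        table = make_event_table(
            ab_map, {"A": rng.normal(size=100), "B": rng.normal(size=100)}
        )
        bits = binarize(table, _tset(A=100.0, B=100.0))
        assert bits.sum() == 0

    def test_missing_threshold_is_config_error(self, ab_map):
        table = make_event_table(ab_map, {"A": np.ones(5), "B": np.ones(5)})
        with pytest.raises(ConfigurationError, match="B"):
            binarize(table, _tset(A=2.0))


def _brute_force_counts(binary: np.ndarray) -> Counter:
    return Counter("".join(str(int(b)) for b in row) for row in binary)


class TestEnumerate:
    def test_single_cell_single_phenotype(self):
        table = enumerate_populations({"S1": np.array([[1, 0]])}, MARKERS)
        assert table.phenotypes == ["10"]
        assert table.df["percent"].tolist() == [100.0]

    def test_four_cells_three_phenotypes(self):
        binary = np.array([[0, 0], [0, 0], [0, 1], [1, 1]])
        table = enumerate_populations({"S1": binary}, MARKERS)
        by_pheno = table.df.set_index("phenotype")["percent"]
        assert by_pheno["00"] == 50.0
        assert by_pheno["01"] == 25.0
        assert by_pheno["11"] == 25.0

    def test_zero_filled_grid_across_samples(self):
        table = enumerate_populations(
            {"S1": np.array([[0, 0]]), "S2": np.array([[1, 1]])}, MARKERS
        )
        grid = table.percent_matrix()
        assert grid.shape == (2, 2)
        assert grid.loc["S1", "11"] == 0.0
        assert grid.loc["S2", "00"] == 0.0

    def test_conservation_before_filtering(self):
        rng = np.random.default_rng(31)
        binary = {f"S{i}": rng.integers(0, 2, size=(500, 4)) for i in range(3)}
        table = enumerate_populations(binary, ("A", "B", "C", "D"))
        sums = table.df.groupby("sample_id")[["count", "percent"]].sum()
        for s in binary:
            assert sums.loc[s, "count"] == table.denominators[s]
            assert sums.loc[s, "percent"] == pytest.approx(100.0, abs=1e-9)

    def test_inconsistent_marker_count_rejected(self):
        with pytest.raises(ConfigurationError, match="columns"):
            enumerate_populations({"S1": np.ones((3, 3), dtype=int)}, MARKERS)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        n_markers=st.integers(1, 8),
        n_events=st.integers(1, 400),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_agrees_with_brute_force_counter(self, n_markers, n_events, seed):
        rng = np.random.default_rng(seed)
        binary = rng.integers(0, 2, size=(n_events, n_markers))
        markers = tuple(f"M{i}" for i in range(n_markers))
        table = enumerate_populations({"S1": binary}, markers)
        expected = _brute_force_counts(binary)
        observed = dict(zip(table.df["phenotype"], table.df["count"]))
        assert observed == dict(expected)
        assert len(table.phenotypes) <= min(2**n_markers, n_events)


class TestFilter:
    def _table(self):
        # phenotype 01: 0.6% in one sample only; 11: always abundant;
        # 00: abundant but A-negative; 10: everywhere rare
        rows = []
        percents = {
            "S1": {"00": 49.4, "01": 0.6, "10": 0.1, "11": 49.9},
            "S2": {"00": 49.8, "01": 0.1, "10": 0.2, "11": 49.9},
        }
        for s, per in percents.items():
            for p, pct in per.items():
                rows.append((s, p, int(pct * 10), pct))
        df = pd.DataFrame(rows, columns=["sample_id", "phenotype", "count", "percent"])
        return PopulationTable(
            df=df, marker_order=MARKERS, denominators={"S1": 1000, "S2": 1000}
        )

    def test_no_filter_is_identity(self):
        table = self._table()
        out = filter_populations(table, min_percent=0.0)
        assert set(out.phenotypes) == set(table.phenotypes)

    def test_at_least_one_sample_semantics(self):
        out = filter_populations(self._table(), min_percent=0.5)
        assert "01" in out.phenotypes  # 0.6% in one sample is enough
        assert "10" not in out.phenotypes

    def test_marker_constraint(self):
        out = filter_populations(
            self._table(), min_percent=0.5, marker_constraints={"A": 1}
        )
        assert set(out.phenotypes) == {"11"}

    def test_min_count_rescues_rare_population(self):
        out = filter_populations(self._table(), min_percent=0.5, min_count=1)
        assert "10" in out.phenotypes

    def test_strictly_greater_than(self):
        table = self._table()
        out = filter_populations(table, min_percent=0.6)
        assert "01" not in out.phenotypes  # 0.6% is not > 0.6%

    def test_monotonicity_in_min_percent_and_constraints(self):
        rng = np.random.default_rng(32)
        binary = {f"S{i}": rng.integers(0, 2, size=(300, 3)) for i in range(3)}
        table = enumerate_populations(binary, ("A", "B", "C"))
        previous = None
        for min_percent in (0.0, 0.5, 2.0, 10.0):
            kept = set(filter_populations(table, min_percent).phenotypes)
            if previous is not None:
                assert kept <= previous
            previous = kept
        unconstrained = set(filter_populations(table, 1.0).phenotypes)
        constrained = set(
            filter_populations(table, 1.0, marker_constraints={"A": 1}).phenotypes
        )
        assert constrained <= unconstrained

    def test_ids_dense_and_deterministic(self):
        out = filter_populations(self._table(), min_percent=0.0)
        ids = out.population_ids
        assert sorted(ids.values()) == list(range(1, len(ids) + 1))
        # descending mean percent without lineage info
        ordered = sorted(ids, key=ids.get)
        means = out.df.groupby("phenotype")["percent"].mean()
        assert list(means[ordered]) == sorted(means, reverse=True)


RULES = LineageRuleset(
    rules=(
        LineageRule("lineage", (("A", 1), ("B", 0)), "T helper"),
        LineageRule("lineage", (("A", 0), ("B", 1)), "cytotoxic"),
        LineageRule("resident", (("B", 1),), "resident"),
    ),
)


class TestClassify:
    def _table(self):
        df = pd.DataFrame(
            {
                "sample_id": ["S1"] * 3,
                "phenotype": ["10", "01", "11"],
                "count": [1, 1, 1],
                "percent": [30.0, 30.0, 40.0],
            }
        )
        return PopulationTable(df=df, marker_order=MARKERS, denominators={"S1": 3})

    def test_first_match_and_default(self):
        out = classify(self._table(), RULES)
        labels = out.df.set_index("phenotype")
        assert labels.loc["10", "lineage"] == "T helper"
        assert labels.loc["01", "lineage"] == "cytotoxic"
        assert labels.loc["11", "lineage"] == "unknown"
        assert labels.loc["10", "subset"] == "unknown"

    def test_resident_label_tracks_bit(self):
        out = classify(self._table(), RULES)
        labels = out.df.set_index("phenotype")
        assert labels.loc["01", "resident"] == "resident"
        assert labels.loc["11", "resident"] == "resident"
        assert labels.loc["10", "resident"] == "unknown"

    def test_undeclared_marker_in_rule_rejected(self):
        bad = LineageRuleset(rules=(LineageRule("lineage", (("Z", 1),), "x"),))
        with pytest.raises(ConfigurationError, match="Z"):
            classify(self._table(), bad)

    def test_rule_order_irrelevant_for_disjoint_rules(self):
        flipped = LineageRuleset(rules=RULES.rules[::-1])
        a = classify(self._table(), RULES).df
        b = classify(self._table(), flipped).df
        pd.testing.assert_frame_equal(
            a.sort_values("phenotype").reset_index(drop=True),
            b.sort_values("phenotype").reset_index(drop=True),
        )

    def test_lineage_order_drives_population_ids(self):
        out = assign_population_ids(
            classify(self._table(), RULES), lineage_order=["cytotoxic", "T helper"]
        )
        ordered = sorted(out.population_ids, key=out.population_ids.get)
        assert ordered == ["01", "10", "11"]  # cytotoxic, T helper, unknown last


class TestPhenotypeKey:
    def test_render(self):
        key = PhenotypeKey(("CD3", "CD4"), (1, 0))
        assert key.render() == "CD3+CD4-"
        assert key.bitstring == "10"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            PhenotypeKey(("CD3",), (1, 0))

    def test_csv_round_trip_preserves_leading_zero_bitstrings(self, tmp_path):
        binary = {"S1": np.array([[0, 0], [0, 1]])}
        table = enumerate_populations(binary, MARKERS)
        path = tmp_path / "populations.csv"
        table.to_csv(path)
        back = PopulationTable.from_csv(path, MARKERS)
        assert set(back.phenotypes) == {"00", "01"}
        assert back.denominators == {"S1": 2}
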