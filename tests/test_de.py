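import math

import numpy as np
import pandas as pd
import pytest

from neutroflux.de import (
    call_de,
    contrast_fold_changes,
    contrast_table,
    cross_contrast_regression,
    extreme_changes,
    group_medians,
    overlap_percentage,
    venn_partition,
)
from neutroflux.errors import ConfigError, IntegrityError
from neutroflux.io_formats import StudyDesign


def design_for(columns):
    mapping = {}
    for sample in columns:
        if sample.startswith("s"):
            mapping[sample] = "SHAM"
        elif sample.startswith("p"):
            mapping[sample] = "LPS_PMN"
        else:
            mapping[sample] = "LPS_NOPMN"
    return StudyDesign(mapping)


def matrix_from(rows, columns):
    return pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))],
                        columns=columns, dtype=float)


def medians_frame(a=0.0, b=0.0, sham=0.0, gene="G0"):
    return pd.DataFrame(
        {"LPS_PMN": [a], "LPS_NOPMN": [b], "SHAM": [sham]}, index=[gene]
    )


class TestGroupMedians:
    def test_outlier_robustness(self):
        columns = ["s1", "s2", "s3", "p1", "n1"]
        matrix = matrix_from([[1.0, 2.0, 100.0, 0.0, 0.0]], columns)
        medians = group_medians(matrix, design_for(columns))
        assert medians.loc["G0", "SHAM"] == 2.0

    def test_even_group_uses_central_mean(self):
        columns = ["s1", "s2", "p1", "n1"]
        matrix = matrix_from([[1.0, 3.0, 0.0, 0.0]], columns)
        medians = group_medians(matrix, design_for(columns))
        assert medians.loc["G0", "SHAM"] == 2.0

    def test_single_sample_group_identity(self):
        columns = ["s1", "p1", "n1"]
        matrix = matrix_from([[1.0, 7.5, 0.0]], columns)
        medians = group_medians(matrix, design_for(columns))
        assert medians.loc["G0", "LPS_PMN"] == 7.5

    def test_unknown_sample_rejected(self):
        columns = ["s1", "p1", "n1"]
        matrix = matrix_from([[1.0, 2.0, 3.0]], columns)
        design = design_for(["s1", "p1", "n2"])
        with pytest.raises(IntegrityError):
            group_medians(matrix, design)


class TestContrastFoldChanges:
    def test_up_two_fold(self):
        frame = contrast_fold_changes(medians_frame(a=math.log(2.0)), "A")
        row = frame.loc["G0"]
        assert math.isclose(row["fold_change"], 2.0)
        assert row["direction"] == "up"

    def test_no_change(self):
        row = contrast_fold_changes(medians_frame(), "A").loc["G0"]
        assert row["fold_change"] == 1.0
        assert row["direction"] == "none"

    def test_down_regulation_magnitude(self):
        frame = contrast_fold_changes(medians_frame(a=-math.log(2.6)), "A")
        row = frame.loc["G0"]
        assert math.isclose(row["fold_change"], 2.6)
        assert row["direction"] == "down"

    def test_antisymmetry(self, rng):
        medians = pd.DataFrame(
            rng.normal(0, 1, (20, 3)), columns=["LPS_PMN", "LPS_NOPMN", "SHAM"],
            index=[f"G{i}" for i in range(20)],
        )
        forward = contrast_fold_changes(medians, "A")
        swapped = medians.rename(columns={"LPS_PMN": "SHAM", "SHAM": "LPS_PMN"})
        backward = contrast_fold_changes(swapped, "A")
        assert np.allclose(forward["log_ratio"], -backward["log_ratio"])
        assert np.allclose(forward["fold_change"], backward["fold_change"])


class TestCallDe:
    def table_with_folds(self, folds):
        log_ratio = np.log(np.asarray(folds))
        frame = pd.DataFrame(
            {
                "log_ratio": log_ratio,
                "fold_change": np.exp(np.abs(log_ratio)),
                "direction": np.where(log_ratio > 0, "up",
                                      np.where(log_ratio < 0, "down", "none")),
            },
            index=[f"G{i}" for i in range(len(folds))],
        )
        return {"A": frame}

    def test_boundary_strict(self):
        flags, _counts = call_de(self.table_with_folds([1.50]), threshold=1.5)
        assert not flags["A"].iloc[0]

    def test_boundary_non_strict(self):
        flags, _counts = call_de(
            self.table_with_folds([1.50]), threshold=1.5, strict=False
        )
        assert flags["A"].iloc[0]

    def test_just_above_threshold(self):
        flags, _counts = call_de(self.table_with_folds([1.51]), threshold=1.5)
        assert flags["A"].iloc[0]

    def test_counts_by_direction(self):
        flags, counts = call_de(self.table_with_folds([2.0, 0.4, 1.2]), threshold=1.5)
        assert counts.loc["A", "n_de"] == 2
        assert counts.loc["A", "n_up"] == 1
        assert counts.loc["A", "n_down"] == 1

    def test_threshold_monotonicity(self, rng):
        folds = np.exp(rng.normal(0, 0.7, 200))
        table = self.table_with_folds(folds)
        previous = None
        for threshold in (1.2, 1.5, 2.0, 3.0):
            flags, _ = call_de(table, threshold=threshold)
            current = set(flags.index[flags["A"]])
            if previous is not None:
                assert current <= previous
            previous = current

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            call_de(self.table_with_folds([2.0]), threshold=0.9)


def flags_from_sets(universe, *sets):
    return tuple(
        pd.Series([g in s for g in universe], index=universe) for s in sets
    )


class TestVennPartition:
    def test_disjoint_sets(self):
        universe = [f"G{i}" for i in range(10)]
        a, b, c = {"G0"}, {"G1", "G2"}, {"G3", "G4", "G5"}
        venn = venn_partition(*flags_from_sets(universe, a, b, c))
        assert venn.union_count == 6
        assert venn.counts["AB"] == venn.counts["AC"] == venn.counts["BC"] == 0
        assert venn.counts["ABC"] == 0

    def test_identical_sets(self):
        universe = [f"G{i}" for i in range(6)]
        s = {"G0", "G1", "G2"}
        venn = venn_partition(*flags_from_sets(universe, s, s, s))
        assert venn.union_count == 3
        assert venn.counts["ABC"] == 3
        assert sum(v for k, v in venn.counts.items() if k != "ABC") == 0

    def test_counts_sum_to_union_property(self, rng):
        universe = [f"G{i}" for i in range(60)]
        sets = [set(rng.choice(universe, size=rng.integers(5, 30), replace=False))
                for _ in range(3)]
        venn = venn_partition(*flags_from_sets(universe, *sets))
        assert sum(venn.counts.values()) == venn.union_count
        assert venn.union_count == len(set().union(*sets))
        assert venn.set_size("A") == len(sets[0])
        regions = list(venn.members.values())
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                assert not (set(regions[i]) & set(regions[j]))

    def test_mismatched_universe_rejected(self):
        a = pd.Series([True], index=["G0"])
        b = pd.Series([True], index=["G1"])
        with pytest.raises(IntegrityError):
            venn_partition(a, a, b)


class TestOverlapPercentage:
    def test_printed_counts(self):
        x = {f"g{i}" for i in range(360)}
        y = {f"g{i}" for i in range(265)} | {f"h{i}" for i in range(500)}
        assert overlap_percentage(x, y) == 74

    def test_high_overlap(self):
        x = {f"g{i}" for i in range(107)}
        y = {f"g{i}" for i in range(95)}
        assert overlap_percentage(x, y) == 89

    def test_subset_is_hundred(self):
        assert overlap_percentage({"a", "b"}, {"a", "b", "c"}) == 100

    def test_half_up_rounding(self):
        # 1/8 = 12.5% rounds up to 13
        x = {f"g{i}" for i in range(8)}
        assert overlap_percentage(x, {"g0"}) == 13

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigError):
            overlap_percentage(set(), {"a"})


class TestExtremeChanges:
    def frame(self, entries):
        return pd.DataFrame(
            {
                "log_ratio": [math.copysign(math.log(f), 1 if d == "up" else -1)
                              if d != "none" else 0.0 for _g, f, d in entries],
                "fold_change": [f for _g, f, d in entries],
                "direction": [d for _g, f, d in entries],
            },
            index=[g for g, _f, _d in entries],
        )

    def test_basic_extremes(self):
        frame = self.frame(
            [("Up1", 3.0, "up"), ("Up2", 15.0, "up"), ("Dn1", 2.6, "down")]
        )
        extremes = extreme_changes(frame)
        assert extremes.up == ("Up2", 15.0)
        assert extremes.down == ("Dn1", 2.6)

    def test_lexicographic_tie_break(self):
        frame = self.frame([("Zeta", 2.0, "up"), ("Alpha", 2.0, "up")])
        assert extreme_changes(frame).up[0] == "Alpha"

    def test_all_flat_reports_absent(self):
        frame = self.frame([("G1", 1.0, "none"), ("G2", 1.0, "none")])
        extremes = extreme_changes(frame)
        assert extremes.up is None and extremes.down is None

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            extreme_changes(self.frame([]))


class TestCrossContrastRegression:
    def table(self, x, y):
        genes = [f"G{i}" for i in range(len(x))]
        make = lambda v: pd.DataFrame(
            {"log_ratio": v, "fold_change": np.exp(np.abs(v)),
             "direction": "up"}, index=genes
        )
        return {"A": make(np.asarray(x, dtype=float)),
                "B": make(np.asarray(y, dtype=float))}, genes

    def test_identical_vectors(self):
        table, genes = self.table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        r, slope = cross_contrast_regression(table, genes)
        assert math.isclose(r, 1.0) and math.isclose(slope, 1.0)

    def test_attenuated_response(self):
        x = [0.5, 1.0, 1.5, 2.0]
        table, genes = self.table(x, [0.6 * v for v in x])
        r, slope = cross_contrast_regression(table, genes)
        assert math.isclose(slope, 0.6) and math.isclose(r, 1.0)

    def test_five_point_instance_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.5])
        table, genes = self.table(x, y)
        r, slope = cross_contrast_regression(table, genes)
        # independent closed-form least squares
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        sxx = ((x - x.mean()) ** 2).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert math.isclose(slope, sxy / sxx, rel_tol=1e-12)
        assert math.isclose(r, sxy / math.sqrt(sxx * syy), rel_tol=1e-12)

    def test_zero_variance_predictor_rejected(self):
        table, genes = self.table([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ConfigError):
            cross_contrast_regression(table, genes)

    def test_too_few_genes_rejected(self):
        table, genes = self.table([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ConfigError):
            cross_contrast_regression(table, genes)


class TestContrastTableOnSimulation:
    def test_shared_genes_attenuated_in_depleted_group(self, noisefree_pipeline):
        _exp, _matrix, table = noisefree_pipeline
        flags, _counts = call_de(table, threshold=1.5)
        shared = sorted(flags.index[flags["A"] & flags["B"]])
        r, slope = cross_contrast_regression(table, shared)
        # injected shared effects are weaker without neutrophils
        assert 0 < slope < 1.0
        assert r > 0
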