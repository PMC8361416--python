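"""Aggregation, normalization and gated testing against exact oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import rbploc as R
from rbploc.stats import EXACT_MW_MAX_N, mann_whitney_exact_p, mann_whitney_u


def brute_force_mw_p(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments.

    U is computed by direct pair counting; every C(n_a+n_b, n_a) split of
    the pooled values is enumerated and the fraction with a
    min(U, n_a*n_b - U) at least as extreme as observed is returned.
    """
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    m = n_a * (n - n_a)

    def u_of(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    obs = min(u_of(a, b), m - u_of(a, b))
    hits = total = 0
    for idx in combinations(range(n), n_a):
        rest = [i for i in range(n) if i not in idx]
        u = u_of(pooled[list(idx)], pooled[rest])
        hits += min(u, m - u) <= obs
        total += 1
    return hits / total


def cells_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["line", "condition", "repeat", "well", "field", "cell",
                 "nc_ratio", "valid"],
    )


class TestAggregate:
    def test_two_fields_average_to_well(self):
        df = cells_frame(
            [
                ["l", "c", 1, "w1", "f1", 1, 1.0, True],
                ["l", "c", 1, "w1", "f2", 1, 2.0, True],
            ]
        )
        well = R.aggregate(df, "well", "nc_ratio")
        assert len(well) == 1 and well["nc_ratio"][0] == 1.5 and well["n"][0] == 2

    def test_identity_chain_single_cell(self):
        df = cells_frame([["l", "c", 1, "w1", "f1", 1, 1.7, True]])
        for level in ("field", "well", "line"):
            out = R.aggregate(df, level, "nc_ratio")
            assert out["nc_ratio"][0] == 1.7

    def test_flagged_only_field_dropped(self):
        df = cells_frame(
            [
                ["l", "c", 1, "w1", "f1", 1, 1.0, True],
                ["l", "c", 1, "w1", "f2", 1, 99.0, False],
            ]
        )
        well = R.aggregate(df, "well", "nc_ratio")
        assert well["nc_ratio"][0] == 1.0  # flagged field contributes nothing

    def test_unweighted_two_step_mean(self):
        # field means (1+3)/2=2 and 5 -> well mean 3.5, not the pooled cell mean
        df = cells_frame(
            [
                ["l", "c", 1, "w1", "f1", 1, 1.0, True],
                ["l", "c", 1, "w1", "f1", 2, 3.0, True],
                ["l", "c", 1, "w1", "f2", 1, 5.0, True],
            ]
        )
        assert R.aggregate(df, "well", "nc_ratio")["nc_ratio"][0] == 3.5

    def test_cannot_aggregate_downward(self):
        well = R.aggregate(
            cells_frame([["l", "c", 1, "w1", "f1", 1, 1.0, True]]), "well", "nc_ratio"
        )
        with pytest.raises(ValueError):
            R.aggregate(well, "field", "nc_ratio")


class TestNormalizeToControl:
    def table(self):
        return pd.DataFrame(
            {
                "condition": ["control"] * 3 + ["mutant"] * 2 + ["control"] * 2 + ["mutant"],
                "repeat": [1, 1, 1, 1, 1, 2, 2, 2],
                "value": [0.8, 1.0, 1.2, 0.9, 1.1, 100.0, 300.0, 150.0],
            }
        )

    def test_control_mean_exactly_one_per_repeat(self):
        out = R.normalize_to_control(self.table(), "value", "control")
        ctrl = out[out["condition"] == "control"]
        for _, grp in ctrl.groupby("repeat"):
            assert grp["value_norm"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_arithmetic(self):
        out = R.normalize_to_control(self.table(), "value", "control")
        mut1 = out[(out["condition"] == "mutant") & (out["repeat"] == 1)]
        assert list(mut1["value_norm"]) == [0.9, 1.1]
        mut2 = out[(out["condition"] == "mutant") & (out["repeat"] == 2)]
        assert list(mut2["value_norm"]) == [0.75]

    def test_idempotent(self):
        once = R.normalize_to_control(self.table(), "value", "control", out_col="v")
        twice = R.normalize_to_control(once, "v", "control", out_col="v2")
        np.testing.assert_allclose(twice["v2"], once["v"], rtol=1e-12)

    def test_missing_control_repeat_raises(self):
        t = self.table()
        t = t[~((t["repeat"] == 2) & (t["condition"] == "control"))]
        with pytest.raises(ValueError, match="repeat 2"):
            R.normalize_to_control(t, "value", "control")


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        # U = 0; only 2 of the C(6,3)=20 assignments are as extreme
        assert mann_whitney_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(size=5)
        assert mann_whitney_u(a, b) == pytest.approx(
            float(sps.mannwhitneyu(a, b).statistic)
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
        st.lists(st.integers(0, 6), min_size=2, max_size=6),
    )
    def test_exact_p_equals_enumeration_with_ties(self, a, b):
        a, b = np.array(a, float), np.array(b, float)
        assert mann_whitney_exact_p(a, b) == pytest.approx(
            brute_force_mw_p(a, b), abs=1e-12
        )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 7))
            b = rng.normal(size=rng.integers(3, 7))
            expected = float(
                sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
            assert mann_whitney_exact_p(a, b) == pytest.approx(expected)


class TestCompareGroups:
    def test_identical_samples_unit_p(self):
        res = R.compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_equal_samples_p_near_one(self):
        res = R.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_forced_mw_example(self):
        res = R.compare_groups([1, 2, 3], [4, 5, 6], force_mannwhitney=True)
        assert res.test_used == "mann_whitney"
        assert res.p_value == pytest.approx(0.1)

    def test_gaussian_groups_use_t_test(self):
        rng = np.random.default_rng(12)
        a = rng.normal(1.0, 0.05, size=6)
        b = rng.normal(0.85, 0.05, size=6)
        res = R.compare_groups(a, b)
        assert res.test_used == "t_test"
        # closed-form pooled two-sample t on the drawn values
        expected = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(float(expected.statistic))
        assert res.p_value == pytest.approx(float(expected.pvalue))
        assert res.p_value < 0.05 and res.stars != "ns"

    def test_small_groups_force_mann_whitney(self):
        res = R.compare_groups([1.0, 2.0], [3.0, 4.0])
        assert res.test_used == "mann_whitney"
        assert "forced" in res.notes

    def test_non_gaussian_group_routes_to_mw(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.normal(0, 1.5, size=20))  # heavy-tailed
        b = rng.normal(1.0, 0.1, size=20)
        res = R.compare_groups(a, b)
        assert res.test_used == "mann_whitney"
        assert res.normality_p_a <= 0.05

    def test_large_sample_mw_uses_tie_corrected_normal_approx(self):
        rng = np.random.default_rng(8)
        a = np.round(rng.normal(0, 1, size=15), 1)
        b = np.round(rng.normal(0.5, 1, size=14), 1)
        res = R.compare_groups(a, b, force_mannwhitney=True)
        expected = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(expected.pvalue))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            R.compare_groups([1.0], [1.0, 2.0])

    def test_stars(self):
        assert R.significance_stars(0.04) == "*"
        assert R.significance_stars(0.009) == "**"
        assert R.significance_stars(0.0005) == "***"
        assert R.significance_stars(0.2) == "ns"


@pytest.fixture(scope="module")
def experiment():
    layout = R.PlateLayout(
        {"c1": "control", "m1": "mutant"}, wells_per_line=3, fields_per_well=3,
        repeats=1,
    )
    return R.run_synthetic_experiment(
        layout, {"mutant": R.MUTANT_EFFECT}, R.sim_params(), seed=17,
        report_config=R.ReportConfig(control="control"),
    )


class TestPipelineReport:
    def test_levels_and_counts(self, experiment):
        comp = experiment["report"].comparisons.set_index("metric")
        assert comp.loc["nc_ratio", "level"] == "well"
        assert comp.loc["nu_ne_ratio", "level"] == "field"
        assert comp.loc["nc_ratio", "n_a"] == 3  # wells per group
        assert comp.loc["nu_ne_ratio", "n_b"] <= 9  # fields per group

    def test_mutant_effect_detected_with_direction(self, experiment):
        comp = experiment["report"].comparisons.set_index("metric")
        assert comp.loc["nc_ratio", "mean_b"] < comp.loc["nc_ratio", "mean_a"]
        assert comp.loc["nc_ratio", "p_value"] <= 0.05

    def test_control_normalized_to_one(self, experiment):
        comp = experiment["report"].comparisons.set_index("metric")
        assert comp.loc["nc_ratio", "mean_a"] == pytest.approx(1.0, abs=1e-12)

    def test_plotdata_contains_line_overlay(self, experiment):
        plot = experiment["report"].plotdata
        assert any(name.endswith("_line_means") for name in plot)

    def test_report_written_to_disk(self, experiment, tmp_path):
        R.write_report(experiment["report"], tmp_path)
        assert (tmp_path / "comparisons.csv").exists()
        assert (tmp_path / "comparisons.json").exists()
        assert list((tmp_path / "plotdata").glob("*.csv"))
        assert (tmp_path / "run.log").exists()

    def test_unknown_level_rejected(self, experiment):
        with pytest.raises(ValueError, match="level"):
            R.run_pipeline_report(
                experiment["cells"],
                experiment["fields"],
                R.ReportConfig(control="control", nc_level="plate"),
            )

    def test_unknown_control_rejected(self, experiment):
        with pytest.raises(ValueError, match="control"):
            R.run_pipeline_report(
                experiment["cells"],
                experiment["fields"],
                R.ReportConfig(control="untreated"),
            )
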