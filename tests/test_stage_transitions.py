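"""Differential testing, FDR control, direction calls, and arm summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xchrom import (
    ArmSummary,
    StageDesign,
    arm_contingency_summary,
    bh_adjust,
    classify_transitions,
    fisher_x_vs_a,
    magnitude_summary,
    make_expression_matrix,
    probe_t_tests,
    render_arm_summary,
    scenario_params,
    simulate_expression,
)


def _stage_matrix(stage1_rows, stage2_rows, arms=None):
    """Probes x replicates for two stages from per-probe replicate lists."""
    n = len(stage1_rows)
    probes = pd.Index([f"p{i}" for i in range(n)], name="probe_id")
    cols = {}
    for r in range(len(stage1_rows[0])):
        cols[f"premeiotic:{r + 1}"] = [row[r] for row in stage1_rows]
    for r in range(len(stage2_rows[0])):
        cols[f"meiotic:{r + 1}"] = [row[r] for row in stage2_rows]
    arms = arms or ["2L"] * n
    return make_expression_matrix(
        pd.DataFrame(cols, index=probes), pd.Series(arms, index=probes)
    )


class TestProbeTTests:
    def test_identical_vectors_are_null(self):
        m = _stage_matrix([[1.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero variance"):
            out = probe_t_tests(m, "premeiotic", "meiotic")
        assert out.loc["p0", "log2fc"] == 0.0
        assert out.loc["p0", "p"] == 1.0

    def test_matches_closed_form_welch_t(self):
        a, b = [1.0, 1.0, 1.0], [2.0, 2.1, 1.9]
        m = _stage_matrix([a], [b])
        out = probe_t_tests(m, "premeiotic", "meiotic")
        assert out.loc["p0", "log2fc"] == pytest.approx(1.0)
        assert out.loc["p0", "p"] < 0.01
        # hand Welch formula on a second, non-degenerate pair
        a, b = [1.0, 1.2, 0.8], [2.0, 2.1, 1.9]
        out = probe_t_tests(_stage_matrix([a], [b]), "premeiotic", "meiotic")
        sa2, sb2 = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 3
        t_hand = (np.mean(b) - np.mean(a)) / np.sqrt(sa2 + sb2)
        df_hand = (sa2 + sb2) ** 2 / (sa2**2 / 2 + sb2**2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert out.loc["p0", "t"] == pytest.approx(t_hand, rel=1e-12)
        assert out.loc["p0", "p"] == pytest.approx(p_hand, rel=1e-9)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(17)
        s1 = rng.normal(8, 0.5, (1000, 3)).tolist()
        s2 = rng.normal(8, 0.5, (1000, 3)).tolist()
        out = probe_t_tests(_stage_matrix(s1, s2), "premeiotic", "meiotic")
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q, flags = bh_adjust([0.01, 0.02, 0.03, 0.9], fdr=0.05)
        # step-up: p(3)=0.03 <= 0.05*3/4 -> first three rejected
        assert list(flags) == [True, True, True, False]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.9])

    def test_single_p(self):
        q, flags = bh_adjust([0.04], fdr=0.05)
        assert flags[0] and q[0] == pytest.approx(0.04)

    def test_all_unity_never_significant(self):
        _, flags = bh_adjust([1.0] * 10, fdr=0.05)
        assert not flags.any()

    def test_matches_bruteforce_step_up_oracle(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=200) ** 2
        q, flags = bh_adjust(p, fdr=0.05)
        # oracle: largest k with p_(k) <= k/m * alpha; reject those ranks
        order = np.argsort(p)
        m = len(p)
        ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= 0.05 * k / m]
        expected = np.zeros(m, bool)
        if ks:
            expected[order[: max(ks)]] = True
        np.testing.assert_array_equal(flags, expected)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestClassifyTransitions:
    def test_fold2_scheme_thresholds_on_magnitude(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 0.2, (4, 3))
        shifts = np.array([1.2, -1.2, 0.5, 0.0])
        m = make_expression_matrix(
            pd.DataFrame(
                {
                    **{f"premeiotic:{r+1}": base[:, r] for r in range(3)},
                    **{f"meiotic:{r+1}": base[:, r] + shifts for r in range(3)},
                    **{f"postmeiotic:{r+1}": base[:, r] + shifts for r in range(3)},
                },
                index=pd.Index([f"p{i}" for i in range(4)], name="probe_id"),
            ),
            pd.Series(["2L"] * 4, index=[f"p{i}" for i in range(4)]),
        )
        calls = classify_transitions(m, scheme="fold2")
        early = calls.tables["early"]["direction"]
        assert early.loc["p0"] == "up"
        assert early.loc["p1"] == "down"
        assert early.loc["p2"] == "ns"
        assert early.loc["p3"] == "ns"

    def test_stricter_fdr_calls_are_nested(self, tiny_design):
        m = simulate_expression(tiny_design, scenario_params("no_dc"), seed=6)
        loose = classify_transitions(m, scheme="fdr05")
        strict = classify_transitions(m, scheme="fdr005")
        for transition in loose.tables:
            loose_called = set(
                loose.tables[transition]
                .index[loose.tables[transition]["direction"] != "ns"]
            )
            strict_called = set(
                strict.tables[transition]
                .index[strict.tables[transition]["direction"] != "ns"]
            )
            assert strict_called <= loose_called

    def test_null_data_flags_at_most_nominal_fraction(self):
        design = StageDesign(
            genes_per_arm={"X": 300, "2L": 300, "3R": 300},
            stage_effect=((1.0, 0.0, 0.0),),
        )
        m = simulate_expression(design, scenario_params("full_dc"), seed=31)
        calls = classify_transitions(m, scheme="fdr05")
        flagged = sum(
            (t["direction"] != "ns").sum() for t in calls.tables.values()
        )
        assert flagged / (3 * 900) <= 0.05


class TestArmSummary:
    @pytest.fixture
    def calls(self, tiny_design):
        m = simulate_expression(tiny_design, scenario_params("no_dc"), seed=9)
        return classify_transitions(m, scheme="fdr05")

    def test_partition_and_aggregate_row(self, calls):
        summary = arm_contingency_summary(calls)
        counts = summary.counts
        for transition in ("early", "late", "net"):
            table = calls.tables[transition]
            for arm in ("X", "2L", "2R", "3L", "3R", "4"):
                sel = (calls.arms == arm).to_numpy()
                n_ns = (table["direction"][sel] == "ns").sum()
                assert (
                    counts.loc[arm, (transition, "down")]
                    + counts.loc[arm, (transition, "up")]
                    + n_ns
                    == counts.loc[arm, (transition, "n_expressed")]
                )
            for field in ("n_expressed", "down", "up"):
                assert counts.loc["A", (transition, field)] == sum(
                    counts.loc[arm, (transition, field)]
                    for arm in ("2L", "2R", "3L", "3R")
                )

    def test_rendering_formats_printed_style_cells(self, calls):
        summary = arm_contingency_summary(calls)
        rendered = render_arm_summary(summary)
        down = summary.counts.loc["X", ("early", "down")]
        n = summary.counts.loc["X", ("early", "n_expressed")]
        assert rendered.loc["X", "early_down"].startswith(f"{down:,} (")
        assert f"{100 * down / n:.0f}" in rendered.loc["X", "early_down"].split(".")[0]

    def test_all_ns_calls_give_zero_counts(self, small_matrix):
        calls = classify_transitions(small_matrix, scheme="fdr005")
        summary = arm_contingency_summary(calls)
        if (summary.counts.loc["A", ("early", "down")] == 0) and (
            summary.counts.loc["A", ("early", "up")] == 0
        ):
            rendered = render_arm_summary(summary)
            assert rendered.loc["2L", "early_down"].endswith("(0.0%)")


def _fisher_enumeration_oracle(table):
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities of
    tables with the observed margins that are no more probable than observed."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    k = a + c
    total = n1 + n2
    p_obs = stats.hypergeom.pmf(a, total, n1, k)
    p = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = stats.hypergeom.pmf(x, total, n1, k)
        if px <= p_obs * (1 + 1e-7):
            p += px
    return min(p, 1.0)


class TestFisherXvsA:
    def _summary(self, x_n, x_dir, a_n, a_dir):
        counts = pd.DataFrame(
            {
                ("early", "n_expressed"): {"X": x_n, "A": a_n},
                ("early", "down"): {"X": x_dir, "A": a_dir},
                ("early", "up"): {"X": 0, "A": 0},
            }
        )
        counts.columns = pd.MultiIndex.from_tuples(counts.columns)
        return ArmSummary(counts=counts)

    def test_proportional_rows_are_null(self):
        p = fisher_x_vs_a(self._summary(20, 5, 40, 10), "early", "down")
        assert p == pytest.approx(1.0)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            p = fisher_x_vs_a(self._summary(20, 0, 40, 0), "early", "down")
        assert p == 1.0

    def test_matches_enumeration_on_all_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            if max(a + b, c + d, a + c, b + d) > 8:
                continue
            p_impl = fisher_x_vs_a(
                self._summary(a + b, a, c + d, c), "early", "down"
            )
            p_oracle = _fisher_enumeration_oracle([[a, b], [c, d]])
            assert p_impl == pytest.approx(p_oracle, rel=1e-9), (a, b, c, d)


class TestMagnitudeSummary:
    def test_single_up_call_median(self):
        tables = {
            "early": pd.DataFrame(
                {
                    "log2fc": [0.84, -0.5],
                    "direction": ["up", "ns"],
                },
                index=pd.Index(["x1", "a1"], name="probe_id"),
            )
        }
        from xchrom.stage_transitions import TransitionCalls

        calls = TransitionCalls(
            tables=tables,
            arms=pd.Series(["X", "2L"], index=["x1", "a1"]),
            scheme="fdr05",
        )
        summary = magnitude_summary(calls)
        assert summary.loc["X", ("early", "up")] == pytest.approx(0.84)
        assert np.isnan(summary.loc["X", ("early", "down")])

    def test_symmetric_calls_have_zero_combined_median(self):
        from xchrom.stage_transitions import TransitionCalls

        fc = [0.8, -0.8, 1.2, -1.2]
        tables = {
            "early": pd.DataFrame(
                {"log2fc": fc, "direction": ["up", "down", "up", "down"]},
                index=pd.Index([f"p{i}" for i in range(4)], name="probe_id"),
            )
        }
        calls = TransitionCalls(
            tables=tables,
            arms=pd.Series(["2L"] * 4, index=[f"p{i}" for i in range(4)]),
            scheme="fdr05",
        )
        summary = magnitude_summary(calls)
        assert summary.loc["2L", ("early", "up_down")] == pytest.approx(0.0)

    def test_matches_bruteforce_median_over_flagged(self, tiny_design):
        m = simulate_expression(tiny_design, scenario_params("no_dc"), seed=13)
        calls = classify_transitions(m, scheme="fdr05")
        summary = magnitude_summary(calls)
        table = calls.tables["late"]
        for arm in ("X", "2R", "4"):
            sel = (calls.arms == arm).to_numpy() & (
                table["direction"] == "down"
            ).to_numpy()
            expected = (
                np.median(table["log2fc"][sel]) if sel.any() else np.nan
            )
            got = summary.loc[arm, ("late", "down")]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
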