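"""Panel statistics: detection filter, two-sample tests, BKY two-stage FDR,
BH adjustment, ratios, median-relative matrices and DE thresholds — all
against enumeration or closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

import scexhaust as sx
from scexhaust.containers import AnalytePanel
from scexhaust.stats import bky_two_stage, bh_adjust, mann_whitney_u, welch_t_test


def make_panel(values: dict, groups, floor=0.0):
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(len(groups))], dtype=float)
    return AnalytePanel(
        values=df,
        group=pd.Series(groups, index=df.index),
        detection_floor=pd.Series(floor, index=df.columns, dtype=float),
    )


class TestFilterDetected:
    def test_all_below_floor_analyte_dropped(self):
        panel = make_panel({"good": [5, 6, 7, 8], "dead": [1, 1, 1, 1]},
                           [sx.MRD_POS] * 2 + [sx.MRD_NEG] * 2, floor=1.0)
        kept = sx.filter_detected(panel, 0.5)
        assert kept.analytes == ["good"]

    def test_threshold_rule_matches_direct_computation(self):
        panel = make_panel({"a": [5, 5, 1, 1], "b": [5, 1, 1, 1], "c": [5, 5, 5, 1]},
                           [sx.MRD_POS] * 2 + [sx.MRD_NEG] * 2, floor=1.0)
        # detection fractions: a=0.5, b=0.25, c=0.75
        assert sx.filter_detected(panel, 0.5).analytes == ["a", "c"]
        assert sx.filter_detected(panel, 0.6).analytes == ["c"]

    def test_zero_threshold_keeps_all(self, cytokine_panel):
        panel, _ = cytokine_panel
        assert sx.filter_detected(panel, 0.0).analytes == panel.analytes


class TestWelchT:
    def test_identical_groups_give_t0_p1(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_hand_evaluation(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        res = welch_t_test(x, y)
        se = np.sqrt(x.var(ddof=1) / 3 + y.var(ddof=1) / 3)
        np.testing.assert_allclose(res.statistic, (x.mean() - y.mean()) / se)

    def test_antisymmetric_in_group_order(self, rng):
        x, y = rng.normal(size=6), rng.normal(1.0, size=8)
        r1, r2 = welch_t_test(x, y), welch_t_test(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_zero_variance(self):
        res = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


def mwu_enumeration_p(x, y):
    """Exact two-sided p by enumerating all group labelings (oracle)."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = rankdata(pooled)
    mean_u = n1 * (n - n1) / 2

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs_dev = abs(u_of(range(n1)) - mean_u)
    devs = [abs(u_of(ix) - mean_u) for ix in itertools.combinations(range(n), n1)]
    return np.mean([d >= obs_dev - 1e-9 for d in devs])


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_exact_enumeration(self):
        # U=0; two-sided exact p = 2/C(6,3) = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.method == "mann_whitney_exact"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(2 / 20)

    def test_shift_invariance(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        r1, r2 = mann_whitney_u(x, y), mann_whitney_u(x + 11.0, y + 11.0)
        assert r1.statistic == r2.statistic and r1.p == r2.p

    def test_exact_path_matches_enumeration_for_all_small_sizes(self, rng):
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                for rep in range(5):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    res = mann_whitney_u(x, y)
                    assert res.method == "mann_whitney_exact"
                    assert res.p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-10)

    def test_ties_fall_back_to_corrected_normal(self):
        res = mann_whitney_u([1, 1, 2, 3], [2, 2, 3, 4])
        assert res.method == "mann_whitney_normal"
        assert 0 < res.p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def bky_oracle_rejections(pvals, q):
    """Step-by-step enumeration of the two-stage procedure (oracle)."""
    m = len(pvals)
    order = np.argsort(pvals)
    q1 = q / (1 + q)

    def step_up(level):
        k = 0
        for i in range(m, 0, -1):
            if pvals[order[i - 1]] <= i * level / m:
                k = i
                break
        rej = np.zeros(m, bool)
        rej[order[:k]] = True
        return rej

    s1 = step_up(q1)
    r1 = s1.sum()
    if r1 == 0 or r1 == m:
        return s1
    return step_up(q1 * m / (m - r1))


class TestBkyTwoStage:
    def test_all_p_one_rejects_nothing(self):
        out = bky_two_stage(np.ones(10), 0.05)
        assert not out["reject"].any()
        assert (out["q_values"] == 1.0).all()

    def test_single_small_p_rejected_at_stage_one_level(self):
        out = bky_two_stage([0.001], 0.05)
        assert out["reject"][0]
        # boundary arithmetic: a single p is rejected iff p <= q/(1+q)
        assert bky_two_stage([0.05 / 1.05 + 1e-9], 0.05)["reject"][0] == False  # noqa: E712
        assert bky_two_stage([0.05 / 1.05 - 1e-9], 0.05)["reject"][0]

    def test_matches_enumeration_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 20))
            p = np.round(rng.random(m) ** rng.uniform(0.5, 3.0), 4)
            mine = bky_two_stage(p, 0.05)["reject"]
            oracle = bky_oracle_rejections(p, 0.05)
            np.testing.assert_array_equal(mine, oracle)

    def test_matches_statsmodels_two_stage(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            m = int(rng.integers(1, 15))
            p = rng.random(m)
            mine = bky_two_stage(p, 0.05)["reject"]
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(mine, ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.2]))
    def test_rejections_contain_stage_one_and_are_monotone_in_q(self, pvals, q):
        p = np.array(pvals)
        out = bky_two_stage(p, q)
        # stage-1 set at q'=q/(1+q) is contained in the final set
        from scexhaust.stats import _step_up_rejections
        s1 = _step_up_rejections(p, q / (1 + q))
        assert (out["reject"] | ~s1).all()
        # monotone: rejections at q also rejected at 2q (capped below 1)
        q2 = min(2 * q, 0.5)
        out2 = bky_two_stage(p, q2)
        assert (out2["reject"] | ~out["reject"]).all()

    def test_q_values_consistent_with_rejection_threshold(self, rng):
        p = rng.random(8) * 0.2
        out = bky_two_stage(p, 0.05)
        for i in range(8):
            qv = out["q_values"][i]
            if qv < 1.0:
                assert bky_two_stage(p, min(qv * 1.01, 0.999))["reject"][i]
                if qv > 1e-4:
                    assert not bky_two_stage(p, qv * 0.99)["reject"][i]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bky_two_stage([0.5, 1.2], 0.05)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.031]), [0.031])

    def test_hand_computed_example(self):
        # sorted p*(m/i): 0.04, 0.04, 0.04, 0.04 after monotone step-down
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_map_to_themselves(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_formula_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 20))
            p = rng.random(m)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)


class TestRatioFeature:
    def test_elementwise_values(self):
        panel = make_panel({"IL-7": [10, 0, 6], "IL-1a": [2, 4, 3]},
                           [sx.MRD_POS, sx.MRD_POS, sx.MRD_NEG])
        r = sx.ratio_feature(panel, "IL-7", "IL-1a")
        np.testing.assert_allclose(r.to_numpy(), [5.0, 0.0, 2.0])

    def test_below_floor_denominator_excluded(self):
        panel = make_panel({"IL-7": [10, 10], "IL-1a": [1, 5]},
                           [sx.MRD_POS, sx.MRD_NEG], floor=1.0)
        r = sx.ratio_feature(panel, "IL-7", "IL-1a")
        assert list(r.index) == ["S1"]

    def test_missing_analyte_rejected(self, cytokine_panel):
        panel, _ = cytokine_panel
        with pytest.raises(KeyError):
            sx.ratio_feature(panel, "IL-7", "NOPE")


class TestMedianRelativeMatrix:
    def test_log2_ratio_to_median(self):
        panel = make_panel({"a": [1, 2, 4]}, [sx.MRD_POS, sx.MRD_POS, sx.MRD_NEG])
        mat = sx.median_relative_matrix(panel)
        np.testing.assert_allclose(mat.loc["a"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_analyte_gives_zero_row(self):
        panel = make_panel({"a": [3, 3, 3, 3]}, [sx.MRD_POS] * 2 + [sx.MRD_NEG] * 2)
        assert (sx.median_relative_matrix(panel).loc["a"] == 0).all()

    def test_row_medians_zero_and_matches_entry_oracle(self, cytokine_panel):
        panel, _ = cytokine_panel
        mat = sx.median_relative_matrix(panel)
        np.testing.assert_allclose(mat.median(axis=1), 0.0, atol=1e-12)
        floored = panel.values.clip(lower=panel.detection_floor, axis=1)
        for analyte in mat.index:
            med = 2.0 ** np.median(np.log2(floored[analyte]))  # log-scale median
            for s in mat.columns:
                np.testing.assert_allclose(
                    mat.loc[analyte, s], np.log2(floored.loc[s, analyte] / med))

    def test_samples_ordered_by_group(self, cytokine_panel):
        panel, _ = cytokine_panel
        mat = sx.median_relative_matrix(panel, group_order=[sx.MRD_NEG, sx.MRD_POS])
        groups = [panel.group[s] for s in mat.columns]
        assert groups == sorted(groups, key=[sx.MRD_NEG, sx.MRD_POS].index)


class TestDETable:
    @staticmethod
    def toy_expr(rng, n_genes=12, n_per_group=4, shift_first=0.0):
        cols = [f"L{i}" for i in range(n_per_group)] + [f"C{i}" for i in range(n_per_group)]
        expr = pd.DataFrame(rng.uniform(1, 10, size=(n_genes, 2 * n_per_group)),
                            index=[f"gene{i}" for i in range(n_genes)], columns=cols)
        expr.iloc[0, :n_per_group] += shift_first
        groups = pd.Series(["leukemia"] * n_per_group + ["control"] * n_per_group, index=cols)
        return expr, groups

    def test_identical_groups_give_unit_fold_change(self):
        expr = pd.DataFrame({"L0": [2.0], "L1": [4.0], "C0": [2.0], "C1": [4.0]},
                            index=["g"])
        groups = pd.Series(["leukemia", "leukemia", "control", "control"],
                           index=expr.columns)
        row = sx.de_table(expr, groups, reference="control").iloc[0]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["log10_fc"] == pytest.approx(0.0)

    def test_tenfold_mean_shift_gives_log10_one(self):
        expr = pd.DataFrame({"L0": [19.0], "L1": [21.0], "C0": [1.5], "C1": [2.5]},
                            index=["g"])
        groups = pd.Series(["leukemia", "leukemia", "control", "control"],
                           index=expr.columns)
        row = sx.de_table(expr, groups, reference="control").iloc[0]
        assert row["log10_fc"] == pytest.approx(1.0)

    def test_matches_per_gene_loop_oracle(self, rng):
        expr, groups = self.toy_expr(rng)
        table = sx.de_table(expr, groups, reference="control").set_index("gene")
        for gene in expr.index:
            test_vals = expr.loc[gene, groups == "leukemia"].to_numpy()
            ref_vals = expr.loc[gene, groups == "control"].to_numpy()
            fc = test_vals.mean() / ref_vals.mean()
            np.testing.assert_allclose(table.loc[gene, "fold_change"], fc)
            np.testing.assert_allclose(table.loc[gene, "log10_fc"], np.log10(fc))
            np.testing.assert_allclose(table.loc[gene, "p"],
                                       welch_t_test(test_vals, ref_vals).p)
        np.testing.assert_allclose(table["q"], bh_adjust(table["p"].to_numpy()))

    def test_missing_reference_rejected(self, rng):
        expr, groups = self.toy_expr(rng)
        with pytest.raises(ValueError, match="reference"):
            sx.de_table(expr, groups, reference="nope")


class TestThresholdGeneList:
    def test_membership_matches_direct_rule(self):
        rows = pd.DataFrame({
            "gene": ["up_big", "up_ns", "down_big", "mid", "up_weak"],
            "fold_change": [4.0, 3.0, 0.2, 1.2, 2.0],
            "log10_fc": np.log10([4.0, 3.0, 0.2, 1.2, 2.0]),
            "p": [0.01, 0.5, 0.001, 0.02, 0.03],
            "q": [0.05, 0.6, 0.01, 0.3, 0.2],
        })
        lists = sx.threshold_gene_list(rows, fc_min=2.0, p_max=0.05)
        assert lists["up"] == ["up_big", "up_weak"]
        assert lists["down"] == ["down_big"]

    def test_fc_min_one_selects_all_significant(self):
        rows = pd.DataFrame({
            "gene": ["a", "b"], "fold_change": [1.01, 0.99],
            "log10_fc": np.log10([1.01, 0.99]), "p": [0.01, 0.2], "q": [0.1, 0.5],
        })
        lists = sx.threshold_gene_list(rows, fc_min=1.0, p_max=0.05)
        assert set(lists["up"]) | set(lists["down"]) == {"a"}

    def test_empty_input_gives_empty_lists(self):
        assert sx.threshold_gene_list(pd.DataFrame(), 2.0, 0.05) == {"up": [], "down": []}


class TestPanelGroupTests:
    def test_spiked_il7_detected_after_fdr(self, cytokine_panel):
        panel, effects = cytokine_panel
        table = sx.panel_group_tests(sx.filter_detected(panel), sx.MRD_POS, sx.MRD_NEG)
        row = table.set_index("analyte").loc["IL-7"]
        assert row["reject"]
        assert row["q"] < 0.05
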