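"""Median-binarization scoring, gene-group split, KM / log-rank / Cox."""

import numpy as np
import pandas as pd
import pytest

from petomics.exceptions import (
    ConfigurationError,
    MissingGenesError,
    ValidationError,
)
from petomics.scoring import (
    GeneGroupSplit,
    cox_hr,
    km_estimate,
    logrank_test,
    median_binarize,
    score_and_label,
    split_gene_groups,
)


def _two_block_normals(rng, n_samples=12):
    """Two gene blocks, correlated within and anticorrelated across."""
    f = rng.standard_normal(n_samples)
    up = pd.DataFrame(
        {f"up{i}": 9 + f + 0.2 * rng.standard_normal(n_samples) for i in range(5)}
    ).T
    dn = pd.DataFrame(
        {f"dn{i}": 5 - f + 0.2 * rng.standard_normal(n_samples) for i in range(4)}
    ).T
    expr = pd.concat([up, dn])
    expr.columns = [f"N{i}" for i in range(n_samples)]
    return expr


class TestSplitGeneGroups:
    def test_anticorrelated_blocks_recovered_exactly(self, rng):
        expr = _two_block_normals(rng)
        split = split_gene_groups(expr, list(expr.index))
        assert sorted(split.group1) == [f"up{i}" for i in range(5)]
        assert sorted(split.group2) == [f"dn{i}" for i in range(4)]

    def test_group1_is_high_in_normals(self, rng):
        expr = _two_block_normals(rng)
        split = split_gene_groups(expr, list(expr.index))
        assert expr.loc[split.group1].mean().mean() > expr.loc[split.group2].mean().mean()

    def test_sample_order_invariance(self, rng):
        expr = _two_block_normals(rng)
        shuffled = expr[list(rng.permutation(expr.columns))]
        a = split_gene_groups(expr, list(expr.index))
        b = split_gene_groups(shuffled, list(expr.index))
        assert sorted(a.group1) == sorted(b.group1)

    def test_k_equal_to_gene_count_gives_singletons(self, rng):
        expr = _two_block_normals(rng)
        genes = list(expr.index)[:4]
        split = split_gene_groups(expr, genes, k=4)
        assert len(split.group1) + len(split.group2) == 4

    def test_missing_gene_raises(self, rng):
        expr = _two_block_normals(rng)
        with pytest.raises(MissingGenesError):
            split_gene_groups(expr, ["up0", "ghost"])

    def test_constant_gene_assigned_with_warning(self, rng):
        expr = _two_block_normals(rng)
        expr.loc["flat"] = 9.0
        with pytest.warns(UserWarning):
            split = split_gene_groups(expr, list(expr.index))
        assert "flat" in split.group1 + split.group2


class TestMedianBinarize:
    def test_worked_example(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                            columns=list("abcd"))
        out = median_binarize(expr, ["g"])
        assert out.loc["g"].tolist() == [0, 0, 1, 1]

    def test_tie_rule_all_identical_gives_zeros(self):
        expr = pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc"))
        assert median_binarize(expr, ["g"]).loc["g"].sum() == 0

    def test_even_n_distinct_values_half_ones(self, rng):
        expr = pd.DataFrame(rng.permutation(10)[None, :].astype(float),
                            index=["g"], columns=[f"s{i}" for i in range(10)])
        assert median_binarize(expr, ["g"]).loc["g"].sum() == 5

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=(3, 8))
        expr = pd.DataFrame(vals, index=list("xyz"), columns=[f"s{i}" for i in range(8)])
        a = median_binarize(expr, list("xyz"))
        b = median_binarize(np.exp(expr), list("xyz"))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_genes_listed(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 4)), index=["a", "b"],
                            columns=list("wxyz"))
        with pytest.raises(MissingGenesError) as err:
            median_binarize(expr, ["a", "gone", "also_gone"])
        assert "gone" in str(err.value)


class TestScoreAndLabel:
    split = GeneGroupSplit(group1=["g1", "g2"], group2=["g3", "g4"])

    def test_all_ones_gives_high_high(self):
        binary = pd.DataFrame(1, index=["g1", "g2", "g3", "g4"], columns=["s1", "s2"])
        sc = score_and_label(binary, self.split)
        assert (sc.combined == "HighGroup1.HighGroup2").all()

    def test_exact_half_score_is_low(self):
        binary = pd.DataFrame(
            {"s": [1, 0, 1, 1]}, index=["g1", "g2", "g3", "g4"]
        )
        sc = score_and_label(binary, self.split)
        assert sc.scores.loc["s", "Group1"] == 0.5
        assert sc.labels.loc["s", "Group1"] == "Low"
        assert sc.labels.loc["s", "Group2"] == "High"

    def test_hand_computed_worked_table(self):
        # 4 genes, 2 groups, 3 samples; indicators chosen by hand:
        #   sample a: G1 scores (1,1)->1.0 High ; G2 (0,0)->0.0 Low
        #   sample b: G1 (1,0)->0.5 Low ; G2 (1,1)->1.0 High
        #   sample c: G1 (0,0)->0.0 Low ; G2 (1,0)->0.5 Low
        binary = pd.DataFrame(
            {"a": [1, 1, 0, 0], "b": [1, 0, 1, 1], "c": [0, 0, 1, 0]},
            index=["g1", "g2", "g3", "g4"],
        )
        sc = score_and_label(binary, self.split)
        assert sc.combined.tolist() == [
            "HighGroup1.LowGroup2",
            "LowGroup1.HighGroup2",
            "LowGroup1.LowGroup2",
        ]

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            score_and_label(
                pd.DataFrame(1, index=["g1"], columns=["s"]),
                GeneGroupSplit(group1=["g1"], group2=[]),
            )


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]})
        km = km_estimate(surv)
        assert (km["survival"] == 1.0).all()

    def test_hand_computed_product_limit(self):
        surv = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        km = km_estimate(surv).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(2 / 3)
        assert km.loc[2.0] == pytest.approx(1 / 3)
        assert km.loc[3.0] == pytest.approx(0.0)

    def test_censor_before_first_event_leaves_curve_unchanged(self):
        # a subject censored before the first event never enters a risk set
        a = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        b = pd.DataFrame({"time": [0.5, 1.0, 2.0, 3.0], "event": [0, 1, 1, 1]})
        ka = km_estimate(a).set_index("time")["survival"]
        kb = km_estimate(b).set_index("time")["survival"]
        for t in (1.0, 2.0, 3.0):
            assert ka.loc[t] == pytest.approx(kb.loc[t])

    def test_trailing_censor_adds_no_step(self):
        # censoring after the last event adds no new drop in the curve
        b = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 0]})
        kb = km_estimate(b).set_index("time")["survival"]
        assert kb.loc[4.0] == pytest.approx(kb.loc[3.0])

    def test_negative_times_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate(pd.DataFrame({"time": [-1.0], "event": [1]}))

    def test_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, size=50)
        km = km_estimate(pd.DataFrame({"time": t, "event": 1}))
        ecdf_surv = 1 - np.searchsorted(np.sort(t), km["time"], side="right") / 50
        np.testing.assert_allclose(km["survival"], ecdf_surv, atol=1e-12)


def _hand_logrank(times_a, events_a, times_b, events_b):
    """Direct O-E / hypergeometric-variance computation for two groups."""
    t = np.concatenate([times_a, times_b])
    e = np.concatenate([events_a, events_b])
    g = np.array([0] * len(times_a) + [1] * len(times_b))
    o_minus_e, var = 0.0, 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = ((t == ti) & (e == 1)).sum()
        d1 = ((t == ti) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_strata_give_null_statistic(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2, 3, 1, 2, 3], "event": [1] * 6,
             "stratum": ["a"] * 3 + ["b"] * 3}
        )
        chi2, p = logrank_test(surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        ta, ea = np.array([1.0, 4.0, 6.0]), np.array([1, 1, 1])
        tb, eb = np.array([2.0, 3.0, 5.0]), np.array([1, 0, 1])
        surv = pd.DataFrame(
            {"time": np.concatenate([ta, tb]), "event": np.concatenate([ea, eb]),
             "stratum": ["a"] * 3 + ["b"] * 3}
        )
        chi2, _ = logrank_test(surv)
        assert chi2 == pytest.approx(_hand_logrank(ta, ea, tb, eb), rel=1e-9)

    def test_label_swap_invariance(self, rng):
        surv = pd.DataFrame(
            {"time": rng.exponential(5, 30), "event": rng.integers(0, 2, 30),
             "stratum": ["a", "b"] * 15}
        )
        chi2_a, _ = logrank_test(surv)
        swapped = surv.assign(stratum=surv["stratum"].map({"a": "b", "b": "a"}))
        chi2_b, _ = logrank_test(swapped)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)


class TestCox:
    def test_null_duplicated_data_gives_hr_near_one(self, rng):
        t = rng.exponential(10, 500)
        e = (rng.random(500) < 0.8).astype(int)
        surv = pd.DataFrame(
            {"time": np.concatenate([t, t]), "event": np.concatenate([e, e]),
             "stratum": rng.permutation(["a"] * 500 + ["b"] * 500)}
        )
        comp = cox_hr(surv)
        assert 0.8 <= comp.hazard_ratio <= 1.25

    def test_reference_swap_inverts_hazard_ratio(self, rng):
        surv = pd.DataFrame(
            {"time": rng.exponential(5, 80), "event": 1,
             "stratum": ["a", "b"] * 40}
        )
        fwd = cox_hr(surv, reference="a")
        rev = cox_hr(surv, reference="b")
        assert fwd.hazard_ratio == pytest.approx(1 / rev.hazard_ratio, rel=1e-6)
        assert fwd.ci95_low == pytest.approx(1 / rev.ci95_high, rel=1e-6)

    def test_ci_brackets_estimate(self, rng):
        surv = pd.DataFrame(
            {"time": rng.exponential(5, 60), "event": 1, "stratum": ["a", "b"] * 30}
        )
        comp = cox_hr(surv)
        assert comp.ci95_low <= comp.hazard_ratio <= comp.ci95_high

    def test_zero_event_stratum_flags_unbounded_ci(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2, 3, 4, 5, 6], "event": [1, 1, 1, 0, 0, 0],
             "stratum": ["a"] * 3 + ["b"] * 3}
        )
        with pytest.warns(UserWarning):
            comp = cox_hr(surv)
        assert comp.unbounded_ci
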