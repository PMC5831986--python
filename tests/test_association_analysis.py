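"""Spearman correlations, exclusion rules, stratification, group comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from defensin_cnv import association_analysis as aa


# ---------------------------------------------------------------- oracles

def rank_then_pearson(x, y):
    """Mid-rank transform followed by the explicit Pearson formula."""
    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def exact_perm_p_oracle(x, y):
    """Full n! enumeration of |rho| tail probability (tie-free inputs)."""
    x = list(x)
    n = len(x)
    r_obs = rank_then_pearson(x, y)
    count = total = 0
    for perm in itertools.permutations(y):
        if abs(rank_then_pearson(x, perm)) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------- spearman

class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [10, 20, 30, 40], 1.0),
            ([1, 2, 3, 4], [40, 30, 20, 10], -1.0),
        ],
    )
    def test_perfect_monotone(self, x, y, expected):
        res = aa.spearman(x, y)
        assert res.rho == pytest.approx(expected)

    def test_frozen_enumeration_case(self):
        res = aa.spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8, abs=1e-12)
        assert res.p_value == pytest.approx(16 / 120, abs=1e-12)
        assert res.method == "exact_permutation"

    def test_exact_p_matches_full_enumeration(self, rng):
        for n in (4, 5, 6, 7):
            x = rng.permutation(n) + 1.0
            y = rng.permutation(n) + 1.0
            res = aa.spearman(x, y)
            assert res.p_value == pytest.approx(exact_perm_p_oracle(x, y),
                                                abs=1e-12)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            x = rng.integers(1, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            res = aa.spearman(x, y)
            if res is None or math.isnan(res.rho):
                continue
            assert res.rho == pytest.approx(rank_then_pearson(x, y), abs=1e-12)
            # independent library implementation agrees
            assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic,
                                            abs=1e-12)

    def test_t_approximation_p_matches_scipy(self, rng):
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = aa.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pairwise_complete_and_min_n(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [1.0, np.nan, 3.0, 4.0]
        res = aa.spearman(x, y)
        assert res is None  # only 2 complete pairs
        assert aa.spearman([1, 1, 1], [1, 2, 3]).method == "CONSTANT_INPUT"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=-1000, max_value=1000), min_size=5,
                    max_size=20, unique=True))
    def test_invariance_and_antisymmetry(self, x):
        # integer-valued inputs keep exp(v/50) strictly increasing in floats
        x = [float(v) for v in x]
        rng = np.random.default_rng(7)
        y = list(rng.normal(size=len(x)))
        base = aa.spearman(x, y)
        # strictly increasing transform of x leaves rho unchanged
        transformed = aa.spearman([math.exp(v / 50) for v in x], y)
        assert transformed.rho == pytest.approx(base.rho, abs=1e-12)
        # reversing the order of y flips the sign
        flipped = aa.spearman(x, [-v for v in y])
        assert flipped.rho == pytest.approx(-base.rho, abs=1e-12)

    def test_exact_vs_t_approx_sanity_envelope(self, rng):
        diffs = []
        for _ in range(100):
            n = int(rng.integers(5, 8))
            x = rng.permutation(n) + 1.0
            y = rng.permutation(n) + 1.0
            res = aa.spearman(x, y)
            res_t = aa.spearman(x, y, exact_n_max=0)
            diffs.append(abs(res.p_value - res_t.p_value))
        assert np.mean(diffs) < 0.05


# ---------------------------------------------------------- pairwise matrix

def _toy_cohort(n=40, seed=3):
    rng = np.random.default_rng(seed)
    cn = rng.integers(1, 9, size=n).astype(float)
    hbd2 = np.exp(0.3 * cn + rng.normal(size=n))
    kill = np.exp(0.8 * np.log(hbd2) + rng.normal(size=n))
    ga = rng.uniform(61, 192, size=n)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "weighted_mean_cn": cn,
            "hbd2_norm_pg_per_ug": hbd2,
            "kill_per_protein": kill,
            "gestational_age_days": ga,
        }
    )


class TestPairwiseMatrix:
    def test_emits_all_pairs(self):
        df = _toy_cohort()
        results, scatter = aa.pairwise_matrix(
            df, ["weighted_mean_cn", "hbd2_norm_pg_per_ug",
                 "kill_per_protein", "gestational_age_days"]
        )
        assert len(results) == 6  # C(4,2)
        assert len(scatter) == 6

    def test_all_missing_variable_not_emitted(self):
        df = _toy_cohort()
        df["empty"] = np.nan
        results, _ = aa.pairwise_matrix(df, ["weighted_mean_cn", "empty"])
        assert results == []

    def test_unknown_variable_is_config_error(self):
        with pytest.raises(KeyError, match="nope"):
            aa.pairwise_matrix(_toy_cohort(), ["weighted_mean_cn", "nope"])

    def test_generating_structure_signs_recovered(self):
        df = _toy_cohort(n=150)
        results, _ = aa.pairwise_matrix(
            df, ["weighted_mean_cn", "hbd2_norm_pg_per_ug", "kill_per_protein"]
        )
        by_pair = {(r.var_x, r.var_y): r.rho for r in results}
        assert by_pair[("weighted_mean_cn", "hbd2_norm_pg_per_ug")] > 0
        assert by_pair[("hbd2_norm_pg_per_ug", "kill_per_protein")] > 0


# ------------------------------------------------------------- exclusions

def _flagged_cohort():
    """One record per flag combination of interest."""
    rows = [
        # sample, outcome, pre_prog, cerclage, post_prog
        ("KEEP", "term", False, False, False),
        ("PRE", "term", True, False, False),
        ("CERC", "term", False, True, False),
        ("POST", "term", False, False, True),
        ("MISC", "miscarriage", False, False, False),
        ("TERMN", "termination", False, False, False),
        ("BOTH", "term", True, True, False),
        ("PTB", "preterm", False, False, False),
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "outcome", "pre_sampling_progesterone",
                 "post_sampling_cerclage", "post_sampling_progesterone"],
    )


class TestApplyExclusions:
    def test_rule_membership(self):
        res = aa.apply_exclusions(_flagged_cohort())
        all_ids = set(res.all_comers["sample_id"])
        out_ids = set(res.outcome_set["sample_id"])
        # pre-sampling progesterone: excluded everywhere
        assert "PRE" not in all_ids and "BOTH" not in all_ids
        # post-sampling treatment and pregnancy loss: only the outcome set
        assert {"CERC", "POST", "MISC", "TERMN"} <= all_ids
        assert {"CERC", "POST", "MISC", "TERMN"} & out_ids == set()
        # unflagged records kept in both
        assert {"KEEP", "PTB"} <= out_ids

    def test_audit_arithmetic(self):
        cohort = _flagged_cohort()
        res = aa.apply_exclusions(cohort)
        n_pre = cohort["pre_sampling_progesterone"].sum()
        assert len(res.all_comers) + n_pre == len(cohort)
        assert set(res.outcome_set["sample_id"]) <= set(
            res.all_comers["sample_id"]
        )
        audit_pre = res.audit[res.audit["rule"] == "pre_sampling_progesterone"]
        assert set(audit_pre["sample_id"]) == {"PRE", "BOTH"}

    def test_missing_flag_column_rejected(self):
        with pytest.raises(KeyError):
            aa.apply_exclusions(_flagged_cohort().drop(
                columns=["post_sampling_cerclage"]))


class TestStratifiedCorrelations:
    def test_strata_counts_and_underpowered(self):
        df = _toy_cohort(n=40)
        df["outcome"] = ["term"] * 36 + ["preterm"] * 4
        variables = ["weighted_mean_cn", "hbd2_norm_pg_per_ug",
                     "kill_per_protein"]
        results, _ = aa.stratified_correlations(df, variables)
        assert len(results) == 6  # 3 pairs x 2 strata
        preterm = [r for r in results if r.stratum == "preterm"]
        assert all("UNDERPOWERED" in r.method_note for r in preterm)

    def test_tiny_stratum_gets_note_not_rho(self):
        df = _toy_cohort(n=20)
        df["outcome"] = ["term"] * 18 + ["preterm"] * 2
        results, _ = aa.stratified_correlations(
            df, ["weighted_mean_cn", "hbd2_norm_pg_per_ug"]
        )
        preterm = [r for r in results if r.stratum == "preterm"]
        assert len(preterm) == 1
        assert math.isnan(preterm[0].rho)
        assert "UNDERPOWERED" in preterm[0].method_note

    def test_coupled_pair_positive_in_small_stratum(self):
        df = _toy_cohort(n=60, seed=9)
        df["outcome"] = ["term"] * 46 + ["preterm"] * 14
        results, _ = aa.stratified_correlations(
            df, ["hbd2_norm_pg_per_ug", "kill_per_protein"]
        )
        preterm = [r for r in results if r.stratum == "preterm"][0]
        assert preterm.rho > 0


# ---------------------------------------------------------- group compare

class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p, method = aa.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        assert method == "exact_enumeration"

    def test_separated_groups_frozen_enumeration(self):
        u, p, method = aa.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == pytest.approx(0.0)
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 assignments
        assert method == "exact_enumeration"

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            u, p, _ = aa.mann_whitney(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact")
            assert u == pytest.approx(float(ref.statistic))
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_groups_use_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(0.3, 1, size=50)
        _, p, method = aa.mann_whitney(a, b)
        assert method == "normal_approx_tie_corrected"
        assert 0 < p <= 1

    def test_compare_groups_empty_group(self):
        df = _toy_cohort()
        df["outcome"] = "term"
        assert aa.compare_groups(df, "weighted_mean_cn") is None

    def test_compare_groups_reports_medians(self):
        df = _toy_cohort()
        df["outcome"] = ["term"] * 30 + ["preterm"] * 10
        res = aa.compare_groups(df, "weighted_mean_cn")
        assert res.n_a == 30 and res.n_b == 10
        assert res.median_a == np.median(
            df.loc[df.outcome == "term", "weighted_mean_cn"]
        )
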