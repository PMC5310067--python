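"""Logit transform, repeatability, test selection, Fisher per-CpG tests,
co-methylation networks and genotype association."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from methylpanel.stats import (
    StatsError,
    compare_groups,
    comethylation_network,
    estimate_repeatability,
    genotype_association,
    logit_array,
    logit_transform,
    per_cpg_fisher,
)


# ---------------------------------------------------------------------------
# independent oracle: two-sided Fisher p by exact hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(a, b, c, d):
    """Sum P(k) over all tables with the observed margins whose point
    probability does not exceed the observed one (integer arithmetic)."""
    r1, r2, c1 = a + b, c + d, a + c
    obs = comb(r1, a) * comb(r2, c1 - a)
    num = 0
    den = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        den += w
        if w <= obs:
            num += w
    return num / den


class TestLogit:
    def test_midpoint_is_zero(self):
        assert logit_transform(0.5).value == 0.0

    def test_ln19_at_95_percent(self):
        assert logit_transform(0.95).value == pytest.approx(math.log(19), abs=1e-4)
        assert logit_transform(0.95).value == pytest.approx(2.9444, abs=1e-4)

    def test_zero_clamped_at_half_min_observable(self):
        lv = logit_transform(0.0, n=100)
        assert lv.clamped
        assert lv.value == pytest.approx(math.log(0.005 / 0.995), abs=1e-4)

    def test_roundtrip_unclamped(self):
        for p in (0.01, 0.3, 0.5, 0.77, 0.99):
            x = logit_transform(p).value
            assert 1 / (1 + math.exp(-x)) == pytest.approx(p, abs=1e-12)

    def test_strictly_increasing(self):
        ps = np.linspace(0.001, 0.999, 200)
        assert np.all(np.diff(logit_array(ps)) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            logit_transform(1.2)

    def test_variance_homogenization(self, rng):
        # the raw proportion's variance peaks at p = 0.5; after the logit
        # transform the mid-range excess over the edges is removed
        n = 200
        var_p, var_l = {}, {}
        for p in (0.2, 0.5, 0.8):
            phat = rng.binomial(n, p, size=4000) / n
            var_p[p] = np.var(phat)
            var_l[p] = np.var(logit_array(phat, eps=1 / (2 * n)))
        assert var_p[0.5] > var_p[0.2] and var_p[0.5] > var_p[0.8]
        assert var_l[0.5] / var_l[0.2] < var_p[0.5] / var_p[0.2]
        assert var_l[0.5] / var_l[0.8] < var_p[0.5] / var_p[0.8]


class TestRepeatability:
    def test_identical_pairs_give_zero(self):
        est = estimate_repeatability(np.column_stack([np.arange(5.0)] * 2))
        assert est.sd == 0.0 and est.df == 5

    def test_constant_difference_closed_form(self):
        d = 0.6
        x = np.arange(10.0)
        est = estimate_repeatability(np.column_stack([x, x + d]))
        assert est.sd == pytest.approx(d / math.sqrt(2))

    def test_missing_pairs_excluded_and_counted(self):
        pairs = np.array([[1.0, 1.2], [np.nan, 0.5], [2.0, 2.0]])
        est = estimate_repeatability(pairs)
        assert est.df == 2 and est.n_missing == 1 and est.n_pairs == 3

    def test_no_complete_pairs_rejected(self):
        with pytest.raises(StatsError):
            estimate_repeatability(np.array([[np.nan, 1.0]]))

    def test_chi_square_sampling_accuracy(self, rng):
        # 112 duplicate pairs, true within-pair SD sigma: the estimate is
        # within 20% of sigma in >= 95% of runs (chi-square oracle: the
        # relative SE is ~1/sqrt(2k) ~ 0.067, 20% is ~3 SE)
        sigma = 0.44
        hits = 0
        runs = 300
        for _ in range(runs):
            base = rng.normal(size=112)
            pairs = base[:, None] + rng.normal(0, sigma, size=(112, 2))
            est = estimate_repeatability(pairs)
            hits += abs(est.sd - sigma) / sigma < 0.20
        assert hits / runs >= 0.95


class TestCompareGroups:
    def test_identical_groups_p_near_one(self):
        x = np.ones(10)
        c = compare_groups({"a": x, "b": x.copy()})
        assert c.test == "wilcoxon" and c.pvalue > 0.99

    def test_clear_gaussian_shift_uses_student(self, rng):
        a = rng.normal(0, 1, size=20)
        b = rng.normal(3, 1, size=20)
        c = compare_groups({"a": a, "b": b})
        assert c.test == "student" and c.pvalue < 1e-3

    def test_unequal_variances_use_welch(self, rng):
        a = rng.normal(0, 1, size=60)
        b = rng.normal(0, 6, size=60)
        c = compare_groups({"a": a, "b": b})
        assert c.test == "welch"

    def test_heavy_tailed_four_groups_prefer_kruskal(self, rng):
        chosen = []
        for _ in range(200):
            groups = {g: rng.standard_t(1, size=15) for g in "abcd"}
            chosen.append(compare_groups(groups).test)
        assert chosen.count("kruskal-wallis") > len(chosen) / 2

    def test_gaussian_four_groups_mostly_use_anova(self, rng):
        # Shapiro at alpha 0.05 per group falsely trips ~18% of 4-group
        # cohorts; ANOVA must still be the majority choice under normality
        chosen = [
            compare_groups({g: rng.normal(0, 1, size=25) for g in "abcd"}).test
            for _ in range(100)
        ]
        assert chosen.count("anova") > 60

    def test_tiny_group_rejected_with_name(self):
        with pytest.raises(StatsError, match="b"):
            compare_groups({"a": np.arange(5.0), "b": np.array([1.0])})

    def test_diagnostics_recorded(self, rng):
        c = compare_groups({"a": rng.normal(size=10), "b": rng.normal(size=12)})
        assert set(c.normality_p) == {"a", "b"}
        assert np.isfinite(c.levene_p)
        assert c.n == {"a": 10, "b": 12}


class TestPerCpgFisher:
    def _frame(self, tables):
        return pd.DataFrame(
            [
                {"gene": "G", "site": i + 1, "meth_case": a, "unmeth_case": b,
                 "meth_control": c, "unmeth_control": d}
                for i, (a, b, c, d) in enumerate(tables)
            ]
        )

    def test_extreme_table_exact_p(self):
        res = per_cpg_fisher(self._frame([(10, 0, 0, 10)]))
        assert res.iloc[0]["p"] == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert res.iloc[0]["direction"] == "+"

    def test_balanced_table_p_one(self):
        res = per_cpg_fisher(self._frame([(5, 5, 5, 5)]))
        assert res.iloc[0]["p"] == 1.0 and res.iloc[0]["direction"] == ""

    def test_empty_table_flagged(self):
        res = per_cpg_fisher(self._frame([(0, 0, 0, 0)]))
        assert res.iloc[0]["p"] == 1.0 and res.iloc[0]["empty_table"]

    def test_direction_sign_convention(self):
        res = per_cpg_fisher(self._frame([(1, 9, 9, 1)]))
        assert res.iloc[0]["direction"] == "-"  # hypomethylated in cases

    def test_matches_hypergeometric_enumeration(self, rng):
        # exhaustive on small margins plus random tables with margins <= 30
        tables = [
            (a, r1 - a, c, r2 - c)
            for r1 in range(0, 9) for r2 in range(0, 9)
            for a in range(r1 + 1) for c in range(r2 + 1)
        ]
        tables += [tuple(rng.integers(0, 16, size=4)) for _ in range(300)]
        res = per_cpg_fisher(self._frame(tables))
        for (a, b, c, d), p in zip(tables, res["p"]):
            if a + b + c + d == 0:
                continue
            assert p == pytest.approx(
                fisher_two_sided_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
            )

    def test_bonferroni_q_and_family_size(self):
        tables = [(10, 0, 0, 10)] * 4
        res = per_cpg_fisher(self._frame(tables), fwer=0.05)
        p = res.iloc[0]["p"]
        assert np.allclose(res["q"], min(1.0, 4 * p))
        assert res["significant"].all() == (p <= 0.05 / 4)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=2, max_size=60),
           st.integers(min_value=1, max_value=59))
    def test_bonferroni_monotone_under_test_removal(self, pvals, n_drop):
        # removing tests never turns a significant one non-significant
        fwer = 0.05
        m = len(pvals)
        keep = pvals[: max(1, m - n_drop)]
        for p in keep:
            if p <= fwer / m:
                assert p <= fwer / len(keep)


class TestNetwork:
    def test_duplicated_variable_gives_perfect_edge(self, rng):
        x = rng.normal(size=30)
        wide = pd.DataFrame({"b-G1": x, "b-G1copy": x, "b-G2": rng.normal(size=30)})
        edges = comethylation_network(wide, "CF")
        e = edges.set_index(["var1", "var2"]).loc[("b-G1", "b-G1copy")]
        assert e["r"] == pytest.approx(1.0) and bool(e["significant"])
        # no self-edges by construction
        assert not ((edges["var1"] == edges["var2"]).any())

    def test_constant_variable_skipped(self, rng):
        wide = pd.DataFrame({"b-G1": np.ones(20), "b-G2": rng.normal(size=20)})
        edges = comethylation_network(wide, "control")
        assert not edges["tested"].any()

    def test_min_pairs_enforced(self, rng):
        x = rng.normal(size=10)
        wide = pd.DataFrame({"n-G1": x, "n-G2": x * 2})
        wide.iloc[:7, 0] = np.nan  # only 3 complete pairs
        edges = comethylation_network(wide, "CF", min_pairs=5)
        assert not edges["tested"].any()

    def test_inter_tissue_flag(self, rng):
        wide = pd.DataFrame(
            {"b-G1": rng.normal(size=12), "n-G1": rng.normal(size=12),
             "n-G2": rng.normal(size=12)}
        )
        edges = comethylation_network(wide, "CF").set_index(["var1", "var2"])
        assert bool(edges.loc[("b-G1", "n-G1")]["inter_tissue"])
        assert not bool(edges.loc[("n-G1", "n-G2")]["inter_tissue"])


class TestGenotypeAssociation:
    def test_perfect_monotone_decrease(self):
        r, p, n = genotype_association([0.3, 0.2, 0.1], [0, 1, 2])
        assert r == pytest.approx(-1.0) and n == 3

    def test_monomorphic_dosage_undefined(self):
        r, p, n = genotype_association([0.3, 0.2, 0.1, 0.4], [1, 1, 1, 1])
        assert math.isnan(r)

    def test_missing_values_dropped(self):
        r, p, n = genotype_association(
            [0.3, np.nan, 0.1, 0.2, 0.2], [0, 1, 2, np.nan, 1]
        )
        assert n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError):
            genotype_association([0.3, np.nan], [0, 1])

    def test_permutation_null_calibration(self, rng):
        # |r| exceeds the alpha = 0.05 critical value in ~5% of permutations
        meth = rng.normal(size=40)
        dosage = rng.binomial(2, 0.3, size=40)
        rejections = 0
        runs = 1000
        for _ in range(runs):
            r, p, _ = genotype_association(meth, rng.permutation(dosage))
            rejections += p < 0.05
        assert 0.03 <= rejections / runs <= 0.07
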