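"""Bias metrics and rank statistics, with independent enumeration oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrobench.bias_eval import (
    UndefinedStatisticError,
    assign_age_group,
    build_report,
    family_recovery,
    fold_change_class,
    mann_whitney_u,
    percent_error,
    spearman_rho,
)
from retrobench.quantify import CountTable


class TestPercentError:
    @pytest.mark.parametrize(
        "assigned,mapped,expected",
        [(131, 131, 0.0), (1000, 900, 10.0), (100, 229, 129.0)],
    )
    def test_formula(self, assigned, mapped, expected):
        assert percent_error(assigned, mapped) == pytest.approx(expected)

    def test_zero_denominator_flagged(self):
        with pytest.raises(UndefinedStatisticError):
            percent_error(0, 5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        assigned=st.integers(min_value=1, max_value=10**6),
        mapped=st.integers(min_value=0, max_value=10**6),
    )
    def test_nonnegative_and_zero_iff_equal(self, assigned, mapped):
        pe = percent_error(assigned, mapped)
        assert pe >= 0
        assert (pe == 0) == (assigned == mapped)


class TestFoldChangeClass:
    @pytest.mark.parametrize(
        "assigned,mapped,fold,cls",
        [
            (100, 229, 2.29, "up"),
            (100, 56, 0.56, "down"),
            (100, 100, 1.0, "unchanged"),
            (100, 110, 1.1, "unchanged"),  # boundary inclusive
            (100, 90, 0.9, "unchanged"),
        ],
    )
    def test_thresholds(self, assigned, mapped, fold, cls):
        f, c = fold_change_class(assigned, mapped)
        assert f == pytest.approx(fold)
        assert c == cls

    def test_undercount_consistency_with_percent_error(self):
        # fold < 0.9 <=> percent error > 10 when undercounting
        for mapped in range(0, 101):
            f, c = fold_change_class(100, mapped)
            pe = percent_error(100, mapped)
            if mapped < 100:
                assert (c == "down") == (pe > 10)


class TestFamilyRecovery:
    @pytest.mark.parametrize(
        "total,simulated,expected",
        [(4000, 4000, 100.0), (2173, 10_000, 21.73), (5523, 10_000, 55.23)],
    )
    def test_arithmetic(self, total, simulated, expected):
        assert family_recovery(total, simulated) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedStatisticError):
            family_recovery(1, 0)


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,group",
        [
            (9.38, "young"),
            (9.999, "young"),
            (10.0, "intermediate"),
            (15.0, "intermediate"),
            (20.0, "intermediate"),
            (20.03, "old"),
            (53.79, "old"),
        ],
    )
    def test_cutpoints(self, age, group):
        assert assign_age_group(age) == group

    def test_nonpositive_age(self):
        with pytest.raises(UndefinedStatisticError):
            assign_age_group(0.0)


def _mwu_enumeration(a, b):
    """Exact two-tailed Mann-Whitney p by enumerating all rank arrangements."""
    a, b = list(a), list(b)
    pooled = a + b
    n1, n2 = len(a), len(b)

    def u_of(group_a):
        u = 0.0
        group_b = list(pooled)
        for x in group_a:
            group_b.remove(x)
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_of(a)
    us = [u_of(list(comb)) for comb in itertools.combinations(pooled, n1)]
    us = np.array(us)
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        _, p = mann_whitney_u(x, x)
        assert p >= 0.99

    def test_fully_separated_extreme_u(self):
        a = list(range(10))
        b = list(range(100, 110))
        u, p = mann_whitney_u(a, b)
        assert u in (0.0, 100.0)
        u2, _ = mann_whitney_u(b, a)
        assert {u, u2} == {0.0, 100.0}

    def test_exact_p_matches_full_enumeration_6v6(self):
        a = [1.2, 3.4, 0.1, 7.7, 2.2, 5.0]
        b = [2.9, 8.1, 6.6, 4.4, 9.0, 10.5]
        u, p = mann_whitney_u(a, b)
        u_ref, p_ref = _mwu_enumeration(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_empty_sample_error(self):
        with pytest.raises(UndefinedStatisticError):
            mann_whitney_u([], [1.0])


def _spearman_brute(x, y):
    """Pearson correlation of tie-averaged ranks, computed from scratch."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        pos = 1.0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (pos + pos + (j - i)) / 2.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            pos += j - i + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 5, 8]
        y = [10, 20, 21, 40, 41]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, y[::-1])
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_ranks(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(_spearman_brute(x, y), rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_errors(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 2, 3], [4, 5])


class _Locus:
    def __init__(self, locus_id, age_my, age_group, element_class, simulated=True):
        self.locus_id = locus_id
        self.age_my = age_my
        self.age_group = age_group
        self.element_class = element_class
        self.simulated = simulated


def _toy_loci():
    return [
        _Locus("a1", 5.0, "young", "solo_ltr"),
        _Locus("a2", 15.0, "intermediate", "provirus"),
        _Locus("a3", 30.0, "old", "solo_ltr"),
        _Locus("a2_dup", 15.0, "intermediate", "provirus", simulated=False),
    ]


class TestBuildReport:
    def test_perfect_quantification_all_zero(self):
        truth = {"a1": 100, "a2": 200, "a3": 50}
        tables = [
            CountTable("naive", dict(truth), 0, 350),
            CountTable("em", dict(truth), 0, 350),
            CountTable("family", {"FAMILY": 350}, 0, 350),
        ]
        report = build_report(truth, tables, _toy_loci())
        df = report.method_rows("naive")
        assert (df["percent_error"] == 0).all()
        assert report.summary["naive"]["n_up"] == 0
        assert report.summary["naive"]["n_down"] == 0
        assert report.summary["family"]["recovery_percent"] == 100.0

    def test_summary_median(self):
        truth = {"a1": 100, "a2": 100, "a3": 100}
        tables = [CountTable("naive", {"a1": 100, "a2": 90, "a3": 80}, 30, 300)]
        report = build_report(truth, tables, _toy_loci())
        assert report.summary["naive"]["median_percent_error"] == 10.0
        assert report.summary["naive"]["n_down"] == 1

    def test_conservation_check_raises_on_mismatch(self):
        truth = {"a1": 100, "a2": 200, "a3": 50}
        bad = CountTable("naive", {"a1": 100}, 0, 100)
        with pytest.raises(ValueError):
            build_report(truth, [bad], _toy_loci())

    def test_unsimulated_twin_row_flagged_not_dropped(self):
        truth = {"a1": 100, "a2": 200, "a3": 50}
        counts = {"a1": 100, "a2": 150, "a3": 50, "a2_dup": 50}
        report = build_report(truth, [CountTable("naive", counts, 0, 350)], _toy_loci())
        twin = report.per_locus[report.per_locus["locus_id"] == "a2_dup"]
        assert len(twin) == 1
        assert bool(twin["flagged"].iloc[0])
        assert np.isnan(twin["percent_error"].iloc[0])
        # and it is excluded from the summary statistics
        assert report.summary["naive"]["n_loci"] == 3

    def test_unknown_truth_locus_rejected(self):
        with pytest.raises(ValueError):
            build_report({"zz": 5}, [], _toy_loci())
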