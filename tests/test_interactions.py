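"""Correlation statistics, change classification, voting and concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from dietvirome.data_io import AbundanceMatrix
from dietvirome.interactions import (
    bh_adjust,
    classify_change,
    concordance,
    correlate_pairs,
    project_direction,
    screen_differential,
    spearman,
    vote_trend,
)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.arange(1.0, 9.0)
        rho, _ = spearman(x, x**2)
        assert rho == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.arange(1.0, 9.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        # ranks d = (-1, 1, -1, 1, 0), sum d^2 = 4 -> 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_p_matches_enumeration_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        y = np.array([2.0, 0.5, 3.5, 1.0, 2.5])
        rho_obs, p = spearman(x, y)
        rx, ry = rankdata(x), rankdata(y)

        def rho_of(perm):
            return np.corrcoef(rx, perm)[0, 1]

        perms = [rho_of(np.array(p_)) for p_ in itertools.permutations(ry)]
        expected = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in perms])
        assert p == pytest.approx(expected)

    def test_monotone_invariance_property(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho1, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho2)


class TestBHAdjust:
    def test_textbook_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_brute_force_step_up(self, ps):
        got = bh_adjust(ps)
        p = np.asarray(ps)
        n = len(p)
        order = np.argsort(p, kind="stable")
        stepped = p[order] * n / np.arange(1, n + 1)
        # enforce monotonicity from the largest rank down, cap at 1
        expected_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(expected_sorted, 1.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert (got >= p - 1e-12).all()


def _matrix(values, ids):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        pd.DataFrame(values, index=ids, columns=[f"s{j}" for j in range(values.shape[1])]),
        "normalized_1e10",
    )


class TestCorrelatePairs:
    def test_bh_family_is_the_stratum(self, rng):
        phage = _matrix(rng.lognormal(0, 1, (3, 10)), ["p0", "p1", "p2"])
        bact = _matrix(rng.lognormal(0, 1, (3, 10)), ["b0", "b1", "b2"])
        pairs = [("p0", "b0"), ("p1", "b1"), ("p2", "b2")]
        recs = correlate_pairs(phage, bact, pairs, {"G": [f"s{j}" for j in range(10)]})
        assert len(recs) == 3
        np.testing.assert_allclose(
            [r.p_adj for r in recs], bh_adjust([r.p_raw for r in recs])
        )

    def test_small_stratum_skipped(self, rng):
        phage = _matrix(rng.lognormal(0, 1, (1, 10)), ["p0"])
        bact = _matrix(rng.lognormal(0, 1, (1, 10)), ["b0"])
        recs = correlate_pairs(phage, bact, [("p0", "b0")], {"tiny": ["s0", "s1", "s2"]})
        assert recs == []

    def test_planted_correlation_recovered(self):
        # Gaussian copula with planted Spearman 0.9 at n=24
        from dietvirome.synthetic_data import _gauss_copula_r

        r = _gauss_copula_r(0.9)
        good = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            z1 = rng.standard_normal(24)
            z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(24)
            rho, _ = spearman(np.exp(z1), np.exp(z2))
            good += int(abs(rho - 0.9) <= 0.15)
        assert good >= 45

    def test_null_pairs_rarely_significant(self):
        sig, total = 0, 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            phage = _matrix(rng.lognormal(0, 1, (5, 24)), [f"p{i}" for i in range(5)])
            bact = _matrix(rng.lognormal(0, 1, (5, 24)), [f"b{i}" for i in range(5)])
            pairs = [(f"p{i}", f"b{i}") for i in range(5)]
            recs = correlate_pairs(phage, bact, pairs, {"G": [f"s{j}" for j in range(24)]})
            sig += sum(r.significant for r in recs)
            total += len(recs)
        assert sig / total <= 0.07


class TestClassifyChange:
    def test_identical_sets_non_significant(self):
        res = classify_change([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
        assert res.direction == "non-significant"

    def test_planted_increase_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ctrl = rng.uniform(0.1, 0.5, 20)
            intv = np.clip(ctrl + 0.4, 0, 1)
            if classify_change(ctrl, intv).direction == "Increased":
                hits += 1
        assert hits >= 19

    def test_equal_medians_with_low_p_stay_non_significant(self):
        # same medians, very different spreads: the median gate forces
        # non-significant regardless of the rank-sum p
        ctrl = [0.5] * 10
        intv = [0.0] * 4 + [0.5, 0.5] + [1.0] * 4  # median 0.5 as well
        res = classify_change(ctrl, intv)
        assert res.median_abs_rho_control == res.median_abs_rho_intervention
        assert res.direction == "non-significant"

    def test_antisymmetry(self, rng):
        ctrl = rng.uniform(0, 0.4, 15)
        intv = rng.uniform(0.5, 0.9, 15)
        fwd = classify_change(ctrl, intv)
        rev = classify_change(intv, ctrl)
        flip = {"Increased": "Decreased", "Decreased": "Increased", "non-significant": "non-significant"}
        assert rev.direction == flip[fwd.direction]


class TestVoteTrend:
    @pytest.mark.parametrize(
        "dirs,trend",
        [([1, 1, -1], "increasing"), ([1, -1], "indeterminate"), ([], "indeterminate"), ([-1, -1, 1], "decreasing")],
    )
    def test_rule(self, dirs, trend):
        assert vote_trend(dirs).trend == trend

    def test_matches_brute_force_count(self, rng):
        for _ in range(50):
            dirs = [int(d) for d in rng.choice([1, -1], size=rng.integers(0, 9))]
            v = vote_trend(dirs)
            assert v.n_increase == dirs.count(1)
            assert v.n_decrease == dirs.count(-1)
            expected = (
                "increasing"
                if v.n_increase > v.n_decrease
                else "decreasing" if v.n_decrease > v.n_increase else "indeterminate"
            )
            assert v.trend == expected

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            vote_trend([1, 0])


class TestConcordance:
    def test_direct_fraction(self):
        s = concordance({"a": 1, "b": 1, "c": -1, "d": 1}, {"a": 1, "b": 1, "c": -1, "d": -1})
        assert (s.n_concordant, s.n_discordant) == (3, 1)
        assert s.proportion_concordant == pytest.approx(0.75)

    def test_all_concordant(self):
        s = concordance({"a": -1, "b": 1}, {"a": -1, "b": 1})
        assert s.proportion_concordant == 1.0

    def test_no_shared_projects_undefined(self):
        assert concordance({"a": 1}, {"b": 1}).proportion_concordant is None

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            projects = [f"P{i}" for i in range(rng.integers(1, 8))]
            pd_ = {p: int(rng.choice([1, -1])) for p in projects}
            hd_ = {p: int(rng.choice([1, -1])) for p in projects if rng.random() < 0.8}
            s = concordance(pd_, hd_)
            shared = set(pd_) & set(hd_)
            n_con = sum(pd_[p] == hd_[p] for p in shared)
            assert s.n_concordant == n_con and s.n_discordant == len(shared) - n_con

    def test_project_direction_sign(self):
        assert project_direction([1, 1, 1], [5, 5, 5]) == 1
        assert project_direction([5, 5], [1, 1]) == -1
        assert project_direction([2, 2], [2, 2]) is None


class TestScreenDifferential:
    def _study(self, rng, fold=1.0, n=12):
        base = rng.lognormal(3, 0.5, size=(6, 2 * n))
        base[0, n:] *= fold  # taxon t0 planted
        m = _matrix(base, [f"t{i}" for i in range(6)])
        groups = {f"s{j}": ("ctrl" if j < n else "case") for j in range(2 * n)}
        return m, groups

    def test_identical_distributions_not_selected(self, rng):
        m, groups = self._study(rng, fold=1.0)
        got = screen_differential(m, groups)
        assert got.empty or (got["log10_effect"] <= 0.5).all()

    def test_planted_tenfold_selected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m, groups = self._study(rng, fold=10.0)
            got = screen_differential(m, groups)
            hits += int("t0" in set(got["taxon_id"]))
        assert hits >= 48

    def test_supplied_calls_bypass_screen(self, rng):
        m, groups = self._study(rng)
        supplied = pd.DataFrame({"taxon_id": ["x1", "x2"], "lda_score": [3.1, 2.4]})
        got = screen_differential(m, groups, supplied=supplied)
        assert list(got["taxon_id"]) == ["x1", "x2"]
        assert (got["source"] == "provided").all()

    def test_single_group_rejected(self, rng):
        m, _ = self._study(rng)
        with pytest.raises(ValueError):
            screen_differential(m, {f"s{j}": "only" for j in range(24)})
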