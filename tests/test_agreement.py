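"""Bland-Altman agreement, exact Mann-Whitney, and group summaries."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctcomp as cc


def brute_force_mw(a, b):
    """Independent oracle: U by pairwise comparison counts, exact p by
    enumerating every group assignment of the pooled multiset."""
    a, b = list(a), list(b)

    def u_pairwise(x, y):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y)

    u_obs = u_pairwise(a, b)
    pooled = a + b
    n = len(a)
    us = []
    for idx in combinations(range(len(pooled)), n):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_pairwise(ga, gb))
    total = comb(len(pooled), n)
    eps = 1e-9
    n_le = sum(u <= u_obs + eps for u in us)
    n_ge = sum(u >= u_obs - eps for u in us)
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


class TestBlandAltman:
    def test_identity(self):
        res = cc.bland_altman([10.0, 12.0, 14.0], [10.0, 12.0, 14.0])
        assert res.mean_difference == 0.0
        assert res.sd_difference == 0.0
        assert (res.ba_lower, res.ba_upper) == (0.0, 0.0)

    def test_constant_offset_no_noise(self):
        measured = [10.0, 20.0, 30.0]
        derived = [9.5, 19.5, 29.5]
        res = cc.bland_altman(measured, derived)
        assert res.mean_difference == pytest.approx(-0.5)
        assert res.sd_difference == 0.0
        assert res.p_value == 0.0

    def test_printed_group_constants_bracket_printed_limits(self):
        """mean -0.63, SD 0.14 give limits (-0.9044, -0.3556), containing the
        conventionally reported interval (-0.90, -0.37) within 0.01 kg."""
        mean, sd = -0.63, 0.14
        lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
        assert lower == pytest.approx(-0.9044)
        assert upper == pytest.approx(-0.3556)
        assert lower <= -0.90 + 0.01
        assert upper >= -0.37 - 0.01

    def test_errors(self):
        with pytest.raises(ValueError):
            cc.bland_altman([1.0], [1.0])
        with pytest.raises(ValueError):
            cc.bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(min_value=1, max_value=50), min_size=2, max_size=12),
        st.lists(st.floats(min_value=-3, max_value=3), min_size=2, max_size=12),
    )
    @settings(max_examples=50, derandomize=True)
    def test_limit_identities(self, measured, noise):
        n = min(len(measured), len(noise))
        measured = np.array(measured[:n])
        derived = measured + np.array(noise[:n])
        res = cc.bland_altman(measured, derived)
        assert res.ba_lower == pytest.approx(res.mean_difference - 1.96 * res.sd_difference)
        assert res.ba_upper == pytest.approx(res.mean_difference + 1.96 * res.sd_difference)
        assert res.ba_range == pytest.approx(-3.92 * res.sd_difference)

    def test_swap_negates_mean_keeps_p(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(10, 20, 8)
        d = m + rng.normal(-0.5, 0.3, 8)
        r1 = cc.bland_altman(m, d)
        r2 = cc.bland_altman(d, m)
        assert r1.mean_difference == pytest.approx(-r2.mean_difference)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestMannWhitney:
    def test_complete_separation_two_vs_two(self):
        res = cc.mann_whitney_exact([1, 2], [3, 4])
        assert res.u == 0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_one_vs_one_caps_at_one(self):
        res = cc.mann_whitney_exact([1], [2])
        assert res.p_value == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            cc.mann_whitney_exact([], [1.0])

    def test_breed_separation_from_reference_table(self):
        """Day-0 lean:fat of the two breeds separates completely: U = 0 and
        exact p = 2/924 over the C(12,6) assignments."""
        records = cc.load_reference_composition()
        res = cc.breed_ratio_test(records, day=0)
        assert (res.n1, res.n2) == (6, 6)
        assert res.u == 0
        assert res.p_value == pytest.approx(2 / 924)
        assert res.p_value < 0.01

    @given(
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_exact_matches_brute_force_with_ties(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, n1).tolist()  # small support forces ties
        b = rng.integers(0, 5, n2).tolist()
        res = cc.mann_whitney_exact(a, b)
        u_ref, p_ref = brute_force_mw(a, b)
        assert res.u == pytest.approx(u_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            perm = rng.permutation(100).astype(float)  # disjoint draws: no ties
            a, b = perm[:6], perm[6:13]
            res = cc.mann_whitney_exact(a, b)
            ref = mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert res.u == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_invariant_under_monotone_transform(self):
        a = [1.2, 3.4, 2.2, 8.0]
        b = [4.5, 6.6, 9.9]
        r1 = cc.mann_whitney_exact(a, b)
        r2 = cc.mann_whitney_exact(np.exp(a), np.exp(b))
        r3 = cc.mann_whitney_exact(np.power(a, 3), np.power(b, 3))
        assert r1.u == r2.u == r3.u
        assert r1.p_value == r2.p_value == r3.p_value

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 15)
        res = cc.mann_whitney_exact(a, b)
        assert res.method == "asymptotic"
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, method="asymptotic", alternative="two-sided", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestRecordsAndSummaries:
    def test_component_sum_is_ct_derived_bw(self):
        rec = cc.AnimalRecord(id="x", breed="beagle", day=0, bone_kg=1.8, lean_kg=6.4, fat_kg=2.5)
        assert rec.ct_derived_bw_kg == pytest.approx(10.7)

    @pytest.mark.parametrize(
        "lean,fat,expected", [(6.0, 3.9, 1.5), (17.4, 1.7, 10.2), (5.8, 3.2, 1.8)]
    )
    def test_ratio_rounding(self, lean, fat, expected):
        rec = cc.AnimalRecord(id="x", breed="b", day=0, bone_kg=1.0, lean_kg=lean, fat_kg=fat)
        assert cc.round_half_away(rec.lean_fat_ratio) == pytest.approx(expected)

    def test_reference_group_summaries(self):
        records = cc.load_reference_composition()
        summary = cc.summarize_groups(records).set_index(["breed", "day"])
        assert cc.round_half_away(summary.loc[("beagle", 0), "fat_kg_mean"]) == 2.9
        assert cc.round_half_away(summary.loc[("greyhound", 0), "ct_derived_bw_kg_mean"]) == 24.8
        assert cc.round_half_away(summary.loc[("greyhound", 0), "ct_derived_bw_kg_std"]) == 2.0

    def test_single_animal_group_sd_missing(self):
        records = [
            cc.AnimalRecord(id="a", breed="x", day=0, bone_kg=1, lean_kg=2, fat_kg=1),
            cc.AnimalRecord(id="b", breed="y", day=0, bone_kg=1, lean_kg=2, fat_kg=1),
            cc.AnimalRecord(id="c", breed="y", day=0, bone_kg=2, lean_kg=3, fat_kg=1),
        ]
        summary = cc.summarize_groups(records).set_index(["breed", "day"])
        assert np.isnan(summary.loc[("x", 0), "bone_kg_std"])
        assert summary.loc[("y", 0), "bone_kg_std"] == pytest.approx(np.std([1, 2], ddof=1))

    def test_measured_bw_must_be_positive(self):
        with pytest.raises(ValueError):
            cc.AnimalRecord(id="a", breed="x", day=0, bone_kg=1, lean_kg=2, fat_kg=1,
                            measured_bw_kg=-3.0)

    def test_group_agreement_skips_unmeasured(self):
        records = [
            cc.AnimalRecord(id="a", breed="x", day=0, bone_kg=1, lean_kg=2, fat_kg=1,
                            measured_bw_kg=4.5),
            cc.AnimalRecord(id="b", breed="x", day=0, bone_kg=1, lean_kg=3, fat_kg=1,
                            measured_bw_kg=5.5),
            cc.AnimalRecord(id="c", breed="y", day=0, bone_kg=2, lean_kg=3, fat_kg=1),
            cc.AnimalRecord(id="d", breed="y", day=0, bone_kg=2, lean_kg=4, fat_kg=1),
        ]
        out = cc.group_agreement(records)
        assert list(out) == [("x", 0)]
        res = out[("x", 0)]
        assert res.mean_difference == pytest.approx(-0.5)


def test_animal_table_round_trip(tmp_path):
    path = tmp_path / "animals.tsv"
    path.write_text(
        "id\tbreed\tday\tbone_kg\tlean_kg\tfat_kg\tmeasured_bw_kg\n"
        "a\tx\t0\t1.0\t2.0\t1.0\t4.5\n"
        "b\ty\t0\t2.0\t3.0\t1.5\t\n"
    )
    records = cc.read_animal_table(path)
    assert records[0].measured_bw_kg == 4.5
    assert records[1].measured_bw_kg is None


def test_missing_columns_rejected(tmp_path):
    path = tmp_path / "animals.tsv"
    path.write_text("id\tbreed\tday\tbone_kg\n" "a\tx\t0\t1.0\n")
    with pytest.raises(ValueError, match="missing columns"):
        cc.read_animal_table(path)
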