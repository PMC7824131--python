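"""The four plane metrics and the cohort agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fetalmsp import metrics as pm
from fetalmsp.geometry import normalize_plane, plane_from_angles


def unit4(a, b, c, d):
    return normalize_plane([a, b, c, d])


P100 = unit4(1, 0, 0, 0)
P010 = unit4(0, 1, 0, 0)


class TestIncludedAngle:
    def test_identical_is_zero(self):
        assert pm.included_angle(P100, P100) == 0.0

    def test_orthogonal_four_vectors(self):
        assert np.isclose(pm.included_angle(P100, P010), 90.0, atol=1e-9)

    def test_forty_five_degrees(self):
        p = unit4(1, 1, 0, 0)
        assert np.isclose(pm.included_angle(P100, p), 45.0, atol=1e-9)

    def test_symmetric_and_antipodal_invariant(self):
        p = unit4(1, 0.3, -0.2, 0.5)
        q = unit4(0.9, -0.1, 0.3, -0.4)
        assert np.isclose(pm.included_angle(p, q), pm.included_angle(q, p))
        # the same plane with flipped coefficients compares as identical
        assert pm.included_angle(p.vector, -p.vector) < 1e-5

    def test_unnormalized_input_warns(self):
        with pytest.warns(UserWarning):
            pm.included_angle((2.0, 0, 0, 0), (1.0, 0, 0, 0))


class TestCoeffDistance:
    def test_identical_is_zero(self):
        assert pm.coeff_distance(P100, P100) == 0.0

    def test_orthogonal_is_sqrt2(self):
        assert np.isclose(pm.coeff_distance(P100, P010), np.sqrt(2), atol=1e-9)

    @given(
        a=st.floats(0.2, 1), b=st.floats(-1, 1), c=st.floats(-1, 1), d=st.floats(-1, 1),
        a2=st.floats(0.2, 1), b2=st.floats(-1, 1), c2=st.floats(-1, 1), d2=st.floats(-1, 1),
    )
    @settings(deadline=None, max_examples=100)
    def test_distance_angle_identity(self, a, b, c, d, a2, b2, c2, d2):
        p, q = unit4(a, b, c, d), unit4(a2, b2, c2, d2)
        if float(p.vector @ q.vector) < 0:
            return  # identity stated for representative pairs with nonneg dot
        theta = np.deg2rad(pm.included_angle(p, q))
        assert np.isclose(pm.coeff_distance(p, q) ** 2, 2 * (1 - np.cos(theta)), atol=1e-9)


class TestYawRoll:
    def test_canonical_sagittal(self):
        p = unit4(1, 0, 0, -0.5)
        assert pm.yaw(p) == 0.0
        assert pm.roll(p) == 0.0

    def test_yaw_forty_five(self):
        assert np.isclose(pm.yaw(unit4(1, 1, 0, 0)), 45.0, atol=1e-9)

    def test_roll_forty_five(self):
        assert np.isclose(pm.roll(unit4(1, 0, -1, 0)), 45.0, atol=1e-9)

    def test_vertical_plane_yaw_is_ninety(self):
        assert np.isclose(abs(pm.yaw(unit4(0, 1, 0, 0))), 90.0)

    def test_small_for_near_sagittal_planes(self):
        p = plane_from_angles((0.0, 0.0, 0.0), 5.0, -3.0)
        assert abs(pm.yaw(p)) < 10
        assert abs(pm.roll(p)) < 10


class TestEvaluateCohort:
    def test_identical_pairs(self):
        pairs = [(P100, P100)] * 4
        df, summary = pm.evaluate_cohort(pairs)
        assert summary["mean_theta"] == 0.0
        assert summary["frac_dist_lt_0.05"] == 1.0
        assert summary["frac_theta_lt_1deg"] == 1.0

    def test_threshold_fraction_counting(self):
        good = plane_from_angles((0, 0, 0), 0.0, 0.0)
        off = plane_from_angles((0, 0, 0), 2.0, 0.0)
        pairs = [(good, good)] * 9 + [(off, good)]
        _, summary = pm.evaluate_cohort(pairs)
        assert np.isclose(summary["frac_theta_lt_1deg"], 0.9)

    def test_means_match_per_pair_averages(self, rng):
        pairs = []
        for _ in range(15):
            pairs.append(
                (
                    plane_from_angles((0, 0, 0), *rng.uniform(-30, 30, 2)),
                    plane_from_angles((0, 0, 0), *rng.uniform(-30, 30, 2)),
                )
            )
        df, summary = pm.evaluate_cohort(pairs)
        brute = np.mean([pm.included_angle(p, q) for p, q in pairs])
        assert np.isclose(summary["mean_theta"], brute, atol=1e-12)

    def test_permutation_invariance(self, rng):
        pairs = [
            (
                plane_from_angles((0, 0, 0), *rng.uniform(-30, 30, 2)),
                plane_from_angles((0, 0, 0), *rng.uniform(-30, 30, 2)),
            )
            for _ in range(10)
        ]
        _, s1 = pm.evaluate_cohort(pairs)
        _, s2 = pm.evaluate_cohort(pairs[::-1])
        assert s1.keys() == s2.keys()
        for k in s1:
            assert np.isclose(s1[k], s2[k], atol=1e-12), k

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            pm.evaluate_cohort([])


class TestAgreement:
    def test_constant_shift(self, rng):
        a = rng.normal(size=30)
        b = a + 0.1
        st_ = pm.agreement(a, b)
        assert np.isclose(st_.bias, 0.1)
        assert np.isclose(st_.r, 1.0)
        assert np.isclose(st_.ci_low, st_.ci_high)

    def test_identical_arms(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        st_ = pm.agreement(a, a)
        assert st_.bias == 0.0
        assert st_.loa_low == st_.loa_high == 0.0
        assert st_.p is None  # not-applicable marker, not NaN

    def test_matches_reference_statistics(self, rng):
        a = rng.normal(size=50)
        b = a + rng.normal(0.2, 0.3, size=50)
        st_ = pm.agreement(a, b)
        d = b - a
        assert np.isclose(st_.mean, d.mean(), atol=1e-12)
        assert np.isclose(st_.sd, d.std(ddof=1), atol=1e-12)
        tt = stats.ttest_rel(b, a)
        assert np.isclose(st_.p, tt.pvalue, atol=1e-12)
        lo, hi = stats.t.interval(0.95, 49, loc=d.mean(), scale=stats.sem(d))
        assert np.isclose(st_.ci_low, lo, atol=1e-9)
        assert np.isclose(st_.ci_high, hi, atol=1e-9)
        assert np.isclose(st_.r, stats.pearsonr(a, b).statistic, atol=1e-12)
        assert np.isclose(st_.loa_high - st_.loa_low, 2 * 1.96 * st_.sd, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pm.agreement([1.0, 2.0], [1.0, 2.0])

    def test_bland_altman_plot_writes_file(self, tmp_path, rng):
        a = rng.normal(size=20)
        b = a + rng.normal(0, 0.1, size=20)
        out = tmp_path / "ba.png"
        st_ = pm.bland_altman_plot(a, b, out)
        assert out.exists() and out.stat().st_size > 0
        assert st_.loa_low <= st_.bias <= st_.loa_high
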