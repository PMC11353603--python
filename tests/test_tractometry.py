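"""Along-tract profiling: resampling exactness, orientation, central segment,
pointwise group testing."""

import numpy as np
import pytest

from microtract.io import ScalarMap, StreamlineBundle
from microtract.tractometry import (
    TractProfile,
    central_segment,
    mean_group_profile,
    orient_bundle,
    pointwise_test,
    resample_streamline,
    tract_profile,
)


def straight_bundle(n_streamlines=1, length=99.0, y0=5.0):
    sls = [
        np.stack([np.linspace(0, length, 40),
                  np.full(40, y0 + i * 0.1),
                  np.full(40, 5.0)], axis=1)
        for i in range(n_streamlines)
    ]
    return StreamlineBundle(sls, "forceps_minor")


def profile_from_values(values, tract="forceps_minor", metric="FA"):
    values = np.asarray(values, dtype=float)
    n_valid = (~np.isnan(values)).astype(int)
    return TractProfile(tract, metric, values[None, :], values, n_valid)


class TestResample:
    def test_uniform_spacing_on_straight_segment(self):
        poly = np.array([[0.0, 0, 0], [99.0, 0, 0]])
        pts = resample_streamline(poly, 100)
        spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 1.0, atol=1e-12)
        np.testing.assert_allclose(pts[0], poly[0])
        np.testing.assert_allclose(pts[-1], poly[-1])

    def test_idempotence(self):
        poly = np.stack([np.linspace(0, 50, 100), np.zeros(100), np.zeros(100)], axis=1)
        np.testing.assert_allclose(resample_streamline(poly, 100), poly, atol=1e-9)

    def test_semicircle_arc_length_parameterization(self):
        r = 30.0
        t = np.linspace(0, np.pi, 5000)
        poly = np.stack([r * np.cos(t), r * np.sin(t), np.zeros_like(t)], axis=1)
        pts = resample_streamline(poly, 100)
        spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert spacing.max() - spacing.min() < 1e-6 * r

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            resample_streamline(np.array([[1.0, 1, 1], [1.0, 1, 1 + 1e-18]]))


class TestOrientBundle:
    def test_reversed_streamlines_realigned(self):
        bundle = straight_bundle(6)
        mixed = StreamlineBundle(
            [sl if i % 2 == 0 else sl[::-1] for i, sl in enumerate(bundle.streamlines)],
            bundle.name,
        )
        ref = bundle.streamlines[0][0]
        oriented = orient_bundle(mixed, ref)
        starts = np.array([sl[0, 0] for sl in oriented.streamlines])
        assert np.all(starts < 1.0)

    def test_idempotence(self):
        bundle = straight_bundle(4)
        ref = bundle.streamlines[0][0]
        once = orient_bundle(bundle, ref)
        twice = orient_bundle(once, ref)
        for a, b in zip(once.streamlines, twice.streamlines):
            np.testing.assert_array_equal(a, b)

    def test_equidistant_tie_not_flipped(self):
        sl = np.array([[-1.0, 0, 0], [0.0, 1, 0], [1.0, 0, 0]])
        bundle = StreamlineBundle([sl], "other")
        oriented = orient_bundle(bundle, np.array([0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(oriented.streamlines[0], sl)


class TestTractProfile:
    def test_constant_field(self):
        smap = ScalarMap(np.full((110, 12, 12), 0.7), "FA")
        prof = tract_profile(straight_bundle(5), smap)
        np.testing.assert_allclose(prof.mean_profile, 0.7, atol=1e-12)
        assert np.all(prof.n_valid == 5)

    def test_linear_ramp_sampled_exactly(self):
        ii = np.meshgrid(np.arange(110.0), np.arange(12.0), np.arange(12.0),
                         indexing="ij")[0]
        smap = ScalarMap(ii / 99.0, "FA")
        prof = tract_profile(straight_bundle(3), smap)
        expected = np.linspace(0.0, 1.0, 100)
        np.testing.assert_allclose(prof.mean_profile, expected, atol=1e-9)

    def test_single_streamline_equals_its_samples(self):
        rng = np.random.default_rng(0)
        smap = ScalarMap(rng.uniform(size=(110, 12, 12)), "MD")
        bundle = straight_bundle(1)
        prof = tract_profile(bundle, smap)
        np.testing.assert_array_equal(prof.mean_profile, prof.values[0])

    def test_profile_invariant_under_streamline_permutation(self):
        rng = np.random.default_rng(1)
        smap = ScalarMap(rng.uniform(size=(110, 12, 12)), "FA")
        bundle = straight_bundle(6)
        perm = StreamlineBundle(bundle.streamlines[::-1], bundle.name)
        p1 = tract_profile(bundle, smap)
        p2 = tract_profile(perm, smap)
        np.testing.assert_allclose(p1.mean_profile, p2.mean_profile)

    def test_masked_points_excluded(self):
        smap = ScalarMap(np.full((110, 12, 12), 0.9), "FA")
        mask = np.ones((110, 12, 12), bool)
        mask[:30] = False  # first half of the track is outside the mask
        prof = tract_profile(straight_bundle(2), smap, mask=mask)
        assert np.all(np.isnan(prof.mean_profile[:25]))
        assert prof.n_valid[:25].max() == 0
        np.testing.assert_allclose(prof.mean_profile[-20:], 0.9)


class TestCentralSegment:
    def test_linear_ramp_gives_midpoint(self):
        # points 40..60 are symmetric about 50 -> mean of ramp = value at 50
        ramp = np.linspace(0.0, 1.0, 100)
        cs = central_segment(profile_from_values(ramp), "s1")
        assert cs.value == pytest.approx(np.mean(ramp[39:60]))
        assert cs.value == pytest.approx(0.4949, abs=1e-3)

    def test_constant(self):
        assert central_segment(profile_from_values(np.full(100, 0.7))).value == pytest.approx(0.7)

    def test_missing_points_excluded(self):
        vals = np.full(100, np.nan)
        vals[49:60] = 0.9  # labels 50..60
        assert central_segment(profile_from_values(vals)).value == pytest.approx(0.9)

    def test_all_missing_raises(self):
        vals = np.full(100, 0.5)
        vals[39:60] = np.nan
        with pytest.raises(ValueError):
            central_segment(profile_from_values(vals))

    def test_monotone_in_profile_values(self):
        base = np.linspace(0.2, 0.8, 100)
        raised = base.copy()
        raised[39:60] += 0.1
        assert (
            central_segment(profile_from_values(raised)).value
            > central_segment(profile_from_values(base)).value
        )


class TestGroupProfiles:
    def test_identical_subjects(self):
        prof = profile_from_values(np.linspace(0, 1, 100))
        mean, sd = mean_group_profile([prof, prof, prof])
        np.testing.assert_allclose(mean, prof.mean_profile)
        np.testing.assert_allclose(sd, 0.0, atol=1e-15)

    def test_antisymmetric_pair_averages_to_zero(self):
        c = np.sin(np.linspace(0, 3, 100))
        mean, _ = mean_group_profile([profile_from_values(c), profile_from_values(-c)])
        np.testing.assert_allclose(mean, 0.0, atol=1e-15)

    def test_constant_subjects_mean(self):
        profs = [profile_from_values(np.full(100, float(k))) for k in range(1, 6)]
        mean, _ = mean_group_profile(profs)
        np.testing.assert_allclose(mean, 3.0)


class TestPointwiseTest:
    def _group(self, rng, n, shift=0.0, where=None):
        profs = []
        for _ in range(n):
            v = rng.normal(size=100)
            if shift:
                sl = slice(None) if where is None else where
                v[sl] += shift
            profs.append(profile_from_values(v))
        return profs

    def test_extreme_separation_all_points_significant(self):
        rng = np.random.default_rng(0)
        res = pointwise_test(
            {"control": self._group(rng, 8), "MCI": self._group(rng, 8, shift=10.0)}
        )
        assert len(res.points) == 91
        assert np.all(res.p_values < 0.01)
        assert res.significant_runs == [(5, 95)]

    def test_localized_effect_confined_run(self):
        rng = np.random.default_rng(1)
        res = pointwise_test(
            {
                "control": self._group(rng, 10),
                "MCI": self._group(rng, 10, shift=8.0, where=slice(19, 30)),
            }
        )
        sig_points = res.points[res.p_values < 0.01]
        assert np.all((sig_points >= 18) & (sig_points <= 32))
        assert any(lo >= 19 and hi <= 31 for lo, hi in res.significant_runs)

    def test_all_tied_point_records_p_one(self):
        profs_a = [profile_from_values(np.zeros(100)) for _ in range(3)]
        profs_b = [profile_from_values(np.zeros(100)) for _ in range(3)]
        res = pointwise_test({"a": profs_a, "b": profs_b})
        np.testing.assert_array_equal(res.p_values, 1.0)
        assert res.significant_runs == []

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(2)
        res = pointwise_test(
            {
                "control": self._group(rng, 6),
                "MCI": self._group(rng, 6, shift=6.0),
                "dementia": self._group(rng, 6, shift=12.0),
            }
        )
        assert np.all(res.p_values < 0.01)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            pointwise_test({"a": [profile_from_values(np.zeros(100))],
                            "b": [profile_from_values(np.zeros(100))] * 2})
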