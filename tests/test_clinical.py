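"""Background mean, BTV auto-contour, T/B ratios, Jaccard, acceptance rules."""
import math

import numpy as np
import pytest

from petmrac.clinical import (MetricsRecord, acceptance_check,
                              background_mean, cohort_filter, delineate_btv,
                              jaccard, tumor_metrics)
from petmrac.volume import Volume

VOX2 = (2.0, 2.0, 2.0)  # 8 mm^3 = 0.008 mL voxels


def vol(arr, vox=VOX2):
    return Volume(np.asarray(arr, dtype=float), vox)


def toy_grid():
    """4x4x1 grid with B=1: two suprathreshold voxels (2.0, 1.7), one at
    exactly the 1.6 boundary."""
    a = np.ones((1, 4, 4))
    a[0, 0, 0] = 2.0
    a[0, 1, 1] = 1.7
    a[0, 2, 2] = 1.6
    return vol(a)


class TestBackground:
    def test_constant_activity(self):
        act = vol(np.ones((1, 4, 4)))
        roi = Volume(np.ones((1, 4, 4), bool), VOX2)
        assert background_mean(act, roi) == 1.0

    def test_two_voxel_mean(self):
        act = vol([[[0.8, 1.2], [5.0, 5.0]]])
        roi = Volume(np.array([[[True, True], [False, False]]]), VOX2)
        assert background_mean(act, roi) == pytest.approx(1.0)

    def test_empty_roi_rejected(self):
        act = vol(np.ones((1, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            background_mean(act, Volume(np.zeros((1, 2, 2), bool), VOX2))


class TestDelineation:
    def test_uniform_at_background_empty(self):
        d = delineate_btv(vol(np.ones((1, 4, 4))), b=1.0)
        assert d.btv_ml == 0.0
        assert not d.tumor_mask.data.any()

    def test_toy_grid_strict_boundary(self):
        """Strictly-above rule: 1.6 at threshold 1.6 is excluded;
        2 voxels x 0.008 mL = 0.016 mL."""
        d = delineate_btv(toy_grid(), b=1.0)
        assert int(d.tumor_mask.data.sum()) == 2
        assert d.btv_ml == pytest.approx(0.016)
        assert d.threshold_used == pytest.approx(1.6)

    def test_exclusion_mask_removes_hot_spot(self):
        act = toy_grid()
        excl = np.zeros((1, 4, 4), bool)
        excl[0, 0, 0] = True  # covers the 2.0 voxel
        d = delineate_btv(act, b=1.0, exclusion_mask=Volume(excl, VOX2))
        assert int(d.tumor_mask.data.sum()) == 1
        d_full = delineate_btv(act, b=1.0)
        assert d_full.btv_ml - d.btv_ml == pytest.approx(0.008)

    def test_btv_monotone_in_threshold_multiplier(self):
        act = toy_grid()
        btvs = [delineate_btv(act, 1.0, multiplier=m).btv_ml
                for m in (1.2, 1.6, 1.9, 2.1)]
        assert btvs == sorted(btvs, reverse=True)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            delineate_btv(toy_grid(), b=0.0)


class TestMetrics:
    def test_toy_grid_ratios(self):
        act = toy_grid()
        d = delineate_btv(act, b=1.0)
        rec = tumor_metrics(act, d, b=1.0)
        assert rec.t_mean == pytest.approx(1.85)
        assert rec.t_max == pytest.approx(2.0)
        assert rec.tmean_b == pytest.approx(1.85)
        assert rec.tmax_b == pytest.approx(2.0)

    def test_uniform_tumor_mean_equals_max(self):
        act = vol(np.full((1, 2, 2), 3.0))
        d = delineate_btv(act, b=1.0)
        rec = tumor_metrics(act, d, b=1.0)
        assert rec.t_mean == rec.t_max

    def test_background_scaling_halves_ratios(self):
        act = toy_grid()
        d = delineate_btv(act, b=1.0)
        r1 = tumor_metrics(act, d, b=1.0)
        r2 = tumor_metrics(act, d, b=2.0)
        assert r2.tmean_b == pytest.approx(r1.tmean_b / 2)
        assert r2.tmax_b == pytest.approx(r1.tmax_b / 2)

    def test_empty_mask_flagged(self):
        act = vol(np.ones((1, 2, 2)))
        d = delineate_btv(act, b=1.0)
        rec = tumor_metrics(act, d, b=1.0)
        assert not rec.valid
        assert math.isnan(rec.tmax_b)
        assert rec.btv_ml == 0.0


class TestJaccard:
    def test_identical_masks(self, rng):
        m = rng.random((3, 4, 4)) > 0.5
        assert jaccard(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((1, 2, 2), bool)
        b = np.zeros((1, 2, 2), bool)
        a[0, 0, 0] = True
        b[0, 1, 1] = True
        assert jaccard(a, b) == 0.0

    def test_counting_example(self):
        a = np.zeros(12, bool)
        b = np.zeros(12, bool)
        a[:4] = True
        b[2:6] = True
        assert jaccard(a.reshape(1, 3, 4), b.reshape(1, 3, 4)) == pytest.approx(2 / 6)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((1, 2, 2), bool)
        assert jaccard(z, z) == 1.0

    def test_symmetric_matches_set_oracle(self, rng):
        for _ in range(20):
            a = rng.random((2, 3, 3)) > 0.6
            b = rng.random((2, 3, 3)) > 0.6
            sa = {tuple(i) for i in np.argwhere(a)}
            sb = {tuple(i) for i in np.argwhere(b)}
            expect = 1.0 if not (sa | sb) else len(sa & sb) / len(sa | sb)
            assert jaccard(a, b) == pytest.approx(expect)
            assert jaccard(b, a) == jaccard(a, b)


def rec(tmean_b=1.85, tmax_b=2.0, btv=10.0, sid="s1", exam=0, method="X"):
    return MetricsRecord(1.0, tmean_b, tmax_b * 1.0, tmean_b, tmax_b, btv,
                         method, sid, exam)


class TestAcceptance:
    def test_observed_tmax_overestimate_fails(self):
        """A T_MAX/B overestimation of 0.13 at reference 2.0 exceeds both
        the 0.1 absolute and the 5% relative limit."""
        out = acceptance_check(rec(tmax_b=2.13), rec(tmax_b=2.0))
        assert out["tmax_b"] is False

    def test_zero_differences_all_pass(self):
        out = acceptance_check(rec(), rec())
        assert all(out.values())

    def test_large_btv_passes_on_relative_rule(self):
        # 3 mL > 2 mL absolute, but 7.5% <= 10%
        out = acceptance_check(rec(btv=43.0), rec(btv=40.0))
        assert out["btv_ml"] is True

    @pytest.mark.parametrize("metric,delta,expect", [
        ("tmean_b", 0.04, True),    # inside 0.05 absolute
        ("tmean_b", 0.12, False),   # outside both (ref 1.85 -> 6.5%)
        ("tmax_b", 0.09, True),     # inside 0.1 absolute
        ("btv_ml", 1.5, True),      # inside 2 mL absolute
        ("btv_ml", 9.0, False),     # 22.5% of 40 wait -> uses btv=10
    ])
    def test_rule_truth_table(self, metric, delta, expect):
        base = rec()
        kwargs = {"tmean_b": 1.85, "tmax_b": 2.0, "btv": 10.0}
        key = {"tmean_b": "tmean_b", "tmax_b": "tmax_b", "btv_ml": "btv"}[metric]
        kwargs[key] += delta
        out = acceptance_check(rec(**kwargs), base)
        assert out[metric] is expect

    def test_mismatched_exam_rejected(self):
        with pytest.raises(ValueError):
            acceptance_check(rec(sid="a"), rec(sid="b"))

    def test_zero_reference_uses_absolute_only(self):
        t = rec(btv=1.0)
        r = rec(btv=0.0)
        out = acceptance_check(t, r)
        assert out["btv_ml"] is True  # 1 mL <= 2 mL absolute


class TestCohortFilter:
    def test_small_tumor_excluded_and_idempotent(self):
        records = [rec(btv=0.5, sid="a"), rec(btv=2.0, sid="b"),
                   rec(btv=1.0, sid="c")]  # 1.0 is not "above 1 mL"
        kept = cohort_filter(records)
        assert [r.subject_id for r in kept] == ["b"]
        assert cohort_filter(kept) == kept
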