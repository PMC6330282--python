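"""Sigmoid calibration and the segmentation-based AC maps."""
import numpy as np
import pytest

from petmrac.clinical import jaccard
from petmrac.folds import kfold_split
from petmrac.mrac import classify_tissue, hu_to_mu
from petmrac.phantom import PhantomSpec, generate_battery, generate_case
from petmrac.resolute import (SigmoidParams, build_nobone_map,
                              build_resolute_map, calibrate_bone_sigmoid,
                              fit_sigmoid, resolute_crossval, sigmoid)


def make_pairs(rng, n, L=0.0, U=1500.0, r0=800.0, k=0.01, sigma=30.0):
    r = rng.uniform(0, 2000, n)
    hu = L + (U - L) / (1 + np.exp(-k * (r - r0))) + rng.normal(0, sigma, n)
    return r, hu


class TestSigmoidFit:
    def test_parameter_recovery_under_noise(self, rng):
        p = fit_sigmoid(*make_pairs(rng, 10_000))
        assert abs(p.L - 0.0) / 1500 < 0.05
        assert abs(p.U - 1500) / 1500 < 0.05
        assert abs(p.r0 - 800) / 800 < 0.05
        assert abs(p.k - 0.01) / 0.01 < 0.05

    def test_noiseless_fit_is_exact(self, rng):
        p = fit_sigmoid(*make_pairs(rng, 2000, sigma=0.0))
        assert p.rmse < 1e-6 * 1500

    def test_too_few_samples_refused(self, rng):
        with pytest.raises(ValueError, match="bone samples"):
            fit_sigmoid(*make_pairs(rng, 50))

    def test_inflection_is_midpoint(self):
        p = SigmoidParams(L=0, U=1000, r0=700, k=0.01)
        assert sigmoid(700.0, p) == pytest.approx(500.0)

    def test_bounded_and_monotone(self):
        p = SigmoidParams(L=-50, U=1200, r0=700, k=0.008)
        r = np.linspace(-1000, 5000, 999)
        y = sigmoid(r, p)
        assert np.all(np.diff(y) >= 0)
        assert y.min() >= p.L and y.max() <= p.U

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(L=100, U=50, r0=1, k=0.01)
        with pytest.raises(ValueError):
            SigmoidParams(L=0, U=50, r0=1, k=-0.01)


class TestCalibration:
    def test_two_fold_membership(self):
        """Fold-f parameters are fitted only on out-of-fold subjects."""
        cases = generate_battery(2, seed=5, scale="micro")
        folds = kfold_split(cases, k=2, seed=0)
        params = calibrate_bone_sigmoid(cases, folds)
        # recompute each fold's fit from the single training case by hand
        from petmrac.mrac import compute_r2star
        from petmrac.phantom import TE1_MS, TE2_MS
        for fold in (0, 1):
            (train_id,) = folds.train_subjects(fold)
            case = next(c for c in cases if c.subject_id == train_id)
            r2 = compute_r2star(case.ute1, case.ute2, TE1_MS, TE2_MS).volume.data
            bone = case.ct_hu.data > 300
            expect = fit_sigmoid(r2[bone], case.ct_hu.data[bone])
            assert params[fold].n == expect.n
            assert params[fold].r0 == pytest.approx(expect.r0)

    def test_crossval_never_scores_own_subject(self):
        cases = generate_battery(4, seed=5, scale="micro")
        folds = kfold_split(cases, k=2, seed=0)
        for fold in (0, 1):
            assert set(folds.train_subjects(fold)).isdisjoint(
                folds.test_subjects(fold))


class TestResoluteMap:
    def test_noiseless_bone_jaccard(self):
        cases = [generate_case(PhantomSpec.micro(seed=s, noise_sigma=0.0),
                               subject_id=f"sub-{s}") for s in (31, 32)]
        res, _ = resolute_crossval(cases, k=2, seed=1)
        for c in cases:
            _, pct = res[(c.subject_id, c.exam_index)]
            j = jaccard(classify_tissue(c.ct_hu).data == 2,
                        classify_tissue(pct).data == 2)
            assert j >= 0.9

    def test_all_air_input_gives_zero_mu(self, noiseless_case):
        zero = noiseless_case.ute1.like(np.zeros(noiseless_case.ute1.shape))
        import dataclasses
        case = dataclasses.replace(noiseless_case, ute1=zero, ute2=zero.copy())
        p = SigmoidParams(L=0, U=1000, r0=700, k=0.01)
        mu, _ = build_resolute_map(case, p)
        assert np.all(mu.volume.data == 0.0)

    def test_resolute_beats_nobone_on_noiseless_mu(self):
        case = generate_case(PhantomSpec.micro(seed=41, noise_sigma=0.0))
        other = generate_case(PhantomSpec.micro(seed=42, noise_sigma=0.0),
                              subject_id="sub-001")
        res, _ = resolute_crossval([case, other], k=2, seed=0)
        mu_true = hu_to_mu(case.ct_hu).volume.data
        mu_res, _ = res[(case.subject_id, case.exam_index)]
        mu_nb, _ = build_nobone_map(case)
        mae_res = np.abs(mu_res.volume.data - mu_true).mean()
        mae_nb = np.abs(mu_nb.volume.data - mu_true).mean()
        assert mae_res < mae_nb


class TestNoBone:
    def test_bone_voxels_get_soft_mu(self, noiseless_case):
        mu, _ = build_nobone_map(noiseless_case)
        bone = noiseless_case.labels.data == 2
        expect = 0.096 + 30.0 * 5.1e-5  # soft HU sits on the positive branch
        assert np.all(mu.volume.data[bone] == pytest.approx(expect))

    def test_two_class_histogram(self, noiseless_case):
        mu, _ = build_nobone_map(noiseless_case)
        assert len(np.unique(mu.volume.data)) <= 2
        assert mu.provenance == "NOBONE"
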