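"""Anatomy, signal and activity synthesis of the head phantoms."""
import numpy as np
import pytest

from petmrac.phantom import (BG_AIR, BONE, BRAIN, INT_AIR, SOFT, TUMOR,
                             PhantomSpec, build_anatomy, generate_case,
                             synthesize_activity, synthesize_signals)


def test_label_set_without_air_cavities(micro_spec):
    labels = build_anatomy(micro_spec)
    assert set(np.unique(labels.data)) == {BG_AIR, SOFT, BONE, BRAIN, TUMOR}


def test_air_cavity_toggles_add_internal_air():
    spec = PhantomSpec.micro(seed=3, air_nasal=True, air_mastoid=True)
    labels = build_anatomy(spec)
    assert INT_AIR in np.unique(labels.data)


def test_anatomy_deterministic(micro_spec):
    a = build_anatomy(micro_spec)
    b = build_anatomy(micro_spec)
    assert np.array_equal(a.data, b.data)


def test_case_bit_identical_for_same_spec(micro_spec):
    c1 = generate_case(micro_spec)
    c2 = generate_case(micro_spec)
    for attr in ("labels", "ct_hu", "ute1", "ute2", "activity"):
        assert np.array_equal(getattr(c1, attr).data, getattr(c2, attr).data)


def test_skull_thickness_by_ray_casting():
    """Bone shell thickness along principal axes matches the spec.

    Oracle: cast rays from the head center along each +/- axis and count
    contiguous bone voxels; 4 mm skull at 2 mm voxels must give a 2-voxel
    shell along every axis.
    """
    spec = PhantomSpec.desk(seed=0, skull_thickness_mm=4.0)
    lab = build_anatomy(spec).data
    center = tuple(s // 2 for s in lab.shape)
    counts = []
    for axis in range(3):
        for direction in (1, -1):
            idx = list(center)
            ray = []
            while 0 <= idx[axis] < lab.shape[axis]:
                ray.append(lab[tuple(idx)])
                idx[axis] += direction
            ray = np.array(ray)
            bone_positions = np.nonzero(ray == BONE)[0]
            assert bone_positions.size > 0
            counts.append(bone_positions.size)
    assert min(counts) == 2


def test_bone_count_monotone_in_skull_thickness():
    counts = []
    for t in (3.5, 5.0, 6.5):
        spec = PhantomSpec.micro(seed=0, skull_thickness_mm=t)
        counts.append(int((build_anatomy(spec).data == BONE).sum()))
    assert counts == sorted(counts)


def test_tumor_outside_brain_rejected():
    with pytest.raises(ValueError, match="tumor"):
        build_anatomy(PhantomSpec.micro(seed=0, tumor_center_mm=(0.0, 0.0, 38.0)))


def test_noiseless_echo_decay_closed_form():
    """Echoes follow S(TE) = S0 exp(-TE R2*): S0=100, R2*=1000/s gives
    93.24 / 8.55 at TE 0.07 / 2.46 ms."""
    assert 100 * np.exp(-0.00007 * 1000) == pytest.approx(93.24, abs=5e-3)
    assert 100 * np.exp(-0.00246 * 1000) == pytest.approx(8.54, abs=5e-3)
    spec = PhantomSpec.micro(seed=0, noise_sigma=0.0)
    labels = build_anatomy(spec)
    _, e1, e2 = synthesize_signals(labels, spec)
    soft = labels.data == SOFT
    s0, r2, _ = 100.0, 30.0, 30.0
    assert e1.data[soft] == pytest.approx(s0 * np.exp(-0.00007 * r2), rel=1e-12)
    assert e2.data[soft] == pytest.approx(s0 * np.exp(-0.00246 * r2), rel=1e-12)


def test_air_is_minus_1000_hu(noiseless_case):
    lab = noiseless_case.labels.data
    assert np.all(noiseless_case.ct_hu.data[lab == BG_AIR] == -1000.0)


def test_bone_echo_ordering_and_water_stability(noiseless_case):
    lab = noiseless_case.labels.data
    e1, e2 = noiseless_case.ute1.data, noiseless_case.ute2.data
    assert np.all(e1[lab == BONE] > e2[lab == BONE])
    soft = lab == SOFT
    assert np.allclose(e1[soft], e2[soft], rtol=0.08)  # R2* ~ 30/s barely decays


def test_label_means_stable_across_seeds():
    """Per-tissue signal means agree across noise seeds within 3 SE."""
    means = []
    for seed in (21, 22):
        case = generate_case(PhantomSpec.micro(seed=seed))
        lab = case.labels.data
        soft = lab == SOFT
        n = soft.sum()
        assert n >= 1000
        means.append((case.ute1.data[soft].mean(),
                      case.ute1.data[soft].std() / np.sqrt(n)))
    (m1, se1), (m2, se2) = means
    assert abs(m1 - m2) < 3 * np.hypot(se1, se2)


def test_negative_noise_rejected():
    with pytest.raises(ValueError):
        PhantomSpec.micro(seed=0, noise_sigma=-0.1)


def test_grid_too_small_rejected():
    with pytest.raises(ValueError, match="32"):
        PhantomSpec(grid_shape=(24, 32, 32))


def test_activity_peak_equals_ratio(noiseless_case):
    lab = noiseless_case.labels.data
    act = noiseless_case.activity.data
    b = act[noiseless_case.background_roi.data].mean()
    assert act[lab == TUMOR].max() / b == pytest.approx(2.5, rel=1e-12)


def test_background_roi_disjoint_from_tumor(noisy_case):
    assert not np.any(noisy_case.background_roi.data & noisy_case.tumor_mask())


def test_subthreshold_ratio_warns():
    spec = PhantomSpec.micro(seed=0, tumor_to_background_ratio=1.5)
    labels = build_anatomy(spec)
    with pytest.warns(UserWarning, match="sub-threshold"):
        synthesize_activity(labels, spec)


def test_hot_spot_covered_by_exclusion_mask():
    case = generate_case(PhantomSpec.micro(seed=4, hot_spot=True, noise_sigma=0.0))
    excl = case.exclusion_mask.data
    assert excl.any()
    assert np.all(case.activity.data[excl] > 1.6)


def test_repeat_exam_same_anatomy_fresh_noise(micro_spec):
    c0 = generate_case(micro_spec, exam_index=0)
    c1 = generate_case(micro_spec, exam_index=1)
    assert np.array_equal(c0.labels.data, c1.labels.data)
    assert not np.array_equal(c0.ute1.data, c1.ute1.data)
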