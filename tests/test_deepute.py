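"""Network construction, window bookkeeping, training and inference."""
import numpy as np
import pytest

from petmrac.deepute import (NetworkSpec, TrainConfig, build_network,
                             case_channels, count_parameters, coverage_counts,
                             extract_windows, kfold_split, predict_volume,
                             train)
from petmrac.evaluation import _toy_case


class TestNetwork:
    def test_output_shape_full_size_window(self):
        """A (16, 192, 192, 3) input window maps to (16, 192, 192, 1)."""
        model = build_network(NetworkSpec(depth=4, base_channels=1), seed=0)
        x = np.zeros((1, 3, 16, 192, 192), dtype=np.float32)
        y = model.forward(x, train=False)
        assert y.shape == (1, 1, 16, 192, 192)

    def test_micro_output_shape(self):
        model = build_network(NetworkSpec.micro(), seed=0)
        y = model.forward(np.zeros((2, 3, 16, 32, 32), np.float32), train=False)
        assert y.shape == (2, 1, 16, 32, 32)

    def test_indivisible_plane_rejected(self):
        model = build_network(NetworkSpec.micro(), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 3, 16, 30, 30), np.float32))

    def test_parameter_count_grows_with_base_channels(self):
        small = count_parameters(build_network(NetworkSpec.micro(base_channels=4)))
        large = count_parameters(build_network(NetworkSpec.micro(base_channels=8)))
        assert large > small

    def test_zeroed_final_layer_outputs_zero(self):
        model = build_network(NetworkSpec.micro(), seed=0)
        model.final.params["W"][:] = 0
        model.final.params["b"][:] = 0
        y = model.forward(np.random.default_rng(0)
                          .standard_normal((1, 3, 16, 32, 32)).astype(np.float32),
                          train=False)
        assert np.all(y == 0)

    def test_dropout_schedule_rises_through_encoder(self):
        sched = NetworkSpec(depth=4).dropout_schedule
        assert sched[0] == pytest.approx(0.1)
        assert sched[-1] == pytest.approx(0.3)
        assert np.all(np.diff(sched) > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(window_depth=8)
        with pytest.raises(ValueError):
            NetworkSpec(in_channels=2)


class TestWindows:
    def test_window_count(self):
        assert len(extract_windows(_toy_case(0, n_slices=20))) == 5
        assert len(extract_windows(_toy_case(0, n_slices=16))) == 1

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="slices"):
            extract_windows(_toy_case(0, n_slices=15))

    def test_window_slice_indexing(self):
        """Window at start s, slice j shows source slice s+j."""
        case = _toy_case(3, n_slices=20)
        ws = extract_windows(case)
        chans = case_channels(case)
        c, cs = ws.norm["echo1"]
        for s in (0, 2, 4):
            for j in (0, 7, 15):
                expect = (chans[0, s + j] - c) / cs
                assert np.allclose(ws.windows[s, 0, j], expect, atol=1e-5)

    def test_target_is_matching_ct(self):
        case = _toy_case(3, n_slices=18)
        ws = extract_windows(case)
        assert np.allclose(ws.targets[2, 0, 5],
                           case.ct_hu.data[7] / 1000.0, atol=1e-5)

    def test_coverage_closed_form(self):
        # 20-slice volume: slice 0 in 1 window, slice 10 in 5
        cov = coverage_counts(20)
        assert cov[0] == 1 and cov[10] == 5 and cov[19] == 1


class TestTraining:
    def test_zero_learning_rate_freezes_parameters(self):
        """lr=0 performs no updates: every weight is bit-identical after
        training (the sampled loss still fluctuates through dropout)."""
        case = _toy_case(5, n_slices=16)
        model = build_network(NetworkSpec.micro(), seed=0)
        before = [p.copy() for l in model.layers() for p in l.params.values()]
        train(model, [case], TrainConfig(learning_rate=0.0, epochs=2,
                                         batch_size=1, seed=0,
                                         init_output_bias=False))
        after = [p for l in model.layers() for p in l.params.values()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))

    def test_same_seed_same_history(self):
        case = _toy_case(6, n_slices=16)
        hists = []
        for _ in range(2):
            model = build_network(NetworkSpec.micro(), seed=3)
            hists.append(train(model, [case],
                               TrainConfig.micro(epochs=2, seed=4,
                                                 window_subsample=1)))
        assert hists[0] == hists[1]

    def test_empty_cases_rejected(self):
        with pytest.raises(ValueError):
            train(build_network(NetworkSpec.micro()), [], TrainConfig())


class TestInference:
    def test_constant_model_constant_output(self):
        """A model outputting constant c yields a constant pseudo-CT,
        independent of per-voxel window coverage."""
        case = _toy_case(7, n_slices=20)
        model = build_network(NetworkSpec.micro(), seed=0)
        model.final.params["W"][:] = 0
        model.final.params["b"][:] = 0.25
        pct = predict_volume(model, case)
        assert np.allclose(pct.data, 0.25 * 1000.0, atol=1e-3)

    def test_overlap_average_equals_bruteforce(self):
        from petmrac.evaluation import overlap_equivalence
        res = overlap_equivalence(seed=1)
        assert res["n_windows"] == 3
        assert res["coverage_matches"]
        assert res["max_abs_diff_hu"] < 1e-6

    def test_slice_reversal_equivariance_with_symmetric_model(self):
        """With a slice-symmetric (1x1x1-equivalent) constant-weight model,
        predicting a reversed volume reverses the prediction."""
        case = _toy_case(8, n_slices=18)
        model = build_network(NetworkSpec.micro(), seed=0)
        fwd = predict_volume(model, case).data
        import types
        rev = types.SimpleNamespace(
            ute1=case.ute1.like(case.ute1.data[::-1].copy()),
            ute2=case.ute2.like(case.ute2.data[::-1].copy()),
            ct_hu=case.ct_hu.like(case.ct_hu.data[::-1].copy()))
        model.final.params["W"][:] = 0
        model.final.params["b"][:] = 0.5
        a = predict_volume(model, case).data
        b = predict_volume(model, rev).data
        assert np.allclose(a, b[::-1])
        assert fwd.shape == a.shape


class TestFolds:
    def test_singleton_folds(self):
        split = kfold_split([f"s{i}" for i in range(4)], k=4, seed=0)
        counts = {}
        for s, f in split.assignment.items():
            counts[f] = counts.get(f, 0) + 1
        assert all(v == 1 for v in counts.values())

    def test_repeat_exams_share_fold(self):
        from petmrac.phantom import PhantomSpec, generate_case
        spec = PhantomSpec.micro(seed=9)
        exams = [generate_case(spec, subject_id="sub-a", exam_index=i)
                 for i in range(2)]
        others = [generate_case(PhantomSpec.micro(seed=10 + i),
                                subject_id=f"sub-{i}") for i in range(3)]
        split = kfold_split(exams + others, k=2, seed=1)
        assert split.fold_of("sub-a") in (0, 1)
        assert len(split.assignment) == 4  # subjects, not exams

    def test_partition_property(self):
        split = kfold_split([f"s{i}" for i in range(7)], k=3, seed=2)
        folds = [set(split.test_subjects(f)) for f in range(3)]
        assert set.union(*folds) == {f"s{i}" for i in range(7)}
        for i in range(3):
            for j in range(i + 1, 3):
                assert folds[i].isdisjoint(folds[j])

    def test_k_less_than_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=1, seed=0)
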