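import numpy as np
import pytest

from wmlseg.grids import RigidTransform, Volume
from wmlseg.nets import build_flair_net
from wmlseg.phantom import default_acquisition, lesion_mask_flair, make_phantom, render
from wmlseg.training import (
    FlairSample,
    T1Sample,
    TrainConfig,
    _flair_loss_fn,
    build_curated_dataset,
    rank_by_loss,
    train,
    train_t1_from_flair,
    two_step_flair_workflow,
)

from conftest import SMALL_ROI


def _flair_samples(n, seed0=100, shape=(32, 32, 48)):
    out = []
    for i in range(n):
        truth = make_phantom(seed=seed0 + i, shape=shape,
                             n_lesions_by_class=(1, 1, 0),
                             pv_radius_mm=4, jc_radius_mm=2,
                             lesion_radius_range=(2.5, 4.0))
        spec = default_acquisition(truth, "flair", noise_sd=0.02, seed=seed0 + i)
        vol, _ = render(truth, spec)
        out.append(FlairSample(id=f"s{i:02d}", image=vol,
                               target=lesion_mask_flair(truth, spec)))
    return out


@pytest.fixture(scope="module")
def four_samples():
    return _flair_samples(4)


CFG = TrainConfig(max_epochs=2, width_scale=0.25, seed=0)


class TestTrain:
    def test_lr_zero_leaves_parameters_unchanged(self, four_samples):
        model = build_flair_net(0.25, seed=0)
        before = [p.value.copy() for p in model.params()]
        cfg = TrainConfig(learning_rate=0.0, max_epochs=1, width_scale=0.25)
        train(model, four_samples, _flair_loss_fn(cfg), cfg)
        for p, b in zip(model.params(), before):
            assert np.array_equal(p.value, b)

    def test_deterministic_history(self, four_samples):
        hists = []
        for _ in range(2):
            model = build_flair_net(0.25, seed=1)
            _, h = train(model, four_samples, _flair_loss_fn(CFG), CFG)
            hists.append(h)
        assert hists[0] == hists[1]

    def test_single_sample_loss_decreases(self, four_samples):
        model = build_flair_net(0.25, seed=2)
        cfg = TrainConfig(max_epochs=6, learning_rate=3e-3, width_scale=0.25, seed=2)
        _, h = train(model, four_samples[:1], _flair_loss_fn(cfg), cfg)
        assert h[-1] < h[0]

    def test_empty_dataset_fails(self):
        model = build_flair_net(0.25)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], _flair_loss_fn(CFG), CFG)

    def test_non_finite_loss_aborts_with_sample_index(self, four_samples):
        model = build_flair_net(0.25)

        def bad_loss(m, s, rng):
            return float("nan"), np.zeros((3,) + s.image.grid.shape, dtype=np.float32)

        with pytest.raises(RuntimeError, match="sample index"):
            train(model, four_samples, bad_loss, CFG)

    def test_stop_rule_halts_on_plateau(self, four_samples):
        model = build_flair_net(0.25, seed=3)
        cfg = TrainConfig(max_epochs=50, learning_rate=0.0, stop_patience=2,
                          stop_slope=1e-4, width_scale=0.25)
        _, h = train(model, four_samples[:1], _flair_loss_fn(cfg), cfg)
        assert len(h) == 4  # flat loss stops at the first full window pair


class TestRankByLoss:
    def test_identical_samples_tie_stably(self, four_samples):
        model = build_flair_net(0.25, seed=4)
        clones = [four_samples[0]] * 3
        report = rank_by_loss(model, clones, _flair_loss_fn(CFG))
        assert len(set(report.losses)) == 1
        assert list(report.ranks) == [1, 2, 3]

    def test_ranks_are_permutation(self, four_samples):
        model = build_flair_net(0.25, seed=5)
        report = rank_by_loss(model, four_samples, _flair_loss_fn(CFG))
        assert sorted(report.ranks) == [1, 2, 3, 4]
        assert report.top(1)[0] == report.sample_ids[int(np.argmax(report.losses))]

    def test_empty_fails(self):
        model = build_flair_net(0.25)
        with pytest.raises(ValueError, match="empty"):
            rank_by_loss(model, [], _flair_loss_fn(CFG))


class TestBuildCuratedDataset:
    def test_noop(self, four_samples):
        out = build_curated_dataset(four_samples, {}, set(), 10)
        assert out == four_samples

    def test_oversampling_arithmetic(self):
        samples = _flair_samples(4, seed0=200, shape=(32, 32, 16))
        # emulate N=20 with 2 corrections at 10x: 18 + 2*10 = 38
        big = samples * 5  # 20 entries, ids repeat but sizes illustrate
        fixed = {samples[0].id: samples[0].target, samples[1].id: samples[1].target}
        out = build_curated_dataset(big, fixed, set(), 10)
        # 5 copies each of 2 corrected ids -> 10 entries replaced by 10x each
        assert len(out) == (20 - 10) + 10 * 10

    def test_corrected_target_replaced_and_repeated(self, four_samples):
        new_target = Volume(np.zeros(four_samples[0].target.grid.shape),
                            four_samples[0].target.grid)
        out = build_curated_dataset(four_samples, {"s01": new_target}, {"s03"}, 3)
        ids = [s.id for s in out]
        assert ids.count("s01") == 3 and "s03" not in ids
        assert all(s.target is new_target for s in out if s.id == "s01")

    def test_unknown_ids_fail(self, four_samples):
        with pytest.raises(KeyError, match="unknown"):
            build_curated_dataset(four_samples, {"nope": None}, set(), 2)


class TestTwoStepWorkflow:
    def test_zero_corrections_reduces_to_train_plus_inference(self, four_samples):
        cfg = TrainConfig(max_epochs=2, width_scale=0.25, seed=6)
        model, refs, report = two_step_flair_workflow(four_samples, cfg)
        assert set(refs) == {s.id for s in four_samples}
        assert report.flags == ["kept"] * 4
        for s in four_samples:
            assert refs[s.id].grid.shape == s.image.grid.shape
            assert refs[s.id].data.min() >= 0 and refs[s.id].data.max() <= 1

    def test_deterministic(self, four_samples):
        cfg = TrainConfig(max_epochs=1, width_scale=0.25, seed=7)
        _, refs_a, rep_a = two_step_flair_workflow(four_samples, cfg)
        _, refs_b, rep_b = two_step_flair_workflow(four_samples, cfg)
        assert np.array_equal(rep_a.losses, rep_b.losses)
        for sid in refs_a:
            assert np.array_equal(refs_a[sid].data, refs_b[sid].data)

    def test_unknown_correction_id_fails(self, four_samples):
        cfg = TrainConfig(max_epochs=1, width_scale=0.25)
        with pytest.raises(KeyError, match="unknown"):
            two_step_flair_workflow(four_samples, cfg,
                                    corrections={"ghost": four_samples[0].target})


def _t1_samples(n, seed0=300, shape=(32, 32, 30)):
    out = []
    for i in range(n):
        truth = make_phantom(seed=seed0 + i, shape=shape,
                             n_lesions_by_class=(1, 0, 1),
                             pv_radius_mm=4, jc_radius_mm=2,
                             lesion_radius_range=(2.5, 4.0))
        t1, _ = render(truth, default_acquisition(truth, "t1", 0.02, seed0 + i))
        spec = default_acquisition(truth, "flair", 0.02, seed0 + i)
        out.append(
            (
                truth,
                T1Sample(
                    id=f"t{i:02d}",
                    t1=t1,
                    flair_wmh=lesion_mask_flair(truth, spec),
                    ribbon=Volume(truth.ribbon_mask.astype(float), truth.grid),
                    rigid=RigidTransform.identity(),
                ),
            )
        )
    return out


class TestTrainT1FromFlair:
    def test_smoke_and_determinism(self):
        samples = [s for _, s in _t1_samples(2)]
        cfg = TrainConfig(max_epochs=1, width_scale=0.0625, seed=8)
        _, h1 = train_t1_from_flair(samples, cfg)
        _, h2 = train_t1_from_flair(samples, cfg)
        assert h1 == h2 and np.isfinite(h1).all()

    def test_ribbon_weight_zero_still_trains(self):
        samples = [s for _, s in _t1_samples(1)]
        cfg = TrainConfig(max_epochs=1, width_scale=0.0625, ribbon_weight=0.0)
        _, h = train_t1_from_flair(samples, cfg)
        assert np.isfinite(h).all()

    def test_dense_baseline_runs(self):
        samples = [s for _, s in _t1_samples(1)]
        cfg = TrainConfig(max_epochs=1, width_scale=0.0625)
        _, h = train_t1_from_flair(samples, cfg, loss="dense")
        assert np.isfinite(h).all()

    def test_unknown_loss_fails(self):
        with pytest.raises(ValueError, match="loss"):
            train_t1_from_flair([], TrainConfig(), loss="hinge")

    def test_degenerate_grids_sparse_equals_dense_loss_value(self):
        # FLAIR grid == T1 grid: first-visit loss identical for both modes
        truth = make_phantom(seed=400, shape=(32, 32, 16),
                             n_lesions_by_class=(1, 0, 0),
                             pv_radius_mm=4, jc_radius_mm=2)
        t1, _ = render(truth, default_acquisition(truth, "t1", 0.0))
        target = Volume((truth.lesion_field >= 0.5).astype(float), truth.grid)
        sample = T1Sample("d", t1, target,
                          Volume(truth.ribbon_mask.astype(float), truth.grid),
                          RigidTransform.identity())
        cfg = TrainConfig(max_epochs=1, width_scale=0.0625, seed=9, shuffle=False)
        _, h_sparse = train_t1_from_flair([sample], cfg, loss="sparse")
        _, h_dense = train_t1_from_flair([sample], cfg, loss="dense")
        assert h_sparse[0] == pytest.approx(h_dense[0], rel=1e-6)


def test_oversample_factor_validated():
    with pytest.raises(ValueError):
        TrainConfig(oversample_factor=0)
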