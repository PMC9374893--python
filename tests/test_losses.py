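import numpy as np
import pytest

from wmlseg.grids import Grid, RigidTransform, Volume, build_sampling_map
from wmlseg.losses import (
    LossTerms,
    dense_interpolating_loss,
    dense_interpolating_loss_grad,
    joint_loss,
    joint_loss_grad,
    ribbon_loss,
    sparse_lesion_loss,
    sparse_lesion_loss_grad,
)

from conftest import (
    brute_force_sampling_pairs,
    make_volume,
    random_orthogonal_grid,
    random_rigid,
)

IDENT = RigidTransform.identity()


def _grids_and_map(rng, max_dim=12):
    fg = random_orthogonal_grid(rng, max_dim=max_dim)
    tg = random_orthogonal_grid(rng, max_dim=max_dim)
    rigid = random_rigid(rng)
    return fg, tg, rigid, build_sampling_map(fg, tg, rigid)


class TestSparseLesionLoss:
    def test_perfect_fit_is_zero(self):
        rng = np.random.default_rng(0)
        fg, tg, rigid, smap = _grids_and_map(rng)
        target = Volume((rng.uniform(size=fg.shape) > 0.5).astype(float), fg)
        out1 = Volume(np.zeros(tg.shape), tg)
        for (fi, ti) in smap.pairs:
            out1.data[ti] = target.data[fi]
        # a T1 voxel hit twice with conflicting targets cannot be fit; skip those
        flat = np.ravel_multi_index(smap.t1_indices.T, tg.shape)
        if len(np.unique(flat)) == len(flat):
            assert sparse_lesion_loss(out1, target, smap) == 0.0

    def test_counting_case(self):
        g = Grid.from_spacing((4, 4, 4), (1, 1, 1))
        smap = build_sampling_map(g, g, IDENT)
        target = Volume(np.zeros(g.shape), g)
        target.data[:2, 0, 0] = 1.0  # k = 2 positive voxels
        out1 = Volume(np.zeros(g.shape), g)
        assert sparse_lesion_loss(out1, target, smap) == 2.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            fg, tg, rigid, smap = _grids_and_map(rng)
            out1, target = make_volume(rng, tg), make_volume(rng, fg)
            got = sparse_lesion_loss(out1, target, smap)
            pairs, _ = brute_force_sampling_pairs(fg, tg, rigid)
            expected = sum(
                (out1.data[ti] - target.data[fi]) ** 2 for fi, ti in pairs
            )
            assert abs(got - expected) < 1e-10

    def test_shape_mismatch_fails(self):
        rng = np.random.default_rng(2)
        fg, tg, rigid, smap = _grids_and_map(rng)
        small = Grid.from_spacing((2, 2, 2), (1, 1, 1))
        if smap.n_pairs and np.any(np.array(tg.shape) > 2):
            with pytest.raises(ValueError, match="exceed"):
                sparse_lesion_loss(Volume(np.zeros(small.shape), small),
                                   make_volume(rng, fg), smap)


class TestGradientSparsity:
    def test_zero_gradient_at_unsampled_voxels(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            fg, tg, rigid, smap = _grids_and_map(rng)
            out1, target = make_volume(rng, tg), make_volume(rng, fg)
            g = sparse_lesion_loss_grad(out1, target, smap)
            sampled = np.zeros(tg.shape, dtype=bool)
            if smap.n_pairs:
                sampled[tuple(smap.t1_indices.T)] = True
            assert np.all(g[~sampled] == 0.0)

    def test_gradient_matches_finite_difference_on_sampled(self):
        rng = np.random.default_rng(4)
        fg = Grid.from_spacing((3, 3, 3), (1, 1, 1))
        smap = build_sampling_map(fg, fg, IDENT)
        out1, target = make_volume(rng, fg), make_volume(rng, fg)
        g = sparse_lesion_loss_grad(out1, target, smap)
        eps = 1e-6
        idx = (1, 2, 0)
        out_hi = out1.copy()
        out_hi.data[idx] += eps
        fd = (sparse_lesion_loss(out_hi, target, smap)
              - sparse_lesion_loss(out1, target, smap)) / eps
        assert abs(g[idx] - fd) < 1e-5

    def test_duplicate_hits_accumulate(self):
        # two FLAIR voxels collapsing onto one T1 voxel count twice
        fg = Grid.from_spacing((2, 1, 1), (0.2, 1, 1))
        tg = Grid.from_spacing((1, 1, 1), (1, 1, 1))
        smap = build_sampling_map(fg, tg, IDENT)
        assert smap.n_pairs == 2
        out1 = Volume(np.full(tg.shape, 0.25), tg)
        target = Volume(np.ones(fg.shape), fg)
        assert abs(sparse_lesion_loss(out1, target, smap) - 2 * 0.75**2) < 1e-12
        g = sparse_lesion_loss_grad(out1, target, smap)
        assert abs(g[0, 0, 0] - 2 * 2 * (0.25 - 1.0)) < 1e-12


class TestRibbonLoss:
    def test_identical_is_zero(self):
        rng = np.random.default_rng(5)
        g = random_orthogonal_grid(rng)
        v = make_volume(rng, g)
        assert ribbon_loss(v, v) == 0.0

    def test_all_zero_vs_all_one(self):
        g = Grid.from_spacing((3, 4, 5), (1, 1, 1))
        zero = Volume(np.zeros(g.shape), g)
        one = Volume(np.ones(g.shape), g)
        assert ribbon_loss(zero, one) == g.n_voxels

    def test_matches_direct_sum(self):
        rng = np.random.default_rng(6)
        g = random_orthogonal_grid(rng)
        a, b = make_volume(rng, g), make_volume(rng, g)
        expected = float(np.sum((a.data - b.data) ** 2))
        assert abs(ribbon_loss(a, b) - expected) < 1e-12


class TestJointLoss:
    def test_both_perfect_is_zero(self):
        g = Grid.from_spacing((4, 4, 4), (1, 1, 1))
        smap = build_sampling_map(g, g, IDENT)
        v = Volume(np.zeros(g.shape), g)
        terms = joint_loss(v, v, v, v, smap)
        assert terms.total == 0.0 and terms.n_sampled == g.n_voxels

    def test_weighted_sum_arithmetic(self):
        rng = np.random.default_rng(7)
        g = Grid.from_spacing((5, 5, 5), (1, 1, 1))
        smap = build_sampling_map(g, g, IDENT)
        out1, out2 = make_volume(rng, g), make_volume(rng, g)
        target, ribbon = make_volume(rng, g), make_volume(rng, g)
        terms = joint_loss(out1, out2, target, ribbon, smap, ribbon_weight=0.001)
        assert isinstance(terms, LossTerms)
        expected = sparse_lesion_loss(out1, target, smap) + 0.001 * ribbon_loss(
            out2, ribbon
        )
        assert abs(terms.total - expected) < 1e-12

    def test_ribbon_term_dominance_threshold(self):
        # the ribbon term outweighs the sparse term only past the 1000x ratio
        g = Grid.from_spacing((4, 4, 4), (1, 1, 1))
        smap = build_sampling_map(g, g, IDENT)
        zero = Volume(np.zeros(g.shape), g)
        one = Volume(np.ones(g.shape), g)
        sparse_only = joint_loss(zero, zero, one, zero, smap)  # sparse = 64
        assert sparse_only.total > 0.001 * sparse_only.ribbon
        ribbon_only = joint_loss(zero, zero, zero, one, smap)  # ribbon = 64
        assert ribbon_only.total == pytest.approx(0.001 * 64)

    def test_grad_pair(self):
        rng = np.random.default_rng(8)
        g = Grid.from_spacing((4, 4, 4), (1, 1, 1))
        smap = build_sampling_map(g, g, IDENT)
        out1, out2 = make_volume(rng, g), make_volume(rng, g)
        target, ribbon = make_volume(rng, g), make_volume(rng, g)
        g1, g2 = joint_loss_grad(out1, out2, target, ribbon, smap)
        assert np.allclose(g1, 2 * (out1.data - target.data))
        assert np.allclose(g2, 0.001 * 2 * (out2.data - ribbon.data))


class TestDenseInterpolatingLoss:
    def test_identical_grids_reduces_to_dense_squared_error(self):
        rng = np.random.default_rng(9)
        g = Grid.from_spacing((6, 6, 6), (1, 1, 1))
        out1, target = make_volume(rng, g), make_volume(rng, g)
        got = dense_interpolating_loss(out1, target, IDENT)
        assert abs(got - ribbon_loss(out1, target)) < 1e-10

    def test_perfect_prediction_of_interpolated_target(self):
        from wmlseg.grids import resample

        rng = np.random.default_rng(10)
        fg = Grid.from_spacing((8, 8, 2), (1, 1, 4), origin=(0, 0, 1.5))
        tg = Grid.from_spacing((8, 8, 8), (1, 1, 1))
        target = Volume((rng.uniform(size=fg.shape) > 0.5).astype(float), fg)
        pred = resample(target, tg, IDENT, "trilinear")
        assert dense_interpolating_loss(pred, target, IDENT) < 1e-20

    def test_matches_resample_then_sum_oracle(self):
        from wmlseg.grids import resample

        rng = np.random.default_rng(11)
        fg = random_orthogonal_grid(rng, max_dim=8)
        tg = random_orthogonal_grid(rng, max_dim=8)
        rigid = random_rigid(rng)
        out1, target = make_volume(rng, tg), make_volume(rng, fg)
        got = dense_interpolating_loss(out1, target, rigid)
        interp = resample(target, tg, rigid, "trilinear")
        ones = Volume(np.ones(fg.shape), fg)
        fov = resample(ones, tg, rigid, "trilinear").data > 0
        expected = float(np.sum(((out1.data - interp.data) ** 2)[fov]))
        assert abs(got - expected) < 1e-10

    def test_grad_zero_outside_fov(self):
        rng = np.random.default_rng(12)
        fg = Grid.from_spacing((4, 4, 4), (1, 1, 1))
        tg = Grid.from_spacing((12, 12, 12), (1, 1, 1))
        out1, target = make_volume(rng, tg), make_volume(rng, fg)
        g = dense_interpolating_loss_grad(out1, target, IDENT)
        assert np.all(g[8:] == 0.0)


class TestDegenerateEquivalence:
    def test_sparse_equals_dense_when_grids_coincide(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            g = random_orthogonal_grid(rng, max_dim=10)
            smap = build_sampling_map(g, g, IDENT)
            out1, target = make_volume(rng, g), make_volume(rng, g)
            sparse = sparse_lesion_loss(out1, target, smap)
            dense = dense_interpolating_loss(out1, target, IDENT)
            assert abs(sparse - dense) < 1e-10


class TestNonNegativity:
    def test_losses_nonnegative_and_zero_iff_match(self):
        rng = np.random.default_rng(14)
        g = random_orthogonal_grid(rng, max_dim=8)
        smap = build_sampling_map(g, g, IDENT)
        a, b = make_volume(rng, g), make_volume(rng, g)
        assert sparse_lesion_loss(a, b, smap) > 0
        assert dense_interpolating_loss(a, b, IDENT) > 0
        assert sparse_lesion_loss(a, a, smap) == 0.0
        assert dense_interpolating_loss(a, a, IDENT) < 1e-20
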