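import numpy as np
import pytest

from rlnet import (NormalizationSpec, TrainConfig, Volume3D, build_network,
                   loss_aux, loss_main, lr_schedule, make_itm,
                   percentile_normalize, sample_training_block, ssim_global,
                   train)


class TestPercentileNormalize:
    def test_full_range_maps_to_unit_interval(self, rng):
        v = rng.random((10, 10, 10)) * 700 + 30
        out = percentile_normalize(v, NormalizationSpec(0, 100))
        assert out.min() == pytest.approx(0.0, abs=1e-6)
        assert out.max() == pytest.approx(1.0, abs=1e-6)

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            percentile_normalize(np.full((5, 5, 5), 30.0))

    def test_hot_voxel_maps_above_one_with_clipping_percentiles(self, rng):
        v = rng.random((10, 10, 10))
        v[3, 3, 3] = 1000.0
        out = percentile_normalize(v, NormalizationSpec(0.5, 99.9))
        # matches a direct sort-based percentile evaluation
        lo, hi = np.percentile(v, [0.5, 99.9])
        assert out[3, 3, 3] == pytest.approx((1000.0 - lo) / (hi - lo), rel=1e-5)
        assert out[3, 3, 3] > 1.0

    def test_no_clipping_below_p_low(self, rng):
        v = rng.random((10, 10, 10))
        out = percentile_normalize(v, NormalizationSpec(1.0, 99.0))
        assert out.min() < 0  # values below P_low go negative, not clipped


class TestItm:
    def test_printed_arithmetic(self):
        gt = np.full((4, 4, 4), 100.0)
        inp = np.full((4, 4, 4), 50.0)
        assert np.all(make_itm(gt, inp, 0.8) == 90.0)

    def test_weight_one_returns_gt(self, rng):
        gt, inp = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        np.testing.assert_allclose(make_itm(gt, inp, 1.0), gt, atol=1e-7)

    def test_half_weight_is_voxelwise_mean(self, rng):
        gt, inp = rng.random((5, 5, 5)), rng.random((5, 5, 5))
        np.testing.assert_allclose(make_itm(gt, inp, 0.5), (gt + inp) / 2, rtol=1e-6)

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError):
            make_itm(np.zeros((4, 4, 4)), np.zeros((3, 3, 3)))


class TestLosses:
    def test_aux_zero_on_equality(self, rng):
        v = rng.random((6, 6, 6))
        assert loss_aux(v, v) == 0.0

    def test_aux_constant_difference(self):
        a = np.zeros((5, 5, 5))
        assert loss_aux(a + 2.0, a) == pytest.approx(4.0)

    def test_aux_matches_loop_oracle(self, rng):
        a, b = rng.random((4, 5, 6)), rng.random((4, 5, 6))
        acc = 0.0
        for z in range(4):
            for y in range(5):
                for x in range(6):
                    acc += (a[z, y, x] - b[z, y, x]) ** 2
        assert loss_aux(a, b) == pytest.approx(acc / (4 * 5 * 6), rel=1e-9)

    def test_ssim_global_identity_is_one(self, rng):
        v = rng.random((6, 6, 6))
        assert ssim_global(v, v) == pytest.approx(1.0, abs=1e-9)

    def test_ssim_global_anticorrelation_is_negative(self, rng):
        v = rng.random((8, 8, 8)) - 0.5  # zero-ish mean
        v -= v.mean()
        assert ssim_global(v, -v) < 0

    def test_ssim_global_matches_moment_oracle(self, rng):
        a, b = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        c1, c2 = 1e-4, 9e-4
        mu_a, mu_b = a.mean(), b.mean()
        cov = np.cov(a.ravel(), b.ravel(), bias=True)
        want = ((2 * mu_a * mu_b + c1) * (2 * cov[0, 1] + c2)) / \
               ((mu_a ** 2 + mu_b ** 2 + c1) * (cov[0, 0] + cov[1, 1] + c2))
        assert ssim_global(a, b) == pytest.approx(want, rel=1e-9)

    def test_main_loss_zero_iff_perfect(self, rng):
        v = rng.random((6, 6, 6))
        total, mse, ssim_term = loss_main(v, v)
        assert total == pytest.approx(0.0, abs=1e-9)
        total2, _, _ = loss_main(v + 0.1, v)
        assert total2 > 0

    def test_main_loss_components_sum(self, rng):
        a, b = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        total, mse, ssim_term = loss_main(a, b)
        assert total == pytest.approx(mse + ssim_term, rel=1e-12)
        assert mse == pytest.approx(loss_aux(a, b))
        assert ssim_term == pytest.approx(-np.log((1 + ssim_global(a, b)) / 2))

    def test_graph_loss_agrees_with_reference(self, rng):
        # the differentiable loss graph reproduces the numpy-side values
        from rlnet.nn import Tensor
        from rlnet.train import loss_total_graph
        e1 = rng.random((1, 1, 6, 6, 6)).astype(np.float32)
        o = rng.random((1, 1, 6, 6, 6)).astype(np.float32)
        itm = rng.random((1, 1, 6, 6, 6)).astype(np.float32)
        gt = rng.random((1, 1, 6, 6, 6)).astype(np.float32)
        total, parts = loss_total_graph(Tensor(e1), Tensor(o), itm, gt)
        assert parts.l_aux == pytest.approx(loss_aux(e1, itm), rel=1e-4)
        want_main, want_mse, want_ssim = loss_main(o, gt)
        assert parts.l_mse == pytest.approx(want_mse, rel=1e-4)
        assert parts.l_ssim_term == pytest.approx(want_ssim, rel=1e-3)
        assert total.item() == pytest.approx(parts.l_total, rel=1e-5)


class TestLrSchedule:
    def test_step_zero_is_r0(self):
        assert lr_schedule(0.1, 0.5, 0, 1000) == 0.1

    def test_one_decay_period_halves(self):
        assert lr_schedule(0.1, 0.5, 1000, 1000) == pytest.approx(0.05)

    def test_monotone_nonincreasing(self):
        rs = [lr_schedule(1e-3, 0.95, s, 100) for s in range(0, 5000, 37)]
        assert all(b <= a for a, b in zip(rs, rs[1:]))

    def test_continuous_exponent(self):
        assert lr_schedule(1.0, 0.25, 500, 1000) == pytest.approx(0.5)


class TestBlockSampling:
    def test_full_size_block_is_whole_volume(self, rng):
        v = rng.random((8, 8, 8))
        i, g = sample_training_block(v, v, (8, 8, 8), rng)
        np.testing.assert_array_equal(i, v)

    def test_blocks_are_colocated(self, rng):
        base = np.arange(16 ** 3, dtype=np.float64).reshape(16, 16, 16)
        for _ in range(20):
            i, g = sample_training_block(base, base + 1, (6, 6, 6), rng)
            np.testing.assert_array_equal(g, i + 1)

    def test_offsets_cover_valid_range(self, rng):
        base = np.arange(32 ** 3, dtype=np.float64).reshape(32, 32, 32)
        corners = set()
        for _ in range(500):
            blk, _ = sample_training_block(base, base, (16, 16, 16), rng)
            z = int(blk[0, 0, 0]) // (32 * 32)
            corners.add(z)
        assert min(corners) == 0 and max(corners) == 16  # endpoints reached

    def test_oversize_block_raises(self, rng):
        with pytest.raises(ValueError):
            sample_training_block(np.zeros((8, 8, 8)), np.zeros((8, 8, 8)),
                                  (9, 8, 8), rng)


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def toy_pairs(self):
        rng = np.random.default_rng(0)
        pairs = []
        from rlnet import PsfSpec, blur, make_psf
        psf = make_psf(PsfSpec(kind="isotropic-gaussian", lateral_sd=1.0,
                               kernel_dims=(5, 5, 5)))
        for s in range(2):
            gt = rng.random((16, 16, 16)).astype(np.float32) * 100 + 10
            pairs.append((Volume3D(gt), blur(Volume3D(gt), psf)))
        return pairs

    def test_loss_log_bookkeeping(self, toy_pairs):
        model = build_network(seed=0)
        cfg = TrainConfig(batch_size=2, block_dims=(16, 16, 16), epochs=2,
                          iters_per_epoch=3, seed=1)
        _, log = train(model, toy_pairs, cfg)
        assert len(log) == 6
        for rec in log:
            assert rec["l_total"] == pytest.approx(
                rec["l_aux"] + rec["l_mse"] + rec["l_ssim_term"], rel=1e-5)
            assert rec["l_total"] >= 0

    def test_descent_on_toy_deconvolution(self, toy_pairs):
        model = build_network(seed=2)
        cfg = TrainConfig(batch_size=2, block_dims=(16, 16, 16), epochs=1,
                          iters_per_epoch=30, seed=2)
        _, log = train(model, toy_pairs, cfg)
        assert log[-1]["l_total"] < log[0]["l_total"]

    def test_fixed_seed_reproduces_trajectory(self, toy_pairs):
        cfg = TrainConfig(batch_size=1, block_dims=(16, 16, 16), epochs=1,
                          iters_per_epoch=3, seed=3)
        _, log_a = train(build_network(seed=4), toy_pairs, cfg)
        _, log_b = train(build_network(seed=4), toy_pairs, cfg)
        assert [r["l_total"] for r in log_a] == [r["l_total"] for r in log_b]

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train(build_network(seed=0), [], TrainConfig())
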