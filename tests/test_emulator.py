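"""Predictor assembly, schedules, losses, two-stage training, inference."""

import numpy as np
import pytest

from shipair import emulator as em
from shipair import synthetic_world as sw

FAST = dict(pretrain_iters=6, pretrain_lr=2e-3, formal_max_iters=10,
            formal_lr0=2e-3, width=8, n_res_blocks=2)


@pytest.fixture(scope="module")
def jan_split(tiny_world):
    samples, grid, params = tiny_world
    train = [s for s in samples if not s.is_test and s.month_label == "Jan"]
    test = [s for s in samples if s.is_test and s.month_label == "Jan"][0]
    return train, test


class TestPredictors:
    def test_channel_count_and_order(self, jan_split):
        train, _ = jan_split
        stats = em.NormStats.from_samples(train)
        x = em.assemble_predictors(train[0], stats)
        assert x.shape[0] == em.N_CHANNELS == 14

    def test_constant_channel_maps_to_zero(self, jan_split):
        train, _ = jan_split
        stats = em.NormStats.from_samples(train)
        stats.x_mean[0], stats.x_sd[0] = 3.0, 1.0
        s = train[0]
        s2 = sw.MonthSample(s.year_index, s.month_label, s.emissions.copy(),
                            s.met, s.truth)
        j = sw.LAND_SPECIES.index("SO2")
        s2.emissions.land[:, j] = 0.0
        s2.emissions.land[0, j] = 3.0 / len(sw.LAND_SECTORS) * 0 + 3.0
        x = em.assemble_predictors(s2, stats)
        np.testing.assert_allclose(x[0], 0.0, atol=1e-12)

    def test_destandardize_round_trip(self, jan_split):
        train, _ = jan_split
        stats = em.NormStats.from_samples(train)
        raw = em.raw_predictors(train[1])
        x = em.assemble_predictors(train[1], stats)
        back = x * stats.x_sd[:, None, None] + stats.x_mean[:, None, None]
        np.testing.assert_allclose(back, raw, atol=1e-6)

    def test_test_year_channels_finite(self, tiny_world):
        """Training stats applied to the extreme year stay finite (sd floor)."""
        samples, _, _ = tiny_world
        for month in sw.MONTHS:
            train = [s for s in samples if not s.is_test
                     and s.month_label == month]
            test = [s for s in samples if s.is_test and s.month_label == month]
            stats = em.NormStats.from_samples(train)
            assert np.all(stats.x_sd >= em.SD_FLOOR)
            for s in test:
                assert np.all(np.isfinite(em.assemble_predictors(s, stats)))

    def test_nan_rejected(self, jan_split):
        train, _ = jan_split
        stats = em.NormStats.from_samples(train)
        s = train[0]
        bad = sw.MonthSample(s.year_index, s.month_label, s.emissions.copy(),
                             s.met, s.truth)
        bad.emissions.land[0, 0, 0, 0] = np.nan
        with pytest.raises(em.EmulatorError):
            em.assemble_predictors(bad, stats)


class TestLrSchedule:
    def test_paper_defaults(self):
        assert em.lr_schedule(0) == pytest.approx(1.0e-4)
        assert em.lr_schedule(1) == pytest.approx(9.9e-5)
        assert em.lr_schedule(100) == pytest.approx(3.660e-5, abs=1e-8)

    def test_closed_form_everywhere(self):
        for it in (0, 7, 333, 1999):
            assert em.lr_schedule(it, 2e-3, 0.995) == \
                pytest.approx(2e-3 * 0.995 ** it)

    def test_negative_iteration_rejected(self):
        with pytest.raises(em.EmulatorError):
            em.lr_schedule(-1)


class TestMultitaskLoss:
    def test_zero_iff_equal(self, rng):
        y = rng.standard_normal((1, 10, 4, 4))
        loss, grad = em.multitask_loss_arrays(y, y.copy())
        assert loss == 0.0
        np.testing.assert_array_equal(grad, 0.0)
        loss2, _ = em.multitask_loss_arrays(y + 0.1, y)
        assert loss2 > 0

    def test_weight_masking(self, rng):
        truth = rng.standard_normal((1, 10, 4, 4))
        pred = truth.copy()
        pred[:, em._PM_IDX] += 1.0  # corrupt only PM2.5 maps
        loss, _ = em.multitask_loss_arrays(pred, truth, w_task1=1.0, w_task2=0.0)
        assert loss == pytest.approx(0.0)
        loss, _ = em.multitask_loss_arrays(pred, truth, w_task1=0.0, w_task2=1.0)
        assert loss > 0

    def test_brute_force_oracle_4x4(self, rng):
        """Loss equals an explicit loop over maps and cells."""
        pred = rng.standard_normal((2, 10, 4, 4))
        truth = rng.standard_normal((2, 10, 4, 4))
        w1, w2 = 0.7, 1.3
        comp_maps = [1, 2, 3, 4, 6, 7, 8, 9]
        pm_maps = [0, 5]
        se1, n1, se2, n2 = 0.0, 0, 0.0, 0
        for n in range(2):
            for k in range(10):
                for i in range(4):
                    for j in range(4):
                        d2 = (pred[n, k, i, j] - truth[n, k, i, j]) ** 2
                        if k in comp_maps:
                            se1 += d2
                            n1 += 1
                        else:
                            se2 += d2
                            n2 += 1
        expect = w1 * (se1 / n1) + w2 * (se2 / n2)
        loss, _ = em.multitask_loss_arrays(pred, truth, w1, w2)
        assert loss == pytest.approx(expect)

    def test_public_bundle_interface(self, jan_split):
        train, _ = jan_split
        truth = train[0].truth
        arr = em.raw_targets(truth)
        k = len(em.BRANCH_MAPS)
        bundle = em.PredictionBundle(
            shipping={m: arr[i] for i, m in enumerate(em.BRANCH_MAPS)},
            total={m: arr[k + i] for i, m in enumerate(em.BRANCH_MAPS)})
        assert em.multitask_loss(bundle, truth) == pytest.approx(0.0)

    def test_shape_mismatch(self, rng):
        with pytest.raises(em.EmulatorError):
            em.multitask_loss_arrays(rng.standard_normal((1, 10, 4, 4)),
                                     rng.standard_normal((1, 10, 5, 5)))


class TestPretrain:
    def test_deterministic_per_seed(self, jan_split):
        train, _ = jan_split
        cfg = em.TrainConfig(**FAST, seed=4)
        g1 = em.Generator(cfg.n_res_blocks, cfg.width, seed=cfg.seed)
        g2 = em.Generator(cfg.n_res_blocks, cfg.width, seed=cfg.seed)
        t1 = em.pretrain_generator(g1, train, cfg)
        t2 = em.pretrain_generator(g2, train, cfg)
        assert t1 == t2
        for a, b in zip(g1.params(), g2.params()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_zero_iters_leaves_generator_unchanged(self, jan_split):
        train, _ = jan_split
        cfg = em.TrainConfig(**{**FAST, "pretrain_iters": 0})
        gen = em.Generator(cfg.n_res_blocks, cfg.width, seed=0)
        before = [p.value.copy() for p in gen.params()]
        trace = em.pretrain_generator(gen, train, cfg)
        assert trace == []
        for p, b in zip(gen.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_loss_decreases_on_benchmark(self, jan_split):
        train, _ = jan_split
        cfg = em.TrainConfig(**{**FAST, "pretrain_iters": 30})
        gen = em.Generator(cfg.n_res_blocks, cfg.width, seed=1)
        trace = em.pretrain_generator(gen, train, cfg)
        assert np.mean(trace[-10:]) < np.mean(trace[:10])

    def test_requires_samples(self):
        cfg = em.TrainConfig(**FAST)
        gen = em.Generator(2, 8, seed=0)
        with pytest.raises(em.EmulatorError):
            em.pretrain_generator(gen, [], cfg)


class TestAdversarialTrain:
    def test_lr_trace_matches_schedule_and_caps(self, jan_split):
        train, _ = jan_split
        cfg = em.TrainConfig(**FAST, seed=2)
        gen = em.Generator(cfg.n_res_blocks, cfg.width, seed=2)
        disc = em.Discriminator(seed=2)
        trace, lrs, _ = em.adversarial_train(gen, disc, train, cfg)
        assert len(trace) <= cfg.formal_max_iters <= 2000
        expect = [em.lr_schedule(i, cfg.formal_lr0, cfg.lr_decay)
                  for i in range(len(lrs))]
        np.testing.assert_allclose(lrs, expect)
        assert np.all(np.diff(lrs) <= 0)

    def test_no_gan_reduction_ignores_discriminator(self, jan_split):
        """With w_adv=0 and a frozen D, the G trajectory is D-independent."""
        train, _ = jan_split
        cfg = em.TrainConfig(**{**FAST, "w_adv": 0.0}, seed=5)
        runs = []
        for d_seed in (1, 99):
            gen = em.Generator(cfg.n_res_blocks, cfg.width, seed=5)
            disc = em.Discriminator(seed=d_seed)
            d_before = [p.value.copy() for p in disc.params()]
            trace, _, _ = em.adversarial_train(gen, disc, train, cfg,
                                               train_discriminator=False)
            for p, b in zip(disc.params(), d_before):
                np.testing.assert_array_equal(p.value, b)  # D untouched
            runs.append(trace)
        assert runs[0] == runs[1]

    def test_early_stop_on_converged_loss(self, jan_split):
        train, _ = jan_split
        cfg = em.TrainConfig(**{**FAST, "formal_max_iters": 200,
                                "conv_window": 5, "conv_tol": 1e9}, seed=0)
        gen = em.Generator(cfg.n_res_blocks, cfg.width, seed=0)
        disc = em.Discriminator(seed=0)
        trace, _, _ = em.adversarial_train(gen, disc, train, cfg)
        assert len(trace) == 5  # stops as soon as the window fills

    def test_full_run_deterministic(self, jan_split):
        train, _ = jan_split
        cfg = em.TrainConfig(**FAST, seed=8)
        m1 = em.train_emulator(train, cfg)
        m2 = em.train_emulator(train, cfg)
        assert m1.formal_trace == m2.formal_trace
        for a, b in zip(m1.gen.params(), m2.gen.params()):
            np.testing.assert_array_equal(a.value, b.value)


@pytest.fixture(scope="module")
def model(jan_split):
    train, _ = jan_split
    cfg = em.TrainConfig(**FAST, seed=3)
    return em.train_emulator(train, cfg)


class TestPredict:
    def test_output_shape_matches_input(self, model, jan_split):
        _, test = jan_split
        pred = em.predict_shipping_pm(model, test)
        assert pred.shipping["pm25"].shape == test.met.ws10.shape
        assert set(pred.total) == set(em.BRANCH_MAPS)

    def test_inference_deterministic(self, model, jan_split):
        _, test = jan_split
        a = em.predict_shipping_pm(model, test)
        b = em.predict_shipping_pm(model, test)
        np.testing.assert_array_equal(a.shipping["pm25"], b.shipping["pm25"])

    def test_outputs_clipped_non_negative(self, model, jan_split):
        _, test = jan_split
        pred = em.predict_shipping_pm(model, test)
        assert np.all(pred.as_array() >= 0)

    def test_nan_weights_rejected(self, model, jan_split):
        _, test = jan_split
        import copy
        broken = copy.deepcopy(model)
        broken.gen.params()[0].value[0, 0] = np.nan
        with pytest.raises(em.EmulatorError):
            em.predict_shipping_pm(broken, test)

    def test_checkpoint_round_trip(self, model, jan_split, tmp_path):
        _, test = jan_split
        path = tmp_path / "ckpt.npz"
        em.save_emulator(path, model)
        loaded = em.load_emulator(path)
        a = em.predict_shipping_pm(model, test)
        b = em.predict_shipping_pm(loaded, test)
        np.testing.assert_array_equal(a.as_array(), b.as_array())
        assert loaded.cfg == model.cfg
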