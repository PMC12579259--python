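"""trainer: weighted cross-entropy loss, multitask combination, lambda schedule,
augmentation, prior masking, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catrace import trainer as tr
from catrace.network import ModelConfig, build_model, load_checkpoint
from catrace.struct_codec import LabelMasks


def _naive_weighted_ce(logits, labels, w):
    """Per-sample loop oracle for the weighted cross-entropy."""
    K = logits.shape[0]
    flat = logits.reshape(K, -1)
    y = labels.reshape(-1)
    total = 0.0
    for n in range(flat.shape[1]):
        x = flat[:, n].astype(np.float64)
        p = np.exp(x - x.max())
        p /= p.sum()
        total += -w[y[n]] * np.log(p[y[n]])
    return total / flat.shape[1]


class TestWeightedCrossEntropy:
    def test_two_class_uniform_logits(self):
        loss = tr.weighted_cross_entropy(np.zeros((2, 1)), np.array([0]),
                                         np.ones(2))
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-6)

    def test_confident_correct_logits_approach_zero(self):
        logits = np.zeros((3, 1))
        logits[1] = 50.0
        loss = tr.weighted_cross_entropy(logits, np.array([1]), np.ones(3))
        assert float(loss.data) < 1e-6

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (4, 5))
        y = rng.integers(0, 4, 5)
        w = rng.uniform(0.5, 2.0, 4)
        l1 = float(tr.weighted_cross_entropy(x, y, w).data)
        l2 = float(tr.weighted_cross_entropy(x, y, 2 * w).data)
        assert l2 == pytest.approx(2 * l1, rel=1e-5)

    def test_label_out_of_range_raises(self):
        with pytest.raises(ValueError):
            tr.weighted_cross_entropy(np.zeros((2, 1)), np.array([2]), np.ones(2))

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(0, 3, (3, 8))
            y = rng.integers(0, 3, 8)
            assert float(tr.weighted_cross_entropy(x, y, np.ones(3)).data) >= 0

    def test_absent_class_with_any_weight_is_finite(self):
        # class 2 never appears in the labels; its weight must not matter
        x = np.random.default_rng(2).normal(0, 1, (3, 6))
        y = np.array([0, 1, 0, 1, 0, 1])
        loss = tr.weighted_cross_entropy(x, y, np.array([1.0, 1.0, 1e9]))
        assert np.isfinite(float(loss.data))

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        shape = (2, 3, 4)
        x = rng.normal(0, 2, (K,) + shape).astype(np.float32)
        y = rng.integers(0, K, shape)
        w = rng.uniform(0.2, 3.0, K)
        ours = float(tr.weighted_cross_entropy(x, y, w).data)
        ref = _naive_weighted_ce(x, y, w)
        assert ours == pytest.approx(ref, abs=1e-6, rel=1e-5)


class TestMultitaskLoss:
    def _logits_labels(self):
        rng = np.random.default_rng(3)
        logits = (rng.normal(0, 1, (4, 2, 2, 2)).astype(np.float32),
                  rng.normal(0, 1, (4, 2, 2, 2)).astype(np.float32),
                  rng.normal(0, 1, (21, 2, 2, 2)).astype(np.float32))
        labels = (rng.integers(0, 4, (2, 2, 2)), rng.integers(0, 4, (2, 2, 2)),
                  rng.integers(0, 21, (2, 2, 2)))
        return logits, labels

    def test_convexity_identity(self):
        logits, _ = self._logits_labels()
        labels = tuple(np.zeros((2, 2, 2), dtype=int) for _ in range(3))
        # same logits+labels for all tasks of matching channel count would
        # be needed for exactly equal components; instead check lambdas (1,0,0)
        w = tr.LossWeights(1.0, 0.0, 0.0)
        total, (lb, lc, la) = tr.multitask_loss(logits, labels, w)
        assert float(total.data) == pytest.approx(float(lb.data), abs=1e-7)

    def test_weighted_combination_arithmetic(self):
        logits, labels = self._logits_labels()
        w = tr.LossWeights(0.25, 0.4, 0.35)
        total, (lb, lc, la) = tr.multitask_loss(logits, labels, w)
        expect = 0.25 * float(lb.data) + 0.4 * float(lc.data) + 0.35 * float(la.data)
        assert float(total.data) == pytest.approx(expect, rel=1e-6)

    def test_fixed_component_values(self):
        # lambdas (0.25, 0.4, 0.35) on component losses (1, 2, 3) -> 2.10
        assert 0.25 * 1 + 0.4 * 2 + 0.35 * 3 == pytest.approx(2.10)

    def test_invalid_lambdas_raise(self):
        with pytest.raises(tr.ConfigError):
            tr.LossWeights(0.5, 0.5, 0.5)


class TestLambdaSchedule:
    def test_endpoints(self):
        cfg = tr.TrainConfig()
        assert tr.lambda_schedule(1, cfg) == (0.6, 0.3, 0.1)
        assert tr.lambda_schedule(24, cfg) == (0.6, 0.3, 0.1)
        assert tr.lambda_schedule(25, cfg) == (0.25, 0.4, 0.35)
        assert tr.lambda_schedule(100, cfg) == (0.25, 0.4, 0.35)

    def test_always_sums_to_one(self):
        for ramp in (False, True):
            cfg = tr.TrainConfig(ramp=ramp)
            for epoch in range(1, 40):
                assert sum(tr.lambda_schedule(epoch, cfg)) == pytest.approx(1.0)

    def test_ramp_is_monotone_between_endpoints(self):
        cfg = tr.TrainConfig(ramp=True)
        lbs = [tr.lambda_schedule(e, cfg)[0] for e in range(19, 26)]
        assert lbs[0] == 0.6 and lbs[-1] == 0.25
        assert all(a >= b for a, b in zip(lbs, lbs[1:]))

    def test_epoch_zero_rejected(self):
        with pytest.raises(tr.ConfigError):
            tr.lambda_schedule(0, tr.TrainConfig())


def _marker_sample(n=12):
    d = np.zeros((1, n, n, n), np.float32)
    d[0, 3, 5, 7] = 1.0
    m = LabelMasks(np.zeros((n, n, n), np.int64),
                   np.zeros((n, n, n), np.int64),
                   np.zeros((n, n, n), np.int64))
    m.backbone[3, 5, 7] = 3
    p = np.zeros((24, n, n, n), np.float32)
    p[0, 3, 5, 7] = 1.0
    return d, p, m


class TestAugmentPair:
    def test_zero_magnitude_identity(self):
        d, p, m = _marker_sample()
        cfg = tr.TrainConfig(noise_sd=0, blur_sd_max=0, intensity_range=0,
                             max_shift=0, spatial_augment=False)
        d2, p2, m2 = tr.augment_pair(d, p, m, seed=0, config=cfg)
        np.testing.assert_array_equal(d2, d)
        np.testing.assert_array_equal(p2, p)
        np.testing.assert_array_equal(m2.backbone, m.backbone)

    def test_labels_move_with_density(self):
        d, p, m = _marker_sample()
        cfg = tr.TrainConfig(noise_sd=0, blur_sd_max=0, intensity_range=0,
                             max_shift=3)
        for seed in range(8):
            d2, p2, m2 = tr.augment_pair(d, p, m, seed=seed, config=cfg)
            peak = np.unravel_index(np.argmax(d2[0]), d2[0].shape)
            marks = np.argwhere(m2.backbone == 3)
            assert len(marks) <= 1
            if len(marks) == 1:  # marker may be shifted out of the volume
                assert tuple(marks[0]) == peak
                assert p2[0][peak] == 1.0

    def test_intensity_ops_do_not_touch_prior_or_masks(self):
        d, p, m = _marker_sample()
        cfg = tr.TrainConfig(noise_sd=0.1, blur_sd_max=1.0, intensity_range=0.3,
                             spatial_augment=False, max_shift=0)
        d2, p2, m2 = tr.augment_pair(d, p, m, seed=5, config=cfg)
        np.testing.assert_array_equal(p2, p)
        np.testing.assert_array_equal(m2.backbone, m.backbone)
        assert not np.array_equal(d2, d)

    def test_seeded_reproducibility(self):
        d, p, m = _marker_sample()
        a = tr.augment_pair(d, p, m, seed=9)
        b = tr.augment_pair(d, p, m, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2].amino, b[2].amino)


class TestMaskPrior:
    def test_never_and_always(self):
        p = np.ones((24, 2, 2, 2), np.float32)
        assert tr.mask_prior(p, 0, 0.0) is p
        assert tr.mask_prior(p, 0, 1.0) is None
        assert tr.mask_prior(None, 0, 0.5) is None

    def test_drop_fraction(self):
        p = np.ones(1)
        drops = sum(tr.mask_prior(p, s, 0.4) is None for s in range(10000))
        assert abs(drops / 10000 - 0.4) < 0.015

    def test_invalid_prob(self):
        with pytest.raises(tr.ConfigError):
            tr.mask_prior(np.ones(1), 0, 1.5)


class TestClassWeights:
    def test_mean_one_and_inverse_ordering(self):
        labels = np.array([0] * 90 + [1] * 9 + [2] * 1)
        w = tr.compute_class_weights([labels], 3)
        assert w.mean() == pytest.approx(1.0)
        assert w[0] < w[1] < w[2]

    def test_absent_class_gets_unit_weight(self):
        w = tr.compute_class_weights([np.array([0, 0, 1])], 4)
        assert w[2] == 1.0 and w[3] == 1.0
        assert np.all(w > 0)


def _tiny_dataset(rng, n=12, samples=2):
    out = []
    for _ in range(samples):
        d = rng.random((1, n, n, n), dtype=np.float32)
        m = LabelMasks(rng.integers(0, 4, (n, n, n)),
                       rng.integers(0, 4, (n, n, n)),
                       rng.integers(0, 21, (n, n, n)))
        out.append((d, None, m))
    return out


@pytest.fixture(scope="module")
def trained(tmp_path_factory):
    rng = np.random.default_rng(0)
    dataset = _tiny_dataset(rng)
    model = build_model(ModelConfig(width_scale=32), seed=0)
    ckpt = tmp_path_factory.mktemp("ckpt") / "model.npz"
    cfg = tr.TrainConfig(epochs=3, lr=1e-3, augment=False, mask_prob=1.0,
                         seed=0)
    state, history = tr.train(model, dataset, cfg, checkpoint_path=ckpt)
    return dataset, model, ckpt, cfg, history


class TestTrainLoop:
    def test_history_schema(self, trained):
        _, _, _, cfg, history = trained
        assert len(history) == cfg.epochs
        assert all({"epoch", "train_loss", "val_loss", "lr", "lambdas"}
                   <= set(h) for h in history)
        assert history[0]["lambdas"] == [0.6, 0.3, 0.1]

    def test_determinism(self, trained):
        dataset, _, _, cfg, history = trained
        model2 = build_model(ModelConfig(width_scale=32), seed=0)
        _, history2 = tr.train(model2, dataset, cfg)
        assert [h["train_loss"] for h in history] == \
               [h["train_loss"] for h in history2]

    def test_checkpoint_reload_reproduces_val_loss(self, trained):
        dataset, model, ckpt, cfg, history = trained
        model2, _ = load_checkpoint(ckpt)
        # with 2 samples and val_fraction 0.2 the validation set is the
        # whole dataset; recompute its loss with the final-epoch lambdas
        lb, lc, la = tr.lambda_schedule(len(history), cfg)
        cw_b = tr.compute_class_weights([s[2].backbone for s in dataset], 4)
        cw_c = tr.compute_class_weights([s[2].calpha for s in dataset], 4)
        cw_a = tr.compute_class_weights([s[2].amino for s in dataset], 21)
        w = tr.LossWeights(lb, lc, la, cw_b, cw_c, cw_a)
        model2.eval()
        losses = [float(tr._sample_loss(model2, d, p, m, w)[0].data)
                  for d, p, m in dataset]
        best_val = min(h["val_loss"] for h in history)
        assert np.mean(losses) == pytest.approx(best_val, abs=1e-6)

    def test_nan_loss_aborts_with_diagnostics(self):
        rng = np.random.default_rng(1)
        dataset = _tiny_dataset(rng, samples=1)
        bad = (np.full_like(dataset[0][0], np.inf), None, dataset[0][2])
        model = build_model(ModelConfig(width_scale=32), seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            tr.train(model, [bad], tr.TrainConfig(epochs=1, augment=False))

    def test_empty_dataset_rejected(self):
        model = build_model(ModelConfig(width_scale=32), seed=0)
        with pytest.raises(tr.ConfigError):
            tr.train(model, [], tr.TrainConfig(epochs=1))
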