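"""Training protocol: loss gradients, early stopping, reproducibility,
benchmark tables, Pareto report, and Grad-CAM."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

import uwunet.nn as nn
from uwunet import metrics
from uwunet.architectures import ArchitectureSpec, build_model
from uwunet.dataio import grouped_split
from uwunet.experiment import (TradeoffPoint, TrainConfig,
                               _hybrid_loss_and_grad, _sigmoid, benchmark,
                               evaluate, gradcam, green_report, run_experiment,
                               train)
from uwunet.phantom import PhantomConfig, generate_cohort_samples


def _tiny_cohort(n_patients=4, images=20, size=32, seed=0):
    cfg = dataclasses.replace(PhantomConfig().for_size(size),
                              n_patients=n_patients, seed=seed)
    return generate_cohort_samples(cfg, total_images=images)


def test_hybrid_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(2, 1, 6, 6))
    t = (rng.random((2, 1, 6, 6)) > 0.7).astype(np.float64)
    loss, grad = _hybrid_loss_and_grad(z, t)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (1, 0, 3, 2), (0, 0, 5, 5)]:
        zp, zm = z.copy(), z.copy()
        zp[idx] += eps
        zm[idx] -= eps
        fd = (_hybrid_loss_and_grad(zp, t)[0] - _hybrid_loss_and_grad(zm, t)[0]) / (2 * eps)
        assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)


def test_hybrid_loss_value_matches_metrics_module():
    rng = np.random.default_rng(1)
    z = rng.normal(size=(1, 1, 8, 8))
    t = (rng.random((1, 1, 8, 8)) > 0.7).astype(np.float64)
    loss, _ = _hybrid_loss_and_grad(z, t)
    p = _sigmoid(z)[0, 0]
    assert loss == pytest.approx(metrics.hybrid_loss(p, t[0, 0]), rel=1e-6)


def test_train_smoke_produces_finite_history(tiny_spec):
    cohort = _tiny_cohort()
    cfg = TrainConfig(batch_size=8, max_epochs=2, seed=0)
    split = grouped_split([m for _, m in cohort], 0.25, rng_seed=0)
    model = build_model(tiny_spec, rng=np.random.default_rng(0))
    model, history = train(model, cohort, split, cfg)
    assert history.epochs_run <= 2
    assert all(np.isfinite(v) for v in history.train_loss + history.val_loss)


def test_early_stopping_halts_after_patience_without_improvement(tiny_spec):
    cohort = _tiny_cohort()
    # a learning rate too small to move the validation loss by min_delta
    cfg = TrainConfig(learning_rate=1e-12, batch_size=8, max_epochs=10,
                      patience=1, min_delta=1e-4, seed=0)
    split = grouped_split([m for _, m in cohort], 0.25, rng_seed=0)
    model = build_model(tiny_spec, rng=np.random.default_rng(0))
    _, history = train(model, cohort, split, cfg)
    assert history.epochs_run == 1 + cfg.patience


def test_train_rejects_empty_training_fold(tiny_spec):
    cohort = _tiny_cohort()
    split = grouped_split([m for _, m in cohort], 0.25, rng_seed=0)
    empty = dataclasses.replace(split, train_patients=frozenset(),
                                test_patients=split.test_patients)
    with pytest.raises(ValueError, match="empty"):
        train(build_model(tiny_spec), cohort, empty, TrainConfig())


class _StubModel:
    """Deterministic predictor emitting fixed logits (no training)."""

    def __init__(self, masks, value):
        self.masks = list(masks)
        self.value = value

    def forward(self, x, train=False):
        n = x.shape[0]
        out = np.stack(self.masks[:n])[:, None].astype(np.float32)
        self.masks = self.masks[n:]
        return np.where(out > 0, self.value, -self.value)


def test_evaluate_perfect_and_empty_predictors():
    cohort = _tiny_cohort()
    samples = [s for s, _ in cohort]
    perfect = evaluate(_StubModel([s.mask for s in samples], 10.0), samples)
    assert perfect.mean_dice == pytest.approx(1.0)
    assert perfect.mean_iou == pytest.approx(1.0)

    zeros = evaluate(_StubModel([np.zeros_like(s.mask) for s in samples], 10.0),
                     samples)
    assert zeros.mean_dice == pytest.approx(0.0)  # |B|=0, |A|>0 per image

    with pytest.raises(ValueError):
        evaluate(_StubModel([], 1.0), [])


def test_evaluate_agrees_with_metric_functions(trained_tiny):
    model, result, _, cohort = trained_tiny
    from uwunet.experiment import predict
    test_samples = [s for s, _ in cohort][:4]
    preds = predict(model, test_samples)
    for s, p, got in zip(test_samples, preds,
                         evaluate(model, test_samples).dice_per_image):
        assert got == pytest.approx(metrics.dice(s.mask, p))


def test_run_experiment_is_seed_reproducible(tiny_spec):
    cohort = _tiny_cohort()
    cfg = TrainConfig(batch_size=8, max_epochs=2, seed=3)
    _, r1, _ = run_experiment(tiny_spec, cohort, cfg, test_fraction=0.25)
    _, r2, _ = run_experiment(tiny_spec, cohort, cfg, test_fraction=0.25)
    assert abs(r1.mean_dice - r2.mean_dice) <= 1e-6
    assert abs(r1.mean_iou - r2.mean_iou) <= 1e-6


def test_benchmark_emits_well_formed_tables(tiny_spec):
    cohort = _tiny_cohort(images=24)
    specs = [tiny_spec, ArchitectureSpec("tinier", base_width=4, depth=2)]
    cfg = TrainConfig(batch_size=8, max_epochs=2, seed=0)
    result = benchmark(specs, cohort, n_runs=2, base_seed=0, train_config=cfg,
                       test_fraction=0.25)
    assert len(result.per_run) == 4
    assert set(result.per_run.model) == {"tiny", "tinier"}
    assert ((0 <= result.per_run.mean_dice) & (result.per_run.mean_dice <= 1)).all()
    for _, row in result.aggregates.iterrows():
        assert row["min"] <= row["avg"] <= row["max"]
    from uwunet import complexity
    size = cohort[0][0].image.shape[0]
    for _, row in result.complexity_table.iterrows():
        rep = complexity.report(next(s for s in specs if s.name == row.model),
                                size, size)
        assert row.params_m == rep.total_params_m
        assert row.flops_g == rep.total_flops_g
    assert set(result.p_values.model) == {"tinier"}
    assert ((0 <= result.p_values.p_value) & (result.p_values.p_value <= 1)).all()


def test_green_report_pareto_flags():
    single = [TradeoffPoint("only", 0.9, 1000, 1e9)]
    rep = green_report(single)
    assert rep.pareto_params.all() and rep.pareto_flops.all()

    points = [
        TradeoffPoint("light", 0.90, 1_000, 1e9),
        TradeoffPoint("heavy-worse", 0.85, 10_000, 5e9),   # dominated
        TradeoffPoint("heavy-better", 0.95, 20_000, 8e9),  # efficient
    ]
    rep = green_report(points).set_index("model")
    assert rep.loc["light", "pareto_params"] and rep.loc["light", "pareto_flops"]
    assert not rep.loc["heavy-worse", "pareto_params"]
    assert not rep.loc["heavy-worse", "pareto_flops"]
    assert rep.loc["heavy-better", "pareto_params"]
    with pytest.raises(ValueError):
        green_report([])


def test_gradcam_contract_and_layer_validation(trained_tiny):
    model, _, _, cohort = trained_tiny
    image = cohort[0][0].image
    cam = gradcam(model, image)
    assert cam.shape == image.shape
    assert cam.min() >= 0.0 and cam.max() <= 1.0
    cam_deep = gradcam(model, image, layer_selector="down2")
    assert cam_deep.shape == image.shape
    with pytest.raises(KeyError, match="inc"):
        gradcam(model, image, layer_selector="nonexistent")
    with pytest.raises(ValueError):
        gradcam(model, np.zeros((2, 1, 32, 32)))


def test_gradcam_heat_concentrates_on_the_ring(trained_tiny):
    model, result, _, cohort = trained_tiny
    # pick a test-set-like sample; the fixture model is converged enough
    sample = cohort[0][0]
    cam = gradcam(model, sample.image)
    top = cam >= np.quantile(cam, 0.9)
    dilated = ndimage.binary_dilation(sample.mask, iterations=3)
    precision = (top & dilated).sum() / top.sum()
    assert precision >= 0.5


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(validation_fraction=1.0)
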