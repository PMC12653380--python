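"""Training protocol, multi-seed benchmarking, Green-AI trade-off report,
and Grad-CAM explanations.

The training loop follows the evaluation protocol of the study this
package reproduces: Adam on the equal-weight BCE + soft-Dice hybrid loss,
batch size 32, on-the-fly flip/rotation augmentation, a patient-level
90:10 train/test split, and early stopping on the hybrid loss of a
validation fold carved from the *training* patients (the test patients are
never touched during training).  A benchmark repeats this for several
seeds, re-drawing the patient split each run, and aggregates per-run mean
Dice/IoU into avg/min/max/std tables plus Welch-t p-values between
architectures.

Everything is deterministic given the config seed: weight initialization,
split, validation fold, shuffling, and augmentation all derive from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import complexity, metrics
from .architectures import ArchitectureSpec, UNet, build_model
from .dataio import AugmentConfig, Sample, SampleMeta, SplitPlan, augment, grouped_split
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "RunResult",
    "TradeoffPoint",
    "BenchmarkResult",
    "train",
    "evaluate",
    "run_experiment",
    "benchmark",
    "green_report",
    "gradcam",
]

EVAL_BATCH = 16


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10          # early-stopping patience, in epochs
    min_delta: float = 1e-4     # minimum validation-loss improvement
    validation_fraction: float = 0.1  # fraction of *train patients* held out
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_loss: list[float]
    epochs_run: int
    best_epoch: int             # 1-based epoch whose weights were restored


@dataclass
class RunResult:
    """Per-seed evaluation on the held-out test patients."""
    seed: int
    dice_per_image: list[float]
    iou_per_image: list[float]
    mean_dice: float
    mean_iou: float
    epochs_run: int = 0


@dataclass(frozen=True)
class TradeoffPoint:
    """(model, accuracy, cost) point for the Green-AI trade-off report."""
    name: str
    mean_dice: float
    total_params: int
    total_flops: float


@dataclass
class BenchmarkResult:
    per_run: pd.DataFrame        # model, seed, mean_dice, mean_iou, epochs_run
    aggregates: pd.DataFrame     # model, metric, avg, min, max, std_dev
    complexity_table: pd.DataFrame  # model, params_m, flops_g
    p_values: pd.DataFrame       # model, metric, p_value (vs the first model)
    tradeoff: list[TradeoffPoint]


def _stack(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples])[:, None].astype(np.float32)
    t = np.stack([s.mask for s in samples])[:, None].astype(np.float32)
    return x, t


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _hybrid_loss_and_grad(z: np.ndarray, t: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Equal-weight BCE + soft-Dice loss on logits, with its gradient.

    BCE uses the numerically stable log-sum-exp form; the Dice term is
    computed per image (smoothing 1) and averaged over the batch, matching
    the values of :mod:`uwunet.metrics` on the sigmoid probabilities.
    """
    n = z.shape[0]
    p = _sigmoid(z)
    # BCE: mean over all pixels of softplus(z) - z*t
    softplus = np.logaddexp(0.0, z)
    bce = float((softplus - z * t).mean())
    ax = (1, 2, 3)
    num = 2.0 * (p * t).sum(axis=ax) + metrics.DICE_SMOOTHING
    den = p.sum(axis=ax) + t.sum(axis=ax) + metrics.DICE_SMOOTHING
    dice_loss = float((1.0 - num / den).mean())
    loss = 0.5 * bce + 0.5 * dice_loss

    grad = 0.5 * (p - t) / z.size
    den_ = den[:, None, None, None]
    num_ = num[:, None, None, None]
    ddice_dp = -(2.0 * t * den_ - num_) / (den_ * den_)
    grad += 0.5 * ddice_dp * p * (1.0 - p) / n
    return loss, grad.astype(np.float32)


def _validation_patients(train_patients: frozenset[str], fraction: float,
                         seed: int) -> frozenset[str]:
    patients = sorted(train_patients)
    if fraction <= 0 or len(patients) < 2:
        return frozenset()
    n_val = max(1, int(np.floor(fraction * len(patients) + 0.5)))
    n_val = min(n_val, len(patients) - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    return frozenset(patients[i] for i in order[:n_val])


def _mean_val_loss(model: UNet, samples: list[Sample]) -> float:
    total, npix = 0.0, 0
    for i in range(0, len(samples), EVAL_BATCH):
        x, t = _stack(samples[i:i + EVAL_BATCH])
        z = model.forward(x, train=False)
        loss, _ = _hybrid_loss_and_grad(z, t)
        total += loss * x.shape[0]
        npix += x.shape[0]
    return total / npix


def train(model: UNet, cohort: list[tuple[Sample, SampleMeta]],
          split: SplitPlan, config: TrainConfig
          ) -> tuple[UNet, TrainHistory]:
    """Train ``model`` on the split's training patients.

    A validation fold (``validation_fraction`` of the train patients) is
    carved out to drive early stopping on the hybrid loss; the best
    validation weights (including batch-norm running statistics) are
    restored before returning.  Augmentation is applied afresh every epoch.
    Raises on an empty training fold and aborts if the loss goes
    non-finite.
    """
    val_patients = _validation_patients(split.train_patients,
                                        config.validation_fraction, config.seed)
    fit_patients = split.train_patients - val_patients
    fit = [s for s, m in cohort if m.patient_id in fit_patients]
    val = [s for s, m in cohort if m.patient_id in val_patients]
    if not fit:
        raise ValueError("training fold is empty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory([], [], 0, 0)
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(fit))
        augmented = [augment(fit[i], config.augment, rng) for i in order]
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(augmented), config.batch_size):
            x, t = _stack(augmented[i:i + config.batch_size])
            z = model.forward(x, train=True)
            loss, grad = _hybrid_loss_and_grad(z, t)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss={loss}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)
        monitor = _mean_val_loss(model, val) if val else history.train_loss[-1]
        history.val_loss.append(monitor)
        history.epochs_run = epoch

        if monitor < best_val - config.min_delta:
            best_val = monitor
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def predict(model: UNet, samples: list[Sample]) -> list[np.ndarray]:
    """Binary mask predictions (sigmoid then 0.5 threshold), batched."""
    preds: list[np.ndarray] = []
    for i in range(0, len(samples), EVAL_BATCH):
        x, _ = _stack(samples[i:i + EVAL_BATCH])
        z = model.forward(x, train=False)
        preds.extend(metrics.binarize(_sigmoid(z[j, 0])) for j in range(z.shape[0]))
    return preds


def evaluate(model: UNet, test_samples: list[Sample], seed: int = 0,
             epochs_run: int = 0) -> RunResult:
    """Per-image Dice/IoU of the model's thresholded predictions."""
    if not test_samples:
        raise ValueError("test set is empty")
    preds = predict(model, test_samples)
    dice = [metrics.dice(s.mask, p) for s, p in zip(test_samples, preds)]
    iou = [metrics.iou(s.mask, p) for s, p in zip(test_samples, preds)]
    return RunResult(seed=seed, dice_per_image=dice, iou_per_image=iou,
                     mean_dice=float(np.mean(dice)), mean_iou=float(np.mean(iou)),
                     epochs_run=epochs_run)


def run_experiment(spec: ArchitectureSpec, cohort: list[tuple[Sample, SampleMeta]],
                   config: TrainConfig, test_fraction: float = 0.1
                   ) -> tuple[UNet, RunResult, TrainHistory]:
    """One full run: seeded split, build, train, evaluate on test patients."""
    metas = [m for _, m in cohort]
    split = grouped_split(metas, test_fraction=test_fraction, rng_seed=config.seed)
    model = build_model(spec, rng=np.random.default_rng(config.seed))
    model, history = train(model, cohort, split, config)
    test = [s for s, m in cohort if m.patient_id in split.test_patients]
    result = evaluate(model, test, seed=config.seed, epochs_run=history.epochs_run)
    return model, result, history


def benchmark(specs: list[ArchitectureSpec], cohort: list[tuple[Sample, SampleMeta]],
              n_runs: int = 10, base_seed: int = 0,
              train_config: TrainConfig | None = None,
              test_fraction: float = 0.1) -> BenchmarkResult:
    """Multi-seed comparison of several architectures on one cohort.

    Each run uses seed ``base_seed + run_index`` for initialization *and*
    for re-drawing the patient-level split, so runs differ in both weights
    and data partition.  Emits per-run rows, avg/min/max/std aggregates,
    the analytic complexity table at the cohort's image size, Welch-t
    p-values of every architecture against the first, and trade-off points
    for :func:`green_report`.
    """
    if n_runs < 2:
        raise ValueError("benchmark requires n_runs >= 2")
    base_config = train_config or TrainConfig()
    size = cohort[0][0].image.shape[0]
    per_run_rows, agg_rows, cx_rows, p_rows = [], [], [], []
    points: list[TradeoffPoint] = []
    means: dict[str, dict[str, list[float]]] = {}
    for spec in specs:
        dices, ious = [], []
        for run in range(n_runs):
            cfg = dataclasses.replace(base_config, seed=base_seed + run)
            _, result, history = run_experiment(spec, cohort, cfg,
                                                test_fraction=test_fraction)
            per_run_rows.append((spec.name, result.seed, result.mean_dice,
                                 result.mean_iou, result.epochs_run))
            dices.append(result.mean_dice)
            ious.append(result.mean_iou)
        means[spec.name] = {"dice": dices, "iou": ious}
        for metric_name, values in (("dice", dices), ("iou", ious)):
            st = metrics.aggregate(values)
            agg_rows.append((spec.name, metric_name, st.avg, st.min, st.max,
                             st.std_dev))
        rep = complexity.report(spec, size, size)
        cx_rows.append((spec.name, rep.total_params_m, rep.total_flops_g))
        points.append(TradeoffPoint(spec.name, float(np.mean(dices)),
                                    rep.total_params, rep.total_flops))
    first = specs[0].name
    for spec in specs[1:]:
        for metric_name in ("dice", "iou"):
            p = metrics.compare_runs(means[first][metric_name],
                                     means[spec.name][metric_name])
            p_rows.append((spec.name, metric_name, p))
    return BenchmarkResult(
        per_run=pd.DataFrame(per_run_rows, columns=["model", "seed", "mean_dice",
                                                    "mean_iou", "epochs_run"]),
        aggregates=pd.DataFrame(agg_rows, columns=["model", "metric", "avg",
                                                   "min", "max", "std_dev"]),
        complexity_table=pd.DataFrame(cx_rows, columns=["model", "params_m",
                                                        "flops_g"]),
        p_values=pd.DataFrame(p_rows, columns=["model", "metric", "p_value"]),
        tradeoff=points,
    )


def green_report(points: list[TradeoffPoint]) -> pd.DataFrame:
    """Tag each trade-off point as Pareto-efficient or dominated.

    A point is dominated on an axis (parameters or FLOPs) if some other
    point is at least as accurate and strictly cheaper, or strictly more
    accurate and at least as cheap; Pareto-efficient otherwise.  The most
    sustainable model is the efficient one nearest the top-left corner of
    the accuracy-vs-cost plane.
    """
    if not points:
        raise ValueError("green_report requires at least one point")

    def efficient(p: TradeoffPoint, cost: str) -> bool:
        for q in points:
            if q is p:
                continue
            cq, cp = getattr(q, cost), getattr(p, cost)
            if ((q.mean_dice >= p.mean_dice and cq < cp)
                    or (q.mean_dice > p.mean_dice and cq <= cp)):
                return False
        return True

    return pd.DataFrame(
        [(p.name, p.mean_dice, p.total_params, p.total_flops,
          efficient(p, "total_params"), efficient(p, "total_flops"))
         for p in points],
        columns=["model", "mean_dice", "total_params", "total_flops",
                 "pareto_params", "pareto_flops"],
    )


def gradcam(model: UNet, image: np.ndarray,
            layer_selector: str | None = None) -> np.ndarray:
    """Gradient-weighted class-activation map for one image.

    The score is the sum of logits over the predicted foreground (all
    logits if nothing is predicted); its gradient is taken at the selected
    stage (default: the last decoder double-conv block), channel-averaged
    into weights, combined with the activations, rectified, bilinearly
    upsampled to the input size, and min–max normalized to [0, 1].  A map
    that is identically zero (vanishing gradients) is returned as-is.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("gradcam expects a single 2-D grayscale image")
    target = layer_selector or f"up{model.spec.depth}"
    valid = model.stage_names()
    if target not in valid:
        raise KeyError(f"unknown layer {target!r}; valid stages: {valid}")

    z = model.forward(image[None, None], train=False)
    fg = z >= 0.0  # sigmoid(z) >= 0.5
    score_grad = fg.astype(np.float32) if fg.any() else np.ones_like(z)
    for p in model.parameters():
        p.grad[...] = 0.0
    model.backward(score_grad)

    # stage tensors are channel-major (C, N, H, W); take the single batch item
    acts = model.stage_outputs[target][:, 0]
    grads = model.stage_grads[target][:, 0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    zoom = (image.shape[0] / cam.shape[0], image.shape[1] / cam.shape[1])
    cam = ndimage.zoom(cam, zoom, order=1)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    return cam.astype(np.float32)
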