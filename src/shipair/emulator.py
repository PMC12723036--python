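"""Adversarially trained multi-task convolutional source-apportionment emulator.

The generator is a residual CNN mapping a 14-channel predictor stack (five
land emission species totals, four shipping emission species totals, five
meteorological fields) to two 5-map output branches: shipping-related PM2.5
with its four components, and total PM2.5 with its four components.  A small
strided-conv binary discriminator distinguishes emulated from surrogate-truth
shipping PM2.5 maps; its adversarial signal sharpens the generator's
sensitivity to the small shipping source.

Training is two-stage: a generator-only pre-training phase at fixed learning
rate, then formal adversarial training with a geometrically decaying rate and
an early stop when the multi-task loss stabilizes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .synthetic_world import (COMPONENTS, LAND_SPECIES, SHIP_SPECIES,
                              MetBundle, MonthSample, SourcePMBundle)

N_CHANNELS = len(LAND_SPECIES) + len(SHIP_SPECIES) + len(MetBundle.FIELDS)  # 14
#: Output map order for each branch: PM2.5 followed by the four components.
BRANCH_MAPS = ("pm25",) + COMPONENTS
N_OUTPUTS = 2 * len(BRANCH_MAPS)  # 10
SD_FLOOR = 1e-6


class EmulatorError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Two-stage training hyper-parameters (see module docstring)."""

    pretrain_iters: int = 100
    pretrain_lr: float = 1e-4
    formal_max_iters: int = 2000
    formal_lr0: float = 1e-4
    lr_decay: float = 0.99
    w_task1: float = 1.0   # component-map loss weight
    w_task2: float = 1.0   # PM2.5-map loss weight
    w_adv: float = 0.01    # generator adversarial-term weight
    conv_window: int = 50
    conv_tol: float = 1e-3
    n_res_blocks: int = 8
    width: int = 32
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.lr_decay < 1.0):
            raise EmulatorError("lr_decay must lie in (0, 1)")
        for name in ("pretrain_lr", "formal_lr0"):
            if getattr(self, name) <= 0:
                raise EmulatorError(f"{name} must be positive")
        if self.pretrain_iters < 0 or self.formal_max_iters < 0:
            raise EmulatorError("iteration counts must be non-negative")


@dataclass
class NormStats:
    """Per-channel standardization statistics, estimated on training data only."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray

    @classmethod
    def from_samples(cls, train_samples: Sequence[MonthSample]) -> "NormStats":
        X = np.stack([raw_predictors(s) for s in train_samples])
        Y = np.stack([raw_targets(s.truth) for s in train_samples])
        return cls(
            x_mean=X.mean(axis=(0, 2, 3)),
            x_sd=np.maximum(X.std(axis=(0, 2, 3)), SD_FLOOR),
            y_mean=Y.mean(axis=(0, 2, 3)),
            y_sd=np.maximum(Y.std(axis=(0, 2, 3)), SD_FLOOR),
        )


@dataclass
class PredictionBundle:
    """Emulator output: shipping and total PM2.5, each with four components."""

    shipping: dict
    total: dict

    def as_array(self) -> np.ndarray:
        return np.stack([self.shipping[k] for k in BRANCH_MAPS] +
                        [self.total[k] for k in BRANCH_MAPS])


def raw_predictors(sample: MonthSample) -> np.ndarray:
    """Unstandardized (14, ny, nx) predictor stack in the fixed channel order."""
    chans = [sample.emissions.land_species(s) for s in LAND_SPECIES]
    chans += [sample.emissions.shipping_species(s) for s in SHIP_SPECIES]
    chans += [getattr(sample.met, f) for f in MetBundle.FIELDS]
    return np.stack(chans)


def raw_targets(truth: SourcePMBundle) -> np.ndarray:
    """(10, ny, nx) truth stack: shipping branch then total branch."""
    ship = [truth.shipping_pm25()] + [truth.shipping_component(c) for c in COMPONENTS]
    tot = [truth.total_pm25()] + [truth.total_component(c) for c in COMPONENTS]
    return np.stack(ship + tot)


def assemble_predictors(sample: MonthSample, stats: NormStats) -> np.ndarray:
    """Standardized predictor stack ((x - mean)/sd, sd floored)."""
    x = raw_predictors(sample)
    if not np.all(np.isfinite(x)):
        raise EmulatorError("non-finite values in predictors")
    return (x - stats.x_mean[:, None, None]) / stats.x_sd[:, None, None]


def destandardize_outputs(y: np.ndarray, stats: NormStats) -> np.ndarray:
    return y * stats.y_sd[:, None, None] + stats.y_mean[:, None, None]


def lr_schedule(iteration: int, lr0: float = 1e-4, decay: float = 0.99) -> float:
    """Formal-stage learning rate: lr0 * decay**iteration."""
    if iteration < 0:
        raise EmulatorError("iteration must be non-negative")
    return lr0 * decay ** iteration


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class Generator:
    """Residual CNN with a shared trunk and two identical output branches."""

    def __init__(self, n_res_blocks: int = 8, width: int = 32, seed: int = 0):
        rng = np.random.default_rng([int(seed), 101])
        w = width
        # No normalization on the stem: the trunk input must retain the
        # absolute amplitude of the emission channels, otherwise uniform
        # emission scaling (the scenario operation) is invisible to the net.
        # Norm layers live inside the residual blocks, where the identity
        # skip preserves amplitude.
        self.stem = nn.Sequential(
            nn.Conv2d(N_CHANNELS, w, rng=rng, name="stem"),
            nn.ReLU(),
            *[nn.ResBlock(w, rng, name=f"res{i}") for i in range(n_res_blocks)],
        )
        self.branch1 = nn.Sequential(  # shipping-related PM2.5 + components
            nn.Conv2d(w, w, rng=rng, name="b1.c1"), nn.ReLU(),
            nn.Conv2d(w, len(BRANCH_MAPS), rng=rng, name="b1.c2"),
        )
        self.branch2 = nn.Sequential(  # total PM2.5 + components
            nn.Conv2d(w, w, rng=rng, name="b2.c1"), nn.ReLU(),
            nn.Conv2d(w, len(BRANCH_MAPS), rng=rng, name="b2.c2"),
        )
        self.n_res_blocks, self.width = n_res_blocks, width

    def params(self):
        return self.stem.params() + self.branch1.params() + self.branch2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 14, H, W) -> (N, 10, H, W): branch 1 maps then branch 2 maps."""
        h = self.stem.forward(x)
        return np.concatenate([self.branch1.forward(h), self.branch2.forward(h)],
                              axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = len(BRANCH_MAPS)
        dh = self.branch1.backward(dy[:, :k]) + self.branch2.backward(dy[:, k:])
        return self.stem.backward(dh)


class Discriminator:
    """Strided-conv binary classifier on single-channel concentration maps."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng([int(seed), 202])
        self.net = nn.Sequential(
            nn.Conv2d(1, 8, stride=2, rng=rng, name="d1"), nn.LeakyReLU(),
            nn.Conv2d(8, 16, stride=2, rng=rng, name="d2"), nn.LeakyReLU(),
            nn.Conv2d(16, 16, stride=2, rng=rng, name="d3"), nn.LeakyReLU(),
            nn.Conv2d(16, 32, stride=2, rng=rng, name="d4"), nn.LeakyReLU(),
            nn.GlobalAvgPool(),
            nn.Linear(32, 1, rng=rng, name="dfc"),
        )

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) -> (N,) real/fake logits."""
        return self.net.forward(x)[:, 0]

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogit[:, None])

    def prob(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward(x))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_COMP_IDX = [i for i, m in enumerate(BRANCH_MAPS + BRANCH_MAPS) if m != "pm25"]
_PM_IDX = [i for i, m in enumerate(BRANCH_MAPS + BRANCH_MAPS) if m == "pm25"]


def _mse_and_grad(pred: np.ndarray, truth: np.ndarray, idx, weight: float):
    err = pred[:, idx] - truth[:, idx]
    n = err.size
    loss = float(np.mean(err ** 2))
    grad = np.zeros_like(pred)
    grad[:, idx] = weight * 2.0 * err / n
    return loss, grad


def multitask_loss_arrays(pred: np.ndarray, truth: np.ndarray,
                          w_task1: float = 1.0, w_task2: float = 1.0):
    """Weighted multi-task loss on stacked (N, 10, H, W) arrays.

    Task 1 is the mean-squared error over the eight component maps; Task 2
    over the two PM2.5 maps.  Returns (loss, dloss/dpred).
    """
    if pred.shape != truth.shape:
        raise EmulatorError(f"shape mismatch {pred.shape} vs {truth.shape}")
    l1, g1 = _mse_and_grad(pred, truth, _COMP_IDX, w_task1)
    l2, g2 = _mse_and_grad(pred, truth, _PM_IDX, w_task2)
    return w_task1 * l1 + w_task2 * l2, g1 + g2


def multitask_loss(pred: PredictionBundle, truth: SourcePMBundle,
                   w_task1: float = 1.0, w_task2: float = 1.0) -> float:
    """Public multi-task loss on physical-unit prediction/truth bundles."""
    loss, _ = multitask_loss_arrays(pred.as_array()[None],
                                    raw_targets(truth)[None], w_task1, w_task2)
    return loss


def _bce_with_logits(logits: np.ndarray, target: float):
    """Mean binary cross-entropy; returns (loss, dloss/dlogits)."""
    # softplus(-z) for target 1, softplus(z) for target 0, numerically stable
    z = logits
    loss = float(np.mean(np.logaddexp(0.0, z) - target * z))
    grad = (_sigmoid(z) - target) / z.size
    return loss, grad


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedEmulator:
    """A trained generator with its normalization statistics and provenance."""

    gen: Generator
    stats: NormStats
    cfg: TrainConfig
    month: Optional[str] = None
    pretrain_trace: list = field(default_factory=list)
    formal_trace: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)


def _training_arrays(train_samples, stats):
    X = np.stack([assemble_predictors(s, stats) for s in train_samples])
    Y = np.stack([(raw_targets(s.truth) - stats.y_mean[:, None, None]) /
                  stats.y_sd[:, None, None] for s in train_samples])
    return X, Y


def pretrain_generator(gen: Generator, train_samples: Sequence[MonthSample],
                       cfg: TrainConfig, stats: Optional[NormStats] = None):
    """Generator-only stage: fixed learning rate, full-batch Adam steps.

    Returns the loss trace; the generator is modified in place and the
    discriminator is untouched (it does not exist yet at this stage).
    """
    cfg.validate()
    if len(train_samples) == 0:
        raise EmulatorError("need at least one training sample")
    stats = stats or NormStats.from_samples(train_samples)
    X, Y = _training_arrays(train_samples, stats)
    opt = nn.Adam(gen.params())
    trace = []
    for _ in range(cfg.pretrain_iters):
        pred = gen.forward(X)
        loss, grad = multitask_loss_arrays(pred, Y, cfg.w_task1, cfg.w_task2)
        if not np.isfinite(loss):
            raise EmulatorError("pre-training diverged (non-finite loss)")
        opt.zero_grad()
        gen.backward(grad)
        opt.step(cfg.pretrain_lr)
        trace.append(loss)
    return trace


def _converged(trace, window, tol):
    if len(trace) < window:
        return False
    recent = trace[-window:]
    hi = max(recent)
    return hi > 0 and (hi - min(recent)) / hi < tol


def adversarial_train(gen: Generator, disc: Optional[Discriminator],
                      train_samples: Sequence[MonthSample], cfg: TrainConfig,
                      stats: Optional[NormStats] = None,
                      train_discriminator: bool = True):
    """Formal stage: alternating discriminator / generator updates.

    Each iteration takes one full-batch discriminator step (binary
    cross-entropy, real vs emulated shipping-PM2.5 maps) and one generator
    step (multi-task loss plus ``w_adv`` times the generator adversarial
    term), both at the decayed learning rate.  Stops at ``formal_max_iters``
    or earlier once the multi-task loss is stable over the convergence
    window.  Returns ``(multitask_trace, lr_trace, disc_trace)``.
    """
    cfg.validate()
    if len(train_samples) == 0:
        raise EmulatorError("need at least one training sample")
    stats = stats or NormStats.from_samples(train_samples)
    X, Y = _training_arrays(train_samples, stats)
    real_maps = Y[:, 0:1]  # standardized shipping PM2.5 truth maps
    g_opt = nn.Adam(gen.params())
    d_opt = nn.Adam(disc.params()) if disc is not None else None
    use_adv = cfg.w_adv != 0.0 and disc is not None

    trace, lr_trace, d_trace = [], [], []
    d_acc_window = []
    for it in range(cfg.formal_max_iters):
        lr = lr_schedule(it, cfg.formal_lr0, cfg.lr_decay)
        lr_trace.append(lr)

        pred = gen.forward(X)
        fake_maps = pred[:, 0:1]

        if disc is not None and train_discriminator:
            logits_real = disc.forward(real_maps)
            lr_loss, g_real = _bce_with_logits(logits_real, 1.0)
            disc.backward(g_real)  # accumulate real-batch grads
            logits_fake = disc.forward(fake_maps)
            lf_loss, g_fake = _bce_with_logits(logits_fake, 0.0)
            disc.backward(g_fake)
            d_opt.step(lr)
            d_opt.zero_grad()
            d_trace.append(0.5 * (lr_loss + lf_loss))
            acc = 0.5 * (float(np.mean(logits_real > 0)) +
                         float(np.mean(logits_fake <= 0)))
            d_acc_window.append(acc)
            if len(d_acc_window) >= cfg.conv_window and \
                    min(d_acc_window[-cfg.conv_window:]) >= 1.0:
                warnings.warn("discriminator accuracy pinned at 1.0 "
                              "(possible collapse)", RuntimeWarning)
                d_acc_window.clear()

        loss, grad = multitask_loss_arrays(pred, Y, cfg.w_task1, cfg.w_task2)
        if use_adv:
            for p in disc.params():
                p.grad[...] = 0.0
            logits = disc.forward(fake_maps)
            _, dlogit = _bce_with_logits(logits, 1.0)  # generator wants "real"
            dfake = disc.backward(dlogit)
            for p in disc.params():  # generator step must not move D
                p.grad[...] = 0.0
            grad[:, 0:1] += cfg.w_adv * dfake
        if not np.isfinite(loss):
            raise EmulatorError("formal training diverged (non-finite loss)")
        g_opt.zero_grad()
        gen.backward(grad)
        g_opt.step(lr)
        trace.append(loss)

        if _converged(trace, cfg.conv_window, cfg.conv_tol):
            break
    return trace, lr_trace, d_trace


def train_emulator(train_samples: Sequence[MonthSample], cfg: TrainConfig,
                   month: Optional[str] = None,
                   with_discriminator: bool = True) -> TrainedEmulator:
    """Convenience wrapper running both stages on one month's samples."""
    if month is not None:
        train_samples = [s for s in train_samples if s.month_label == month]
    stats = NormStats.from_samples(train_samples)
    gen = Generator(cfg.n_res_blocks, cfg.width, seed=cfg.seed)
    disc = Discriminator(seed=cfg.seed) if with_discriminator else None
    pre = pretrain_generator(gen, train_samples, cfg, stats)
    formal, lrs, dtr = adversarial_train(gen, disc, train_samples, cfg, stats,
                                         train_discriminator=with_discriminator)
    return TrainedEmulator(gen=gen, stats=stats, cfg=cfg, month=month,
                           pretrain_trace=pre, formal_trace=formal,
                           lr_trace=lrs)


def save_emulator(path, model: TrainedEmulator) -> None:
    """Checkpoint: weights plus embedded config/stats (npz container)."""
    import json

    cfg_json = json.dumps({
        "cfg": dataclasses.asdict(model.cfg), "month": model.month,
        "pretrain_trace": model.pretrain_trace,
        "formal_trace": model.formal_trace, "lr_trace": model.lr_trace,
    })
    arrays = {f"p{i}": p.value for i, p in enumerate(model.gen.params())}
    arrays.update(x_mean=model.stats.x_mean, x_sd=model.stats.x_sd,
                  y_mean=model.stats.y_mean, y_sd=model.stats.y_sd)
    np.savez(path, meta=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **arrays)


def load_emulator(path) -> TrainedEmulator:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = TrainConfig(**meta["cfg"])
        gen = Generator(cfg.n_res_blocks, cfg.width, seed=cfg.seed)
        for i, p in enumerate(gen.params()):
            p.value[...] = z[f"p{i}"]
        stats = NormStats(x_mean=z["x_mean"], x_sd=z["x_sd"],
                          y_mean=z["y_mean"], y_sd=z["y_sd"])
    return TrainedEmulator(gen=gen, stats=stats, cfg=cfg, month=meta["month"],
                           pretrain_trace=meta["pretrain_trace"],
                           formal_trace=meta["formal_trace"],
                           lr_trace=meta["lr_trace"])


def predict_shipping_pm(model: TrainedEmulator,
                        sample: MonthSample) -> PredictionBundle:
    """Deterministic inference; outputs de-standardized and clipped at zero."""
    for p in model.gen.params():
        if not np.all(np.isfinite(p.value)):
            raise EmulatorError("generator has non-finite weights")
    x = assemble_predictors(sample, model.stats)
    y = model.gen.forward(x[None])[0]
    y = np.clip(destandardize_outputs(y, model.stats), 0.0, None)
    k = len(BRANCH_MAPS)
    ship = {m: y[i] for i, m in enumerate(BRANCH_MAPS)}
    tot = {m: y[k + i] for i, m in enumerate(BRANCH_MAPS)}
    return PredictionBundle(shipping=ship, total=tot)
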