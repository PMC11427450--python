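"""Droplet-state semantic segmentation: model, Dice loss, training, inference.

The network is built by :func:`build_model` from a :class:`ModelSpec`;
training minimizes the Dice loss

    loss = 1 - 2 |x ∩ y| / (|x| + |y|)

averaged over the foreground state classes (background is excluded — droplet
scenes are overwhelmingly background, and Dice is the standard remedy for
that class imbalance), with Adam under a cosine-annealing learning-rate
schedule restarting every 5 epochs.  Inference resizes any RGB frame to the
working resolution (bilinear), runs the network, takes the per-pixel argmax
(ties break to the lowest class id) and resizes the mask back (nearest).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import Adam, DropletNet, cosine_annealing_lr
from .states import FOREGROUND_CLASSES, NUM_CLASSES

DICE_SMOOTH = 1e-6


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    The encoder stacks four convolution blocks (two shallow blocks of 2
    conv layers, two deep blocks of 3), widths doubling per block from
    ``base_width``; the decoder holds 8 convolution layers over four direct
    twofold-upsampling stages; the head is a 1x1 convolution with 5 channels.
    ``width_scale`` shrinks every width proportionally for desk-scale runs.
    """

    in_channels: int = 3
    num_classes: int = NUM_CLASSES
    base_width: int = 64
    width_scale: float = 1.0
    working_resolution: int = 512
    upsample_mode: str = "nearest"
    #: "group" adds group normalization between each conv and its ReLU
    #: (a trainability aid for short schedules); "none" gives the plain
    #: conv + ReLU stacks.
    normalization: str = "group"

    def __post_init__(self) -> None:
        if self.num_classes != NUM_CLASSES:
            raise ValueError("the droplet-state head has exactly 5 classes")
        if self.in_channels != 3:
            raise ValueError("the network consumes RGB input")
        if self.working_resolution % 16:
            raise ValueError("working_resolution must be divisible by 2^4 "
                             "(four pooling stages)")


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    min_learning_rate: float = 1e-6
    scheduler_period: int = 5
    #: per-cycle decay of the restart peak (1.0 = plain warm restarts)
    restart_decay: float = 1.0
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    #: weight of the auxiliary per-pixel cross-entropy added to the Dice
    #: objective during optimization (0 disables it); loss values recorded
    #: in the history are always the pure Dice term
    aux_ce_weight: float = 1.0
    #: stop once validation mIoU has held at or above this level for
    #: ``patience`` consecutive epochs (convergence shortcut; set to a value
    #: > 1 to disable).
    early_stop_miou: float = 0.98
    patience: int = 2
    #: also stop when the best validation mIoU has not improved by at least
    #: 0.003 for this many epochs (0 disables); the restarting schedule
    #: oscillates within cycles, so the window should span a full cycle
    plateau_patience: int = 0
    #: restore the weights of the best-validation-mIoU epoch when done
    restore_best: bool = True

    def __post_init__(self) -> None:
        if self.min_learning_rate > self.learning_rate:
            raise ValueError("min_learning_rate must be <= learning_rate")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_miou: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    #: epoch index whose weights the trained network carries (best
    #: validation mIoU when ``restore_best``, else the last epoch)
    best_epoch: int = 0


def desk_training_config(seed: int = 0) -> TrainingConfig:
    """Training configuration for desk-scale (single-CPU) runs.

    Keeps the Adam optimizer and the 5-epoch cosine-annealing restarts, but
    trades the reference learning-rate band (1e-4 -> 1e-6) for a larger one
    (3e-3 -> 3e-5): the desk-scale schedule has two orders of magnitude
    fewer optimizer steps than a GPU-scale run, and the larger rate is what
    lets the Dice objective converge within it.  Batch size 2 maximizes the
    step count per unit compute on one core.
    """
    return TrainingConfig(epochs=36, batch_size=2, learning_rate=3e-3,
                          min_learning_rate=3e-5, restart_decay=0.7,
                          early_stop_miou=0.985, patience=2,
                          plateau_patience=10, seed=seed)


def resize_frames(images: np.ndarray, masks: np.ndarray, resolution: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Resize a frame stack to a square working resolution (bilinear for
    images, nearest for masks)."""
    si = np.stack([np.asarray(Image.fromarray(im).resize(
        (resolution, resolution), Image.BILINEAR)) for im in images])
    sm = np.stack([np.asarray(Image.fromarray(m).resize(
        (resolution, resolution), Image.NEAREST)) for m in masks])
    return si, sm


def build_model(spec: ModelSpec, seed: int = 0) -> DropletNet:
    """Construct the network with seeded He initialization."""
    rng = np.random.default_rng(seed)
    return DropletNet(base_width=spec.base_width, width_scale=spec.width_scale,
                      num_classes=spec.num_classes,
                      upsample_mode=spec.upsample_mode,
                      norm=spec.normalization, rng=rng)


# ---------------------------------------------------------------------------
# Dice loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_loss(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Dice loss between per-class soft masks and an integer label mask.

    ``predicted`` is ``(C, H, W)`` or ``(N, C, H, W)`` with rows summing to 1
    across classes; ``truth`` holds class ids of matching spatial shape.  The
    per-class soft Dice ``2*sum(p*y) / (sum(p) + sum(y))`` (smoothed by 1e-6)
    is averaged over the foreground classes present in prediction or truth;
    classes absent from both carry no signal and are skipped.
    """
    pred = np.asarray(predicted, dtype=np.float64)
    if pred.ndim == 3:
        pred = pred[None]
        truth = np.asarray(truth)[None]
    truth = np.asarray(truth)
    if pred.shape[0] != truth.shape[0] or pred.shape[2:] != truth.shape[1:]:
        raise ValueError("prediction and truth shapes disagree")
    hard = pred.argmax(axis=1)
    terms = []
    for c in FOREGROUND_CLASSES:
        y = truth == c
        sy = y.sum()
        sp = pred[:, c].sum()
        if sy == 0 and not (hard == c).any():
            continue
        inter = pred[:, c][y].sum()
        terms.append(1.0 - (2.0 * inter + DICE_SMOOTH) / (sp + sy + DICE_SMOOTH))
    return float(np.mean(terms)) if terms else 0.0


def _dice_loss_and_grad(logits: np.ndarray, truth: np.ndarray,
                        ce_weight: float = 0.0) -> tuple[float, np.ndarray]:
    """Training objective: softmax + foreground-averaged soft Dice, plus an
    optional auxiliary cross-entropy term.

    ``logits`` are channels-last ``(N, H, W, C)``.  For the optimization
    target all four foreground classes enter the average (with smoothing, a
    class absent from batch and prediction contributes a constant 0), which
    keeps the gradient a fixed function of the batch.  The cross-entropy
    term (weight ``ce_weight``) supplies a dense per-pixel signal that lets
    short schedules break class ties quickly; the reported loss value is
    always the pure Dice term.  Returns the Dice loss and the gradient of
    the combined objective with respect to the logits.
    """
    p = softmax(logits.astype(np.float32), axis=-1)
    n, h, w, c = p.shape
    onehot = np.zeros_like(p)
    onehot.reshape(-1, c)[np.arange(n * h * w), truth.ravel()] = 1.0

    fg = list(FOREGROUND_CLASSES)
    pf, yf = p[..., fg], onehot[..., fg]
    inter = (pf * yf).sum(axis=(0, 1, 2))
    sp = pf.sum(axis=(0, 1, 2))
    sy = yf.sum(axis=(0, 1, 2))
    denom = sp + sy + DICE_SMOOTH
    dice = (2.0 * inter + DICE_SMOOTH) / denom
    loss = float(1.0 - dice.mean())

    # d loss / d p_c  =  -(2*y*denom - (2*inter+smooth)) / denom^2 / n_fg
    gp = np.zeros_like(p)
    k = len(fg)
    coef1 = (2.0 / (denom * k)).astype(np.float32)
    coef2 = ((2.0 * inter + DICE_SMOOTH) / (denom * denom * k)).astype(np.float32)
    gp[..., fg] = -(coef1 * yf - coef2)
    # softmax backward
    dot = (gp * p).sum(axis=-1, keepdims=True)
    dlogits = p * (gp - dot)
    if ce_weight:
        dlogits += (ce_weight / (n * h * w)) * (p - onehot)
    return loss, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _to_batch(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 channels-last scaled to [-0.5, 0.5]."""
    return np.ascontiguousarray(images.astype(np.float32) / 255.0 - 0.5)


def evaluate(net: DropletNet, images: np.ndarray, masks: np.ndarray,
             batch_size: int = 8) -> tuple[float, float]:
    """Mean validation Dice loss and mIoU over a frame set."""
    from .evaluation import segmentation_metrics
    losses, preds = [], []
    for i in range(0, len(images), batch_size):
        xb = _to_batch(images[i:i + batch_size])
        logits = net.forward(xb, train=False)
        p = np.moveaxis(softmax(logits, axis=-1), -1, 1)
        losses.append(dice_loss(p, masks[i:i + batch_size]))
        preds.append(logits.argmax(axis=-1).astype(np.uint8))
    pred = np.concatenate(preds, axis=0)
    m = segmentation_metrics(list(pred), list(masks))
    return float(np.mean(losses)), m.miou


def train(
    net: DropletNet,
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    config: TrainingConfig | None = None,
    verbose: bool = False,
) -> TrainingHistory:
    """Train in place; returns the per-epoch history.

    Frames are uint8 ``(N, H, W, 3)`` images with ``(N, H, W)`` label masks.
    Fully seeded: batch shuffling comes from ``config.seed``.
    """
    config = config if config is not None else TrainingConfig()
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation partitions must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    hist = TrainingHistory()
    streak = 0
    plateau = 0
    best_miou, best_state = -1.0, None
    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(epoch, config.learning_rate,
                                 config.min_learning_rate,
                                 config.scheduler_period,
                                 config.restart_decay)
        opt.lr = lr
        order = rng.permutation(len(train_images))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            xb = _to_batch(train_images[sel])
            logits = net.forward(xb, train=True)
            loss, g = _dice_loss_and_grad(logits, train_masks[sel],
                                          config.aux_ce_weight)
            net.backward(g)
            opt.step()
            losses.append(loss)
        vloss, vmiou = evaluate(net, val_images, val_masks,
                                batch_size=max(16, config.batch_size))
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(vloss)
        hist.val_miou.append(vmiou)
        hist.learning_rate.append(lr)
        if verbose:
            print(f"epoch {epoch + 1:3d}  lr {lr:.2e}  "
                  f"train {hist.train_loss[-1]:.4f}  val {vloss:.4f}  "
                  f"mIoU {vmiou:.4f}")
        plateau = 0 if vmiou > best_miou + 0.003 else plateau + 1
        if vmiou > best_miou:
            best_miou = vmiou
            hist.best_epoch = epoch
            if config.restore_best:
                best_state = {k: v.copy()
                              for k, v in net.state_arrays().items()}
        streak = streak + 1 if vmiou >= config.early_stop_miou else 0
        if streak >= config.patience:
            break
        if config.plateau_patience and plateau >= config.plateau_patience:
            break
    if config.restore_best and best_state is not None:
        net.load_state_arrays(best_state)
    else:
        hist.best_epoch = len(hist.val_miou) - 1
    return hist


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(net: DropletNet, frame: np.ndarray,
            working_resolution: int = 512) -> np.ndarray:
    """Full-resolution inference.

    The frame is resized to the square working resolution (bilinear), the
    network produces per-class scores, the scores are resized back to the
    input size (bilinear, so class boundaries stay sub-pixel smooth) and the
    per-pixel argmax gives the mask (ties break to the lowest class id).
    Returns a uint8 label mask of the input's height and width.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB frame")
    h, w = frame.shape[:2]
    r = working_resolution
    if (h, w) != (r, r):
        img = Image.fromarray(frame.astype(np.uint8)).resize((r, r), Image.BILINEAR)
        x = np.asarray(img)
    else:
        x = frame
    logits = net.forward(_to_batch(x[None]), train=False)[0]
    if (h, w) != (r, r):
        planes = [np.asarray(Image.fromarray(logits[:, :, c]).resize(
            (w, h), Image.BILINEAR)) for c in range(logits.shape[-1])]
        logits = np.stack(planes, axis=-1)
    return logits.argmax(axis=-1).astype(np.uint8)


def predict_batch(net: DropletNet, frames, working_resolution: int = 512,
                  chunk: int = 16) -> list[np.ndarray]:
    """Batched :func:`predict` over same-sized frames (one forward pass per
    chunk; identical outputs, much less per-frame overhead)."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        return []
    h, w = frames[0].shape[:2]
    r = working_resolution
    out: list[np.ndarray] = []
    for i in range(0, len(frames), chunk):
        batch = frames[i:i + chunk]
        if (h, w) != (r, r):
            xs = np.stack([np.asarray(Image.fromarray(f.astype(np.uint8))
                                      .resize((r, r), Image.BILINEAR))
                           for f in batch])
        else:
            xs = np.stack(batch)
        logits = net.forward(_to_batch(xs), train=False)
        for lg in logits:
            if (h, w) != (r, r):
                planes = [np.asarray(Image.fromarray(lg[:, :, c]).resize(
                    (w, h), Image.BILINEAR)) for c in range(lg.shape[-1])]
                lg = np.stack(planes, axis=-1)
            out.append(lg.argmax(axis=-1).astype(np.uint8))
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, net: DropletNet, spec: ModelSpec,
                    config: TrainingConfig | None = None) -> None:
    """Weights as .npz next to a .json snapshot of spec + training config."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **net.state_arrays())
    meta = {"spec": spec.__dict__,
            "config": config.__dict__ if config is not None else None}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[DropletNet, ModelSpec]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(**meta["spec"])
    net = build_model(spec)
    with np.load(path.with_suffix(".npz")) as z:
        net.load_state_arrays(dict(z))
    return net, spec
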