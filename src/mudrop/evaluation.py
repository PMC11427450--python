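"""Evaluation protocols: segmentation metrics, continuous-recognition error
rate, the brightness-robustness sweep, and the split-volume CV experiment.

mIoU follows the confusion-matrix form averaged over the ``n + 1`` classes
(background included): ``IoU_i = p_ii / (sum_j p_ij + sum_j p_ji - p_ii)``.
mPrecision, mPA and mRecall are macro averages of the per-class precision
``p_ii / sum_j p_ji``, per-class pixel accuracy and recall ``p_ii / sum_j
p_ij`` (the latter two coincide by definition).  Classes absent from both
prediction and truth have undefined ratios and are skipped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .control import (ControlPolicy, closed_loop_split, coefficient_of_variation,
                      run_split)
from .extraction import observe_mask
from .grid import ElectrodeGrid
from .observers import GroundTruthObserver
from .segmentation import predict
from .simulator import PhysicsParams, SceneFrame, VirtualDevice, VirtualDroplet, adjust_brightness
from .states import NUM_CLASSES, DropletState


# ---------------------------------------------------------------------------
# segmentation metrics
# ---------------------------------------------------------------------------

@dataclass
class SegmentationMetrics:
    miou: float
    m_precision: float
    m_pa: float
    m_recall: float
    per_class_iou: list[float]   # NaN for classes absent from pred and truth

    def summary(self) -> str:
        rows = [f"mIoU        {self.miou:8.4f}",
                f"mPrecision  {self.m_precision:8.4f}",
                f"mPA         {self.m_pa:8.4f}",
                f"mRecall     {self.m_recall:8.4f}"]
        ious = "  ".join("   nan" if math.isnan(v) else f"{v:.4f}"
                         for v in self.per_class_iou)
        return "\n".join(rows + [f"per-class IoU  {ious}"])


def confusion_matrix(pred: list[np.ndarray], truth: list[np.ndarray],
                     n_classes: int = NUM_CLASSES) -> np.ndarray:
    """``cm[i, j]`` = pixels of true class i predicted as class j."""
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    for p, t in zip(pred, truth):
        p, t = np.asarray(p), np.asarray(t)
        if p.shape != t.shape:
            raise ValueError("prediction and truth shapes disagree")
        cm += np.bincount((t.ravel().astype(np.int64) * n_classes
                           + p.ravel()), minlength=n_classes ** 2
                          ).reshape(n_classes, n_classes)
    return cm


def segmentation_metrics(pred: list[np.ndarray], truth: list[np.ndarray],
                         n_classes: int = NUM_CLASSES) -> SegmentationMetrics:
    """Accumulate one confusion matrix over all pairs and macro-average."""
    cm = confusion_matrix(pred, truth, n_classes).astype(np.float64)
    diag = np.diag(cm)
    row = cm.sum(axis=1)     # truth totals   (sum_j p_ij)
    col = cm.sum(axis=0)     # prediction totals (sum_j p_ji)
    union = row + col - diag

    iou = np.full(n_classes, np.nan)
    present = union > 0
    iou[present] = diag[present] / union[present]
    precision = np.where(col > 0, diag / np.maximum(col, 1), np.nan)
    recall = np.where(row > 0, diag / np.maximum(row, 1), np.nan)
    return SegmentationMetrics(
        miou=float(np.nanmean(iou)),
        m_precision=float(np.nanmean(precision)),
        m_pa=float(np.nanmean(recall)),     # per-class pixel accuracy
        m_recall=float(np.nanmean(recall)),
        per_class_iou=[float(v) for v in iou],
    )


# ---------------------------------------------------------------------------
# continuous-recognition error rate
# ---------------------------------------------------------------------------

def error_rate(predicted_states: list[tuple[int, ...]],
               truth_states: list[tuple[int, ...]]) -> float:
    """Percentage of frames whose predicted state multiset differs from the
    ground truth during a continuous control sequence."""
    if len(predicted_states) != len(truth_states):
        raise ValueError("sequences must have equal length")
    if not predicted_states:
        raise ValueError("empty sequence")
    wrong = sum(tuple(p) != tuple(t)
                for p, t in zip(predicted_states, truth_states))
    return 100.0 * wrong / len(predicted_states)


def _frame_multiset(mask: np.ndarray, grid: ElectrodeGrid) -> tuple[int, ...]:
    return tuple(sorted(int(o.state) for o in observe_mask(mask, grid)))


def control_error_rate(net, frames: list[SceneFrame], grid: ElectrodeGrid,
                       working_resolution: int = 512) -> float:
    """Run the model over recorded control footage and score the per-frame
    state multisets against the ground-truth masks."""
    from .segmentation import predict_batch
    masks = predict_batch(net, [f.image for f in frames], working_resolution)
    pred = [_frame_multiset(m, grid) for m in masks]
    truth = [_frame_multiset(f.mask, grid) for f in frames]
    return error_rate(pred, truth)


# ---------------------------------------------------------------------------
# brightness robustness sweep
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    brightness_levels: list[float]
    state_accuracy: list[float]
    position_accuracy: list[float]
    overall_accuracy: list[float]
    state_sd: list[float] = field(default_factory=list)
    position_sd: list[float] = field(default_factory=list)
    overall_sd: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.brightness_levels,
            "state_accuracy": self.state_accuracy,
            "state_sd": self.state_sd,
            "position_accuracy": self.position_accuracy,
            "position_sd": self.position_sd,
            "overall_accuracy": self.overall_accuracy,
            "overall_sd": self.overall_sd,
        })

    def at(self, factor: float) -> dict[str, float]:
        i = self.brightness_levels.index(factor)
        return {"state": self.state_accuracy[i],
                "position": self.position_accuracy[i],
                "overall": self.overall_accuracy[i]}


def _score_frame(pred_mask: np.ndarray, truth_mask: np.ndarray,
                 grid: ElectrodeGrid) -> tuple[bool, bool]:
    """(state correct, position correct) for one frame.

    States: predicted multiset equals truth.  Positions: one-to-one nearest
    matching of predicted to true droplet centroids with every distance
    within half an electrode side.
    """
    p_obs = observe_mask(pred_mask, grid)
    t_obs = observe_mask(truth_mask, grid)
    state_ok = (tuple(sorted(int(o.state) for o in p_obs))
                == tuple(sorted(int(o.state) for o in t_obs)))
    if len(p_obs) != len(t_obs):
        return state_ok, False
    tol = grid.electrode_px / 2.0
    avail = list(p_obs)
    for t in t_obs:
        best = min(avail, key=lambda p: math.dist(p.centroid, t.centroid),
                   default=None)
        if best is None or math.dist(best.centroid, t.centroid) > tol:
            return state_ok, False
        avail.remove(best)
    return state_ok, True


def brightness_sweep(net, scenarios: list[list[SceneFrame]],
                     factors: list[float], grid: ElectrodeGrid,
                     working_resolution: int = 512) -> RobustnessReport:
    """Re-score every scenario under each brightness coefficient factor.

    Per factor and scenario: every frame's pixel values are multiplied by the
    factor, the model predicts, and the frame counts as state-correct
    (multisets agree), position-correct (all centroids within half an
    electrode side) and overall-correct (both).  Mean and SD are taken over
    scenarios, emulating a luminous-environment change of the same footage.
    """
    if 1.0 not in factors:
        raise ValueError("the reference factor 1.0 must be included")
    report = RobustnessReport([], [], [], [])
    for f in factors:
        s_acc, p_acc, o_acc = [], [], []
        for frames in scenarios:
            s = p = o = 0
            for frame in frames:
                img = adjust_brightness(frame.image, f) if f != 1.0 else frame.image
                pred = predict(net, img, working_resolution)
                st, pos = _score_frame(pred, frame.mask, grid)
                s += st
                p += pos
                o += st and pos
            n = len(frames)
            s_acc.append(s / n)
            p_acc.append(p / n)
            o_acc.append(o / n)
        report.brightness_levels.append(f)
        report.state_accuracy.append(float(np.mean(s_acc)))
        report.position_accuracy.append(float(np.mean(p_acc)))
        report.overall_accuracy.append(float(np.mean(o_acc)))
        report.state_sd.append(float(np.std(s_acc, ddof=1)) if len(s_acc) > 1 else 0.0)
        report.position_sd.append(float(np.std(p_acc, ddof=1)) if len(p_acc) > 1 else 0.0)
        report.overall_sd.append(float(np.std(o_acc, ddof=1)) if len(o_acc) > 1 else 0.0)
    return report


# ---------------------------------------------------------------------------
# split-volume CV experiment
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    cv_percent: float
    volumes: list[int]
    failures: int
    n: int


def cv_experiment(device_params: PhysicsParams, n: int, mode: str,
                  policy: ControlPolicy | None = None, seed: int = 0,
                  grid: ElectrodeGrid | None = None,
                  droplet_volume: float | None = None) -> CVResult:
    """``n`` independent seeded splitting experiments; returns the sample CV
    of all accepted half volumes (pixel counts).

    ``mode="open"`` accepts the first successful split unconditionally;
    ``mode="closed"`` runs the pixel-count feedback loop and only accepts
    pairs within the volume tolerance.  Runs that exhaust their retries are
    recorded, excluded from the CV, and reported in ``failures``.
    """
    if n < 2:
        raise ValueError("need at least 2 experiments")
    if mode not in ("open", "closed"):
        raise ValueError("mode must be 'open' or 'closed'")
    from .synthetic import NOISE_SD, split_strip
    grid = grid if grid is not None else split_strip()
    policy = policy or ControlPolicy()
    if droplet_volume is None:   # a droplet slightly larger than an electrode
        droplet_volume = 1.15 * grid.footprint_area()
    at = grid.cols // 2
    volumes: list[int] = []
    failures = 0
    children = np.random.SeedSequence(seed).spawn(n)
    for child in children:
        run_seed = int(child.generate_state(1)[0] % (2 ** 31))
        params = replace(device_params, seed=run_seed)
        droplet = VirtualDroplet(0, droplet_volume, grid.center(at))
        device = VirtualDevice([droplet], grid, params, noise_sd=NOISE_SD)
        observer = GroundTruthObserver(grid)
        if mode == "closed":
            pair, out = closed_loop_split(device, observer, at, policy, grid)
            if out.success and pair is not None:
                volumes.extend(pair)
            else:
                failures += 1
        else:
            out = run_split(device, observer, at, policy, grid)
            if out.success:
                halves = [o.pixel_count for o in out.final_observations
                          if o.state is DropletState.SPLIT]
                volumes.extend(halves[:2])
            else:
                failures += 1
    return CVResult(cv_percent=coefficient_of_variation(volumes),
                    volumes=volumes, failures=failures, n=n)
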