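"""Small plotting helpers (training curves, per-frame control traces, CV
comparison).  All figures are written straight to file (Agg backend)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .segmentation import TrainingHistory  # noqa: E402


def plot_training_curves(history: TrainingHistory, path: str | Path) -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    epochs = range(1, len(history.train_loss) + 1)
    ax1.plot(epochs, history.train_loss, label="train")
    ax1.plot(epochs, history.val_loss, label="validation")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("Dice loss")
    ax1.legend()
    ax2.plot(epochs, history.val_miou, color="tab:green")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("validation mIoU")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_observation_trace(log: pd.DataFrame, path: str | Path) -> None:
    """Per-frame droplet positions colored by state (the log produced by
    ``observations_to_frame`` rows concatenated over a session)."""
    fig, ax = plt.subplots(figsize=(7, 3.2))
    colors = {"unsplit": "tab:red", "splitting": "tab:green",
              "split": "tab:olive", "merging": "tab:blue"}
    for state, sub in log.groupby("state"):
        ax.scatter(sub["frame_index"], sub["electrode_id"], s=8,
                   color=colors.get(state, "gray"), label=state)
    ax.set_xlabel("frame")
    ax.set_ylabel("electrode")
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cv_comparison(open_volumes, closed_volumes, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(open_volumes, bins=20, alpha=0.6, label="open loop")
    ax.hist(closed_volumes, bins=20, alpha=0.6, label="closed loop")
    ax.set_xlabel("split half volume (px)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
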