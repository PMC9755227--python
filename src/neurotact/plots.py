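"""Figure rendering: receptive-field heatmaps, rasters, confusion matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .encoding import SpikeTrain
from .features_classify import ClassificationResult
from .innervation import InnervationMap
from .spindle import SpindleResponse

__all__ = ["innervation_heatmap", "raster_plot", "confusion_plot",
           "spindle_plot"]

TYPE_COLORS = {"SA-I": "black", "RA-I": "tab:blue", "RA-II": "tab:orange"}


def innervation_heatmap(imap: InnervationMap, path: str | Path) -> Path:
    """Summed receptive-field weights of each population on the 8x8 grid."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    for ax, kind in zip(axes, ("SA-I", "RA-I")):
        rows = imap.rows_of_type(kind)
        grid = imap.weights[rows].sum(axis=0).reshape(8, 8)
        im = ax.imshow(grid, cmap="viridis")
        ax.set_title(f"{kind} ({rows.sum()} afferents)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle(f"innervation target {imap.target_mean_innervation}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def raster_plot(trains: list[SpikeTrain], path: str | Path) -> Path:
    """Spike raster of the tactile population, one row per afferent."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, tr in enumerate(trains):
        color = TYPE_COLORS.get(tr.afferent_type, "gray")
        ax.vlines(tr.spike_times, i + 0.6, i + 1.4, color=color, lw=0.6)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("afferent")
    ax.set_ylim(0.5, len(trains) + 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def confusion_plot(result: ClassificationResult, path: str | Path) -> Path:
    """Pooled cross-validation confusion matrix as counts."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(result.confusion, cmap="Blues")
    ax.set_xticks(range(len(result.classes)), result.classes, rotation=45)
    ax.set_yticks(range(len(result.classes)), result.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"mean accuracy {result.mean_accuracy:.1%}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def spindle_plot(resp: SpindleResponse, path: str | Path) -> Path:
    t = np.arange(resp.prim_rate.size) / resp.sample_rate
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(t, resp.prim_rate, color="tab:blue", label="MS-Prim")
    ax.plot(t, resp.sec_rate, color="tab:red", label="MS-Sec")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("rate (spikes/s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
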