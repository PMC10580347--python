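"""Minimal figure export: time series, matrix heatmaps, energy landscapes."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import FreeEnergyLandscape

__all__ = ["save_series", "save_matrix", "save_landscape"]


def save_series(values: Sequence[float], path: Union[str, Path], *,
                x: Sequence[float] | None = None,
                xlabel: str = "frame", ylabel: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(x if x is not None else np.arange(len(values)), values, lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_matrix(matrix: np.ndarray, path: Union[str, Path], *,
                vmin: float = -1.0, vmax: float = 1.0,
                cmap: str = "RdBu_r", label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, origin="lower", vmin=vmin, vmax=vmax, cmap=cmap)
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_landscape(fel: FreeEnergyLandscape, path: Union[str, Path]) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    masked = np.ma.masked_invalid(fel.energy)
    im = ax.pcolormesh(fel.x_edges, fel.y_edges, masked.T, cmap="viridis")
    fig.colorbar(im, ax=ax, label="free energy (kcal/mol)")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
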