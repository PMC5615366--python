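"""Heatmaps of shape preferences and PWM sequence logos.

Preference heatmaps are split into positive and negative parts: the
positive panel shows ``max(df, 0)`` (preference for high feature
values), the negative panel ``max(-df, 0)`` (preference for low
values); zero renders grey, intensity grows with magnitude, and the
saturation value is printed in the figure margin.  Every plotted matrix
gets a TSV twin written alongside the image.

The sign convention follows the occupancy exponent ``exp(E - mu)``:
a positive ``df`` entry raises the energy and so lowers affinity when
the feature value is high.  The ``flip_sign`` toggle relabels panels
for the opposite interpretive reading without touching the numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .shape_features import ShapeFeatureTable

_POS_CMAP = LinearSegmentedColormap.from_list("pos_pref", ["#b0b0b0", "#ff7f0e"])
_NEG_CMAP = LinearSegmentedColormap.from_list("neg_pref", ["#b0b0b0", "#1f77b4"])


def export_preference_heatmap(
    df: np.ndarray,
    table: ShapeFeatureTable,
    path: str | Path,
    sign: Literal["positive", "negative"] = "positive",
    flip_sign: bool = False,
) -> Path:
    """Render one signed half of a shape-preference matrix.

    Writes the image to ``path`` and the plotted matrix to
    ``path`` with a ``.tsv`` suffix; returns the image path.
    """
    df = np.asarray(df, dtype=float)
    if df.ndim != 2 or df.shape[1] != table.K:
        raise ValueError(f"df must be (M-1) x {table.K}, got {df.shape}")
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    values = df if not flip_sign else -df
    half = np.maximum(values, 0.0) if sign == "positive" else np.maximum(-values, 0.0)
    path = Path(path)
    vmax = float(half.max())
    cmap = _POS_CMAP if sign == "positive" else _NEG_CMAP
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * df.shape[0] + 1.5), 2.6))
    im = ax.imshow(
        half.T,
        aspect="auto",
        cmap=cmap,
        vmin=0.0,
        vmax=vmax if vmax > 0 else 1.0,
        interpolation="nearest",
    )
    ax.set_yticks(range(table.K), table.feature_names)
    ax.set_xticks(range(df.shape[0]))
    ax.set_xlabel("dinucleotide position")
    ax.set_title(f"{sign} shape preference")
    fig.colorbar(im, ax=ax, shrink=0.8, label=f"|df| (saturates at {vmax:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    pd.DataFrame(
        half, columns=list(table.feature_names)
    ).rename_axis("position").to_csv(path.with_suffix(".tsv"), sep="\t")
    return path


_BASE_COLORS = {"A": "#109648", "C": "#255c99", "G": "#f7b32b", "T": "#d62839"}


def energies_to_probabilities(w: np.ndarray) -> np.ndarray:
    """Per-position Boltzmann probabilities p[j, a] ~ exp(-w[j, a])."""
    w = np.asarray(w, dtype=float)
    p = np.exp(-(w - w.min(axis=1, keepdims=True)))
    return p / p.sum(axis=1, keepdims=True)


def export_pwm_logo(w: np.ndarray, path: str | Path) -> Path:
    """Information-content-scaled sequence logo of the energy matrix.

    Letter heights at position j are p[j, a] * IC_j with
    IC_j = 2 + sum_a p log2 p.
    """
    w = np.asarray(w, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("w must be finite")
    probs = energies_to_probabilities(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    path = Path(path)
    M = w.shape[0]
    fig, ax = plt.subplots(figsize=(max(3, 0.5 * M), 2.2))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for j in range(M):
        y = 0.0
        order = np.argsort(probs[j])  # small letters at the bottom
        for a in order:
            h = probs[j, a] * ic[j]
            if h <= 1e-9:
                continue
            base = "ACGT"[a]
            tp = TextPath((0, 0), base, size=1.0, prop=font)
            bb = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bb.x0, -bb.y0)
                .scale(0.9 / bb.width, h / bb.height)
                .translate(j + 0.05, y)
            )
            ax.add_patch(
                PathPatch(tp.transformed(transform), color=_BASE_COLORS[base], lw=0)
            )
            y += h
    ax.set_xlim(0, M)
    ax.set_ylim(0, 2.0)
    ax.set_xticks(np.arange(M) + 0.5, [str(j) for j in range(M)])
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
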