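"""Evaluation metrics and cross-condition comparison of shape preferences."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outscores a random negative.

    Ties count half.  Rejects one-class inputs.
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve.

    Rectangular integration over recall (the average-precision
    convention): sum over thresholds of (R_n - R_{n-1}) * P_n.  For
    constant scores this equals the positive-class prevalence.  Rejects
    inputs without positives.
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("PR AUC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def recovery_correlation(w_fit: np.ndarray, w_true: np.ndarray) -> float:
    """Pearson correlation of per-position-centered energies, up to strand.

    Per-position additive constants are absorbed by the chemical
    potential, so energies are compared after centering each row; and a
    strand-agnostic scan cannot distinguish a motif from its reverse
    complement, so the better of the two orientations is reported.
    """
    w_fit = np.asarray(w_fit, dtype=float)
    w_true = np.asarray(w_true, dtype=float)
    if w_fit.shape != w_true.shape:
        raise ValueError(f"shape mismatch: {w_fit.shape} vs {w_true.shape}")

    def centered(w: np.ndarray) -> np.ndarray:
        return (w - w.mean(axis=1, keepdims=True)).ravel()

    t = centered(w_true)
    fwd = float(np.corrcoef(centered(w_fit), t)[0, 1])
    rc = float(np.corrcoef(centered(w_fit[::-1, ::-1]), t)[0, 1])
    return max(fwd, rc)


@dataclass
class PreferenceComparison:
    """Pairwise Pearson correlations of shape-preference matrices.

    ``pairwise`` is symmetric with unit diagonal; undefined correlations
    (a zero-variance matrix) are stored as NaN and excluded from the
    median.
    """

    pairwise: np.ndarray
    median_r: float


def compare_preferences(dfs: Sequence[np.ndarray]) -> PreferenceComparison:
    """Correlate flattened preference matrices across conditions."""
    if len(dfs) < 2:
        raise ValueError("need at least 2 preference matrices to compare")
    mats = [np.asarray(m, dtype=float) for m in dfs]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    flat = [m.ravel() for m in mats]
    n = len(flat)
    pairwise = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.std(flat[i]) == 0 or np.std(flat[j]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(flat[i], flat[j])[0, 1])
            pairwise[i, j] = pairwise[j, i] = r
    off_diag = pairwise[np.triu_indices(n, k=1)]
    finite = off_diag[np.isfinite(off_diag)]
    median_r = float(np.median(finite)) if finite.size else float("nan")
    return PreferenceComparison(pairwise=pairwise, median_r=median_r)
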