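"""Binding energies and occupancy for the three affinity-model variants.

A TF's occupancy on a sequence is a sum of Fermi-like terms, one per
M-bp window::

    P(S) = sum_i  1 / (1 + exp(E(window_i) - mu))

where ``mu`` is the chemical potential (set by the nuclear TF
concentration) and ``E`` is the binding energy of the window: the
independent per-position sum ``E_indep(S, w)``, optionally corrected by
either a full dinucleotide-dependency term ``E_dinuc(S, d)`` or the
shape-restricted form ``E_shape(F, df)`` with ``d = df @ D``.  Lower
energy means higher occupancy.  ChIP-seq signal is predicted by the
affine calibration ``a * P + b``.

By default both strands are scanned (ChIP-seq binding is
strand-agnostic); ``scan_both_strands=False`` restores the single-strand
scan of the bare equations.  Windows containing ``N`` contribute zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .seq_encoding import OneHotSequence
from .shape_features import (
    ShapeFeatureTable,
    ShapeProfile,
    project_shape_to_dinuc,
)


def stable_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """1 / (1 + exp(-x)) computed without overflow for any finite x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class IndependentModel:
    """Position-specific binding energies ``w`` (M x 4) and chemical potential."""

    w: np.ndarray = field(repr=False)
    mu: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 2:
            raise ValueError(f"w must be M x 4 with M >= 2, got {w.shape}")
        if not np.isfinite(w).all() or not np.isfinite(self.mu):
            raise ValueError("w and mu must be finite")
        object.__setattr__(self, "w", w)

    @property
    def M(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class DinucCorrection:
    """Pairwise energy corrections ``d``: (M-1) positions x 16 dinucleotides."""

    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[1] != 16:
            raise ValueError(f"d must be (M-1) x 16, got {d.shape}")
        if not np.isfinite(d).all():
            raise ValueError("d must be finite")
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class ShapeCorrection:
    """Shape-preference weights ``df``: (M-1) positions x K features."""

    df: np.ndarray = field(repr=False)
    table: ShapeFeatureTable

    def __post_init__(self) -> None:
        df = np.asarray(self.df, dtype=float)
        if df.ndim != 2 or df.shape[1] != self.table.K:
            raise ValueError(
                f"df must have K={self.table.K} columns, got {df.shape}"
            )
        if not np.isfinite(df).all():
            raise ValueError("df must be finite")
        object.__setattr__(self, "df", df)

    def as_dinuc(self) -> DinucCorrection:
        """Project into the equivalent full dinucleotide correction."""
        return DinucCorrection(d=project_shape_to_dinuc(self.df, self.table))


Correction = Union[DinucCorrection, ShapeCorrection, None]


@dataclass(frozen=True)
class AffinityModel:
    """A fitted binding model: energies, chemical potential, calibration."""

    independent: IndependentModel
    correction: Correction = None
    a: float = 1.0
    b: float = 0.0
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("a and b must be finite")
        M = self.independent.M
        if isinstance(self.correction, DinucCorrection):
            if self.correction.d.shape[0] != M - 1:
                raise ValueError("d must have M-1 rows")
        elif isinstance(self.correction, ShapeCorrection):
            if self.correction.df.shape[0] != M - 1:
                raise ValueError("df must have M-1 rows")

    @property
    def M(self) -> int:
        return self.independent.M

    def effective_dinuc(self) -> Optional[np.ndarray]:
        """The (M-1) x 16 dinucleotide energy matrix, or None."""
        if self.correction is None:
            return None
        if isinstance(self.correction, ShapeCorrection):
            return project_shape_to_dinuc(self.correction.df, self.correction.table)
        return self.correction.d


# ---------------------------------------------------------------------------
# Window energies


def energy_independent(window: OneHotSequence, w: np.ndarray) -> float:
    """Independent binding energy: sum over positions of w[j, base_j]."""
    w = np.asarray(w, dtype=float)
    if window.L != w.shape[0]:
        raise ValueError(f"window length {window.L} != motif length {w.shape[0]}")
    return float(np.sum(w * window.S))

def energy_dinucleotide(window: OneHotSequence, d: np.ndarray) -> float:
    """Dinucleotide correction energy: sum over steps of d[j, 4a+b]."""
    d = np.asarray(d, dtype=float)
    if window.L - 1 != d.shape[0]:
        raise ValueError(
            f"window has {window.L - 1} dinucleotide steps, d has {d.shape[0]} rows"
        )
    codes = window.codes
    left, right = codes[:-1], codes[1:]
    valid = (left >= 0) & (right >= 0)
    idx = 4 * left[valid].astype(int) + right[valid].astype(int)
    return float(d[np.flatnonzero(valid), idx].sum())

def energy_shape(profile_window: ShapeProfile | np.ndarray, df: np.ndarray) -> float:
    """Shape energy: Frobenius inner product of df with the window profile F."""
    F = profile_window.F if isinstance(profile_window, ShapeProfile) else np.asarray(profile_window)
    df = np.asarray(df, dtype=float)
    if F.shape != df.shape:
        raise ValueError(f"profile shape {F.shape} != df shape {df.shape}")
    return float(np.sum(df * F))


# ---------------------------------------------------------------------------
# Vectorized scanning


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement integer codes along the last axis (N stays -1)."""
    flipped = codes[..., ::-1]
    return np.where(flipped >= 0, 3 - flipped, -1).astype(codes.dtype)


def window_code_tensor(codes: np.ndarray, M: int, both_strands: bool) -> np.ndarray:
    """All scan windows of a code matrix.

    Parameters
    ----------
    codes : (n, L) int array of base codes (N = -1)
    M : motif length

    Returns an (n, n_windows, M) int array; with ``both_strands`` the
    reverse-complement scan windows are stacked after the forward ones.
    """
    codes = np.atleast_2d(np.asarray(codes))
    if codes.shape[1] < M:
        raise ValueError(
            f"sequence length {codes.shape[1]} shorter than motif length {M}"
        )
    fwd = np.lib.stride_tricks.sliding_window_view(codes, M, axis=1)
    if not both_strands:
        return np.ascontiguousarray(fwd)
    rev = np.lib.stride_tricks.sliding_window_view(_rc_codes(codes), M, axis=1)
    return np.ascontiguousarray(np.concatenate([fwd, rev], axis=1))


def window_energies(
    B: np.ndarray, w: np.ndarray, d: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total energy of every window in a window-code tensor.

    Returns ``(E, valid)`` where invalid (N-containing) windows carry
    energy 0 and ``valid`` False.
    """
    B = np.asarray(B)
    M = B.shape[-1]
    valid = (B >= 0).all(axis=-1)
    Bsafe = np.where(B >= 0, B, 0)
    E = w[np.arange(M), Bsafe].sum(axis=-1)
    if d is not None:
        dinuc = 4 * Bsafe[..., :-1] + Bsafe[..., 1:]
        E = E + d[np.arange(M - 1), dinuc].sum(axis=-1)
    return np.where(valid, E, 0.0), valid


def occupancy_codes(codes: np.ndarray, model: AffinityModel) -> np.ndarray:
    """Occupancy of each row of a (n, L) code matrix under ``model``."""
    B = window_code_tensor(codes, model.M, model.scan_both_strands)
    E, valid = window_energies(B, model.independent.w, model.effective_dinuc())
    occ = stable_sigmoid(model.independent.mu - E)
    return np.where(valid, occ, 0.0).sum(axis=-1)


def occupancy(s: OneHotSequence, model: AffinityModel) -> float:
    """Expected number of bound TF molecules on sequence ``s``.

    Sums the Fermi factor ``1/(1 + exp(E - mu))`` over every M-bp window
    (both strands unless disabled); windows containing N contribute 0.
    """
    if s.L < model.M:
        raise ValueError(f"sequence length {s.L} < motif length {model.M}")
    return float(occupancy_codes(s.codes[None, :], model)[0])


def predict_signal(s: OneHotSequence, model: AffinityModel) -> float:
    """Calibrated signal prediction ``a * occupancy + b``."""
    return model.a * occupancy(s, model) + model.b


def predict_signal_codes(codes: np.ndarray, model: AffinityModel) -> np.ndarray:
    return model.a * occupancy_codes(codes, model) + model.b


# ---------------------------------------------------------------------------
# Serialization and PWM import


def model_to_dict(model: AffinityModel) -> dict:
    doc: dict = {
        "M": model.M,
        "w": model.independent.w.tolist(),
        "mu": model.independent.mu,
        "a": model.a,
        "b": model.b,
        "scan_both_strands": model.scan_both_strands,
        "correction": "none",
    }
    if isinstance(model.correction, DinucCorrection):
        doc["correction"] = "dinuc"
        doc["d"] = model.correction.d.tolist()
    elif isinstance(model.correction, ShapeCorrection):
        doc["correction"] = "shape"
        doc["df"] = model.correction.df.tolist()
        doc["feature_names"] = list(model.correction.table.feature_names)
        doc["shape_table"] = model.correction.table.D.tolist()
        doc["shape_table_standardized"] = model.correction.table.standardized
    return doc


def model_from_dict(doc: dict) -> AffinityModel:
    indep = IndependentModel(w=np.array(doc["w"]), mu=float(doc["mu"]))
    kind = doc.get("correction", "none")
    correction: Correction = None
    if kind == "dinuc":
        correction = DinucCorrection(d=np.array(doc["d"]))
    elif kind == "shape":
        table = ShapeFeatureTable(
            D=np.array(doc["shape_table"]),
            feature_names=tuple(doc["feature_names"]),
            standardized=bool(doc.get("shape_table_standardized", False)),
        )
        correction = ShapeCorrection(df=np.array(doc["df"]), table=table)
    return AffinityModel(
        independent=indep,
        correction=correction,
        a=float(doc["a"]),
        b=float(doc["b"]),
        scan_both_strands=bool(doc.get("scan_both_strands", True)),
    )


def save_model(model: AffinityModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> AffinityModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def pwm_counts_to_energies(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Convert a 4 x M (or M x 4) count matrix to binding energies.

    Frequencies with a pseudocount are compared to the uniform
    background: ``w = -log(freq / 0.25)``, so the consensus base has the
    lowest energy.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or 4 not in counts.shape:
        raise ValueError("counts must be 4 x M or M x 4")
    if counts.shape[0] == 4 and counts.shape[1] != 4:
        counts = counts.T
    freq = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    return -np.log(freq / 0.25)


def read_jaspar_pwm(path: str | Path) -> np.ndarray:
    """Read a JASPAR-style 4-row count matrix (with or without header).

    Accepts lines like ``A [ 4 19 0 ... ]`` or bare whitespace-separated
    rows in A, C, G, T order; returns the M x 4 count matrix.
    """
    rows: dict[str, list[float]] = {}
    order = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        key = line[0].upper()
        body = line[1:] if key in "ACGT" else line
        nums = [float(tok) for tok in body.replace("[", " ").replace("]", " ").split()]
        if key not in "ACGT":
            key = "ACGT"[len(rows)]
        rows[key] = nums
        order.append(key)
    if set(rows) != set("ACGT"):
        raise ValueError(f"PWM file must provide rows A, C, G, T; got {sorted(rows)}")
    mat = np.array([rows[b] for b in "ACGT"])
    if mat.shape[1] < 2:
        raise ValueError("PWM must span at least 2 positions")
    return mat.T


def with_correction(model: AffinityModel, correction: Correction) -> AffinityModel:
    """Copy of ``model`` with a different correction term."""
    return replace(model, correction=correction)
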