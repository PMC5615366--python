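"""Dinucleotide DNA-shape features.

A :class:`ShapeFeatureTable` holds the matrix ``D`` of K structural
feature values (by default helix twist, minor groove width, propeller
twist and roll) for each of the 16 dinucleotides, in the fixed order
``index(a, b) = 4*a + b`` with A=0, C=1, G=2, T=3.  Per-sequence shape
profiles ``F`` are dictionary lookups into ``D``, which makes any
shape-based energy a dinucleotide-dependency energy restricted to the
row space of ``D``: expanding preference weights ``df`` into full
dinucleotide coefficients is the matrix product ``d = df @ D``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_encoding import ALPHABET, OneHotSequence

DEFAULT_TABLE = "dinucleotide_shape_synthetic"

DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)


def dinucleotide_index(a: str, b: str) -> int:
    """Column index of dinucleotide ``ab``: 4*code(a) + code(b)."""
    return 4 * ALPHABET.index(a) + ALPHABET.index(b)


@dataclass(frozen=True)
class ShapeFeatureTable:
    """K feature rows x 16 dinucleotide columns of shape values.

    When ``standardized`` each feature row has mean 0 and unit sample
    standard deviation across the 16 dinucleotides, so per-position
    shared regularization treats features on comparable scales.
    """

    D: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[1] != 16:
            raise ValueError(f"D must be K x 16, got {D.shape}")
        if D.shape[0] != len(self.feature_names):
            raise ValueError("one name per feature row is required")
        if D.shape[0] < 1:
            raise ValueError("at least one feature row is required")
        object.__setattr__(self, "D", D)
        if self.standardized:
            mean = D.mean(axis=1)
            sd = D.std(axis=1, ddof=1)
            if np.abs(mean).max() > 1e-9 or np.abs(sd - 1).max() > 1e-9:
                raise ValueError("standardized table rows must have mean 0, sd 1")

    @property
    def K(self) -> int:
        return self.D.shape[0]

    def standardize(self) -> "ShapeFeatureTable":
        """Z-score each feature across the 16 dinucleotides."""
        if self.standardized:
            return self
        mean = self.D.mean(axis=1, keepdims=True)
        sd = self.D.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            flat = self.feature_names[int(np.flatnonzero(sd.ravel() == 0)[0])]
            raise ValueError(f"feature {flat!r} is constant; cannot standardize")
        return ShapeFeatureTable(
            D=(self.D - mean) / sd,
            feature_names=self.feature_names,
            standardized=True,
        )


def load_shape_table(
    source: str | Path = DEFAULT_TABLE, standardize: bool = True
) -> ShapeFeatureTable:
    """Load a dinucleotide shape table from the packaged fixture or a TSV.

    The TSV layout is a ``dinucleotide`` column followed by one column
    per feature, with 16 data rows keyed AA..TT.  Missing dinucleotides
    or empty feature sets are rejected by name.
    """
    if isinstance(source, str) and not Path(source).exists():
        res = importlib.resources.files("shapebind.data") / f"{source}.tsv"
        if not res.is_file():
            raise FileNotFoundError(f"no packaged shape table named {source!r}")
        with importlib.resources.as_file(res) as p:
            return load_shape_table(p, standardize=standardize)
    df = pd.read_csv(source, sep="\t", comment="#")
    if "dinucleotide" not in df.columns:
        raise ValueError("shape table needs a 'dinucleotide' column")
    feature_names = tuple(c for c in df.columns if c != "dinucleotide")
    if not feature_names:
        raise ValueError("shape table has no feature columns")
    keyed = df.set_index("dinucleotide")
    missing = [dn for dn in DINUCLEOTIDES if dn not in keyed.index]
    if missing:
        raise ValueError(f"shape table is missing dinucleotide(s) {missing}")
    D = np.array(
        [[float(keyed.loc[dn, name]) for dn in DINUCLEOTIDES] for name in feature_names]
    )
    if not np.isfinite(D).all():
        raise ValueError("shape table contains non-finite values")
    table = ShapeFeatureTable(D=D, feature_names=feature_names)
    return table.standardize() if standardize else table


@dataclass(frozen=True)
class ShapeProfile:
    """Per-position shape profile ``F`` of a sequence.

    Row ``j`` holds the K feature values of the dinucleotide at
    positions (j, j+1); rows spanning an ``N`` base are all-zero.  A
    sequence of length L has L-1 rows.
    """

    F: np.ndarray = field(repr=False)
    feature_names: tuple[str, ...]


def compute_shape_profile(s: OneHotSequence, table: ShapeFeatureTable) -> ShapeProfile:
    """Look up the shape feature values of every dinucleotide step."""
    if s.L < 2:
        raise ValueError("shape profile requires a sequence of length >= 2")
    codes = s.codes
    left, right = codes[:-1], codes[1:]
    valid = (left >= 0) & (right >= 0)
    idx = np.where(valid, 4 * left.astype(int) + right.astype(int), 0)
    F = np.where(valid[:, None], table.D.T[idx], 0.0)
    return ShapeProfile(F=F, feature_names=table.feature_names)


def project_shape_to_dinuc(df: np.ndarray, table: ShapeFeatureTable) -> np.ndarray:
    """Expand shape-preference weights into full dinucleotide coefficients.

    ``d = df @ D``: the shape model is a dinucleotide-dependency model
    whose coefficients live in the linear subspace spanned by the K
    feature rows of ``D``.
    """
    df = np.asarray(df, dtype=float)
    if df.ndim != 2 or df.shape[1] != table.K:
        raise ValueError(
            f"df must have {table.K} columns to match the table, got {df.shape}"
        )
    return df @ table.D
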