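"""Sequence and interval handling: one-hot encoding, window extraction,
training-set assembly.

DNA strings are encoded as indicator matrices ``S`` with one row per
position and one column per nucleotide in the fixed order A, C, G, T.
``N`` bases encode to all-zero rows.  Genomic coordinates are 0-based
half-open throughout; BED input is taken at face value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_CODE_LUT = np.full(128, -2, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_CODE_LUT[ord("N")] = -1
_CODE_LUT[ord("n")] = -1


def sequence_codes(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0, C=1, G=2, T=3, N=-1.

    Raises ``ValueError`` naming the position of the first non-DNA
    character.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_LUT[raw & 0x7F]
    bad = np.flatnonzero(codes == -2)
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-DNA character {seq[pos]!r} at position {pos}"
        )
    return codes.astype(np.int8)


@dataclass(frozen=True)
class OneHotSequence:
    """Indicator encoding of a DNA string.

    Attributes
    ----------
    bases : str
        Uppercase sequence over ``{A, C, G, T, N}``.
    S : ndarray of shape (L, 4)
        Row ``i`` is the indicator of the base at position ``i``;
        all-zero for ``N``.
    """

    bases: str
    S: np.ndarray = field(repr=False)

    @property
    def L(self) -> int:
        """Sequence length in bp."""
        return len(self.bases)

    @property
    def codes(self) -> np.ndarray:
        """Integer codes (A=0 .. T=3, N=-1)."""
        return sequence_codes(self.bases)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.bases)


def encode_sequence(seq: str) -> OneHotSequence:
    """Encode a DNA string as a one-hot indicator matrix.

    >>> encode_sequence("ACGT").S
    array([[1., 0., 0., 0.],
           [0., 1., 0., 0.],
           [0., 0., 1., 0.],
           [0., 0., 0., 1.]])
    """
    if not seq:
        raise ValueError("empty sequence")
    codes = sequence_codes(seq)
    S = np.zeros((len(codes), 4))
    valid = codes >= 0
    S[np.flatnonzero(valid), codes[valid]] = 1.0
    return OneHotSequence(bases=seq.upper(), S=S)


def decode_sequence(one_hot: OneHotSequence) -> str:
    """Inverse of :func:`encode_sequence` (identity on the stored string)."""
    return one_hot.bases


def reverse_complement(s: OneHotSequence) -> OneHotSequence:
    """Reverse complement: rows reversed, columns swapped A<->T, C<->G.

    An involution; ``N`` rows stay all-zero.
    """
    rc_bases = str(Seq(s.bases).reverse_complement())
    rc_S = s.S[::-1, ::-1].copy()
    return OneHotSequence(bases=rc_bases, S=rc_S)


@dataclass
class TrainingSet:
    """Sequences with real-valued targets (signal levels or 1/0 labels)."""

    sequences: list[OneHotSequence]
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if len(self.targets) != len(self.sequences):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.targets)} targets"
            )
        if self.n_data < 2:
            raise ValueError("a training set needs at least 2 sequences")
        lengths = {s.L for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")

    @property
    def n_data(self) -> int:
        return len(self.sequences)

    @property
    def seq_length(self) -> int:
        return self.sequences[0].L

    def code_matrix(self) -> np.ndarray:
        """(n_data, L) int8 matrix of base codes."""
        return np.stack([s.codes for s in self.sequences])


# ---------------------------------------------------------------------------
# Dataset construction from peaks / TSS regions


def extract_peak_windows(
    peaks: Sequence[tuple[str, int, int, float]],
    genome: Mapping[str, str],
    window: int = 100,
    max_peaks: int = 1000,
) -> list[str]:
    """Fixed-width sequences centered on the strongest peaks.

    Parameters
    ----------
    peaks : sequence of (chrom, start, end, signal)
        0-based half-open intervals with a signal value.
    genome : mapping of chromosome name to sequence string.
    window : width of the extracted sequence.
    max_peaks : keep at most this many peaks, by descending signal.

    Peaks whose window would overrun a chromosome end are dropped.  The
    window around center ``c`` is ``[c - window//2, c - window//2 + window)``.
    """
    for chrom, *_ in peaks:
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
    ranked = sorted(enumerate(peaks), key=lambda kv: (-kv[1][3], kv[0]))
    out: list[str] = []
    for _, (chrom, start, end, _signal) in ranked:
        if len(out) >= max_peaks:
            break
        center = (start + end) // 2
        lo = center - window // 2
        hi = lo + window
        contig = genome[chrom]
        if lo < 0 or hi > len(contig):
            continue
        out.append(contig[lo:hi].upper())
    return out


def _interval_overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi


def sample_negative_windows(
    tss: Sequence[tuple[str, int]],
    genome: Mapping[str, str],
    window: int,
    n: int,
    exclusion: Sequence[tuple[str, int, int]] = (),
    rng_seed: int = 0,
    tss_flank: int = 10_000,
) -> list[str]:
    """Random windows near transcription start sites, avoiding exclusions.

    Each window lies fully within ``TSS +/- tss_flank`` for some TSS, does
    not overlap any exclusion interval, and contains no ``N``.  Start
    positions are drawn without replacement; deterministic given
    ``rng_seed``.  Raises ``ValueError`` if fewer than ``n`` eligible
    starts exist.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, lo, hi in exclusion:
        excl_by_chrom.setdefault(chrom, []).append((lo, hi))

    candidates: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for chrom, pos in tss:
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        contig_len = len(genome[chrom])
        lo = max(0, pos - tss_flank)
        hi = min(contig_len, pos + tss_flank)
        for start in range(lo, hi - window + 1):
            if (chrom, start) in seen:
                continue
            seen.add((chrom, start))
            if any(
                _interval_overlaps(start, start + window, e_lo, e_hi)
                for e_lo, e_hi in excl_by_chrom.get(chrom, [])
            ):
                continue
            candidates.append((chrom, start))
    if len(candidates) < n:
        raise ValueError(
            f"requested {n} negative windows but only {len(candidates)} "
            f"eligible start positions exist"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    out = []
    for idx in chosen:
        chrom, start = candidates[idx]
        out.append(genome[chrom][start : start + window].upper())
    return out


def build_training_set(
    positives: Iterable[str],
    negatives: Iterable[str],
    targets: Sequence[float] | None = None,
    positive_signals: Sequence[float] | None = None,
    drop_ambiguous: bool = True,
) -> TrainingSet:
    """Concatenate positive and negative sequences into a training set.

    Without explicit ``targets``, positives receive their signal values
    (or 1.0) and negatives receive 0.  Windows containing ``N`` are
    dropped by default so the signal calibration is not distorted by
    zero-contribution rows.
    """
    pos = [p.upper() for p in positives]
    neg = [q.upper() for q in negatives]
    if targets is not None:
        t = list(targets)
        if len(t) != len(pos) + len(neg):
            raise ValueError("targets length must match total sequence count")
    else:
        if positive_signals is not None:
            if len(positive_signals) != len(pos):
                raise ValueError("one signal value per positive is required")
            t = list(positive_signals) + [0.0] * len(neg)
        else:
            t = [1.0] * len(pos) + [0.0] * len(neg)
    seqs, kept_targets = [], []
    for s, ti in zip(pos + neg, t):
        if drop_ambiguous and "N" in s:
            continue
        seqs.append(encode_sequence(s))
        kept_targets.append(ti)
    return TrainingSet(sequences=seqs, targets=np.array(kept_targets))


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped or unwrapped) as name -> sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        str(path),
        "fasta",
    )


def read_bed_peaks(path: str | Path) -> list[tuple[str, int, int, float]]:
    """BED intervals with a signal value.

    Accepts BED4 (chrom, start, end, score) or BED5
    (chrom, start, end, name, score); the last numeric column is the
    signal.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("peak BED needs at least 4 columns (chrom,start,end,score)")
    score_col = 4 if df.shape[1] >= 5 else 3
    return [
        (str(r[0]), int(r[1]), int(r[2]), float(r[score_col]))
        for r in df.itertuples(index=False)
    ]


def read_tss(path: str | Path) -> list[tuple[str, int]]:
    """Two-column TSV of (chrom, position)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(r[0]), int(r[1])) for r in df.itertuples(index=False)]
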