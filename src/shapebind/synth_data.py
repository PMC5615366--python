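"""Synthetic sequences, signals, and variant benchmarks.

The generator draws data with exactly the statistical structure the
occupancy model assumes: background sequences with a chosen GC content,
motif instances sampled from the Boltzmann distribution implied by the
true energies (optionally with a dinucleotide/shape term, via Metropolis
resampling), targets that are the calibrated occupancy plus Gaussian
noise, and labeled ref/alt variant pairs where positives destroy a
consensus base inside a planted site and negatives mutate plain
background.

Every sampling operation derives its generator from the spec seed plus a
fixed stream offset, so the operations are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .affinity_model import (
    AffinityModel,
    IndependentModel,
    ShapeCorrection,
    occupancy_codes,
)
from .seq_encoding import ALPHABET, TrainingSet, encode_sequence
from .shape_features import ShapeFeatureTable

_STREAM_BACKGROUND = 1
_STREAM_MOTIF = 2
_STREAM_NOISE = 3
_STREAM_VARIANTS = 4


@dataclass
class SimulationSpec:
    """Ground-truth parameters and sizes for one synthetic study."""

    M: int
    true_w: np.ndarray
    true_df: Optional[np.ndarray] = None
    table: Optional[ShapeFeatureTable] = None
    true_mu: float = 0.0
    true_a: float = 1.0
    true_b: float = 0.0
    seq_length: int = 100
    n_pos: int = 500
    n_neg: int = 500
    noise_sd: float = 0.0
    gc_content: float = 0.5
    seed: int = 0
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        self.true_w = np.asarray(self.true_w, dtype=float)
        if self.true_w.shape != (self.M, 4):
            raise ValueError(f"true_w must be {self.M} x 4")
        if self.true_df is not None:
            self.true_df = np.asarray(self.true_df, dtype=float)
            if self.table is None:
                raise ValueError("true_df requires a shape feature table")
            if self.true_df.shape != (self.M - 1, self.table.K):
                raise ValueError(
                    f"true_df must be {self.M - 1} x {self.table.K}"
                )
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.noise_sd < 0 or self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("noise_sd, n_pos, n_neg must be >= 0")
        if self.seq_length < self.M:
            raise ValueError("seq_length must be >= motif length")

    def true_model(self) -> AffinityModel:
        correction = None
        if self.true_df is not None:
            correction = ShapeCorrection(df=self.true_df, table=self.table)
        return AffinityModel(
            independent=IndependentModel(w=self.true_w, mu=self.true_mu),
            correction=correction,
            a=self.true_a,
            b=self.true_b,
            scan_both_strands=self.scan_both_strands,
        )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def sample_background(spec: SimulationSpec, n: Optional[int] = None) -> list[str]:
    """``n_neg`` i.i.d. sequences at the spec's GC content."""
    n = spec.n_neg if n is None else n
    rng = spec._rng(_STREAM_BACKGROUND)
    codes = rng.choice(4, size=(n, spec.seq_length), p=_base_probs(spec.gc_content))
    return [_codes_to_str(row) for row in codes]


def _sample_motif_instances(spec: SimulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Motif windows drawn from the Boltzmann weight of the true energies.

    Independent part: base at position j with probability proportional
    to exp(-w[j, base]).  With a dinucleotide/shape term, instances are
    refined by single-site Metropolis sweeps under the full window
    energy, which converges to the joint Boltzmann distribution.
    """
    w = spec.true_w
    probs = np.exp(-w)
    probs /= probs.sum(axis=1, keepdims=True)
    inst = np.empty((n, spec.M), dtype=np.int64)
    for j in range(spec.M):
        inst[:, j] = rng.choice(4, size=n, p=probs[j])
    d = None
    if spec.true_df is not None:
        d = spec.true_df @ spec.table.D

        def window_energy(rows: np.ndarray) -> np.ndarray:
            E = w[np.arange(spec.M), rows].sum(axis=-1)
            dinuc = 4 * rows[..., :-1] + rows[..., 1:]
            return E + d[np.arange(spec.M - 1), dinuc].sum(axis=-1)

        E_cur = window_energy(inst)
        n_sweeps = 50
        for _ in range(n_sweeps):
            for j in range(spec.M):
                prop = inst.copy()
                prop[:, j] = rng.choice(4, size=n)
                E_prop = window_energy(prop)
                accept = rng.random(n) < np.exp(np.minimum(0.0, E_cur - E_prop))
                inst[accept] = prop[accept]
                E_cur = np.where(accept, E_prop, E_cur)
    return inst


def plant_motif_sequences(
    spec: SimulationSpec, n: Optional[int] = None, return_offsets: bool = False
):
    """Background sequences, each carrying one planted motif instance.

    The instance replaces a window at a uniform random offset.
    """
    n = spec.n_pos if n is None else n
    rng = spec._rng(_STREAM_MOTIF)
    codes = rng.choice(4, size=(n, spec.seq_length), p=_base_probs(spec.gc_content))
    inst = _sample_motif_instances(spec, n, rng)
    offsets = rng.integers(0, spec.seq_length - spec.M + 1, size=n)
    for i in range(n):
        codes[i, offsets[i] : offsets[i] + spec.M] = inst[i]
    seqs = [_codes_to_str(row) for row in codes]
    return (seqs, offsets) if return_offsets else seqs


def simulate_targets(sequences: list[str], spec: SimulationSpec) -> TrainingSet:
    """Targets t = a * P + b + Gaussian noise under the true model."""
    model = spec.true_model()
    encoded = [encode_sequence(s) for s in sequences]
    codes = np.stack([e.codes for e in encoded])
    t = spec.true_a * occupancy_codes(codes, model) + spec.true_b
    if spec.noise_sd > 0:
        t = t + spec._rng(_STREAM_NOISE).normal(0.0, spec.noise_sd, size=len(t))
    return TrainingSet(sequences=encoded, targets=t)


def simulate_training_set(spec: SimulationSpec) -> TrainingSet:
    """Planted-motif positives plus background negatives, with targets."""
    return simulate_targets(
        plant_motif_sequences(spec) + sample_background(spec), spec
    )


@dataclass
class VariantBenchmarkEntry:
    ref_seq: str
    alt_seq: str
    label: str  # "ASB" or "non-ASB"
    position: int = field(default=-1)


def make_variant_benchmark(
    spec: SimulationSpec, n_variants: int, balanced: bool = True
) -> list[VariantBenchmarkEntry]:
    """Labeled ref/alt pairs for allele-specific-binding style ranking.

    Positives ("ASB") place an SNV at the most informative motif
    position of a planted instance, flipping the consensus base to the
    worst base there; negatives ("non-ASB") mutate a random position of
    plain background sequence.  Full ``seq_length`` sequences are
    returned, so every motif placement overlapping the variant is
    scanned.
    """
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    n_pos = n_variants // 2 if balanced else max(1, n_variants // 4)
    n_neg = n_variants - n_pos
    rng = spec._rng(_STREAM_VARIANTS)

    # most informative position: largest energy gap between best and worst base
    gaps = spec.true_w.max(axis=1) - spec.true_w.min(axis=1)
    j_star = int(np.argmax(gaps))
    best_base = int(np.argmin(spec.true_w[j_star]))
    worst_base = int(np.argmax(spec.true_w[j_star]))

    pos_spec = SimulationSpec(
        M=spec.M,
        true_w=spec.true_w,
        true_df=spec.true_df,
        table=spec.table,
        true_mu=spec.true_mu,
        true_a=spec.true_a,
        true_b=spec.true_b,
        seq_length=spec.seq_length,
        n_pos=n_pos,
        n_neg=n_neg,
        noise_sd=0.0,
        gc_content=spec.gc_content,
        seed=spec.seed + 104729,  # distinct stream for benchmark sequences
        scan_both_strands=spec.scan_both_strands,
    )
    planted, offsets = plant_motif_sequences(pos_spec, n=n_pos, return_offsets=True)
    consensus = "".join(ALPHABET[c] for c in spec.true_w.argmin(axis=1))
    entries: list[VariantBenchmarkEntry] = []
    for seq, off in zip(planted, offsets):
        # an ASB-style positive needs a bound site: plant the full
        # consensus (the strongest instance), then destroy its most
        # informative base
        ref = seq[:off] + consensus + seq[off + spec.M :]
        p = off + j_star
        alt = ref[:p] + ALPHABET[worst_base] + ref[p + 1 :]
        entries.append(VariantBenchmarkEntry(ref, alt, "ASB", position=p))
    for seq in sample_background(pos_spec, n=n_neg):
        p = int(rng.integers(0, spec.seq_length))
        current = seq[p]
        alt_base = ALPHABET[
            int(rng.choice([c for c in range(4) if ALPHABET[c] != current]))
        ]
        entries.append(
            VariantBenchmarkEntry(seq, seq[:p] + alt_base + seq[p + 1 :], "non-ASB", position=p)
        )
    return entries
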