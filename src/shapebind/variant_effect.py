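"""Variant-effect scoring: shifted differential binding affinity.

For a model and a background threshold ``theta``, the above-background
binding strength of a sequence is ``dbA(x) = max(0, ln P(x) - theta)``,
and a variant's score is::

    ddbA = dbA(alt) - dbA(ref)

Positive scores mean the alternate allele creates or strengthens a
binding site; negative scores mean an existing site is weakened or
destroyed; variants with both alleles below background score exactly 0.
The threshold is a quantile (default 0.95) of log-occupancy over a
background sequence set, recorded with every score.  When several
models (e.g., alternative PWMs for the same TF) are supplied, the mean
ddbA across models ranks variants for allele-specific binding: the
larger the absolute mean score, the likelier an ASB event.

Callers should pass windows of length >= 2M - 1 centered on the variant
so that every motif placement overlapping the variant is scanned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .affinity_model import AffinityModel, occupancy
from .seq_encoding import encode_sequence


@dataclass
class VariantScore:
    """Per-model and mean ddbA of one ref/alt sequence pair."""

    ref_seq: str
    alt_seq: str
    per_model: list[float]
    mean_ddba: float
    label: Optional[str] = None
    variant_id: Optional[str] = None


def log_occupancy(s, model: AffinityModel) -> float:
    """Natural log of occupancy (occupancy is strictly positive)."""
    if isinstance(s, str):
        s = encode_sequence(s)
    return math.log(occupancy(s, model))


def background_threshold(
    model: AffinityModel, background: Sequence, quantile: float = 0.95
) -> float:
    """A quantile of log-occupancy over a background sequence set."""
    if len(background) == 0:
        raise ValueError("background set is empty")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    vals = np.array([log_occupancy(s, model) for s in background])
    return float(np.quantile(vals, quantile))


def delta_dbA(ref: str, alt: str, model: AffinityModel, threshold: float) -> float:
    """ddbA of one variant under one model at a given background threshold."""
    if len(ref) != len(alt):
        raise ValueError(
            f"ref ({len(ref)} bp) and alt ({len(alt)} bp) differ in length"
        )
    dba_ref = max(0.0, log_occupancy(ref, model) - threshold)
    dba_alt = max(0.0, log_occupancy(alt, model) - threshold)
    return dba_alt - dba_ref


def mean_delta_dbA(
    ref: str,
    alt: str,
    models: Sequence[AffinityModel],
    thresholds: Sequence[float],
    label: Optional[str] = None,
    variant_id: Optional[str] = None,
) -> VariantScore:
    """Average ddbA over several models (one background threshold each)."""
    if len(models) == 0:
        raise ValueError("at least one model is required")
    if len(thresholds) != len(models):
        raise ValueError("one threshold per model is required")
    per_model = [
        delta_dbA(ref, alt, m, th) for m, th in zip(models, thresholds)
    ]
    return VariantScore(
        ref_seq=ref,
        alt_seq=alt,
        per_model=per_model,
        mean_ddba=float(np.mean(per_model)),
        label=label,
        variant_id=variant_id,
    )


def rank_variants(scores: Sequence[VariantScore]) -> list[VariantScore]:
    """Descending by |mean ddbA|; stable for ties."""
    return sorted(scores, key=lambda v: -abs(v.mean_ddba))


# ---------------------------------------------------------------------------
# TSV input/output


def read_variants(path: str | Path) -> list[dict]:
    """Variant TSV in either of two layouts.

    Sequence-pair form: ``id, ref_sequence, alt_sequence[, label]``.
    Positional form: ``id, sequence, position, ref_allele, alt_allele[, label]``
    (0-based position; the sequence must carry the ref allele there).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    out = []
    if {"ref_sequence", "alt_sequence"} <= cols:
        for row in df.itertuples(index=False):
            out.append(
                {
                    "id": row.id,
                    "ref": row.ref_sequence.upper(),
                    "alt": row.alt_sequence.upper(),
                    "label": getattr(row, "label", None),
                }
            )
    elif {"sequence", "position", "ref_allele", "alt_allele"} <= cols:
        for row in df.itertuples(index=False):
            seq = row.sequence.upper()
            pos = int(row.position)
            if seq[pos] != row.ref_allele.upper():
                raise ValueError(
                    f"variant {row.id}: sequence has {seq[pos]} at position "
                    f"{pos}, not the stated ref allele {row.ref_allele}"
                )
            alt = seq[:pos] + row.alt_allele.upper() + seq[pos + 1 :]
            out.append(
                {"id": row.id, "ref": seq, "alt": alt, "label": getattr(row, "label", None)}
            )
    else:
        raise ValueError(
            "variant TSV must have columns (id, ref_sequence, alt_sequence) "
            "or (id, sequence, position, ref_allele, alt_allele)"
        )
    return out


def write_scores(scores: Sequence[VariantScore], path: str | Path) -> None:
    """Ranked score table with per-model ddbA columns."""
    ranked = rank_variants(scores)
    n_models = len(ranked[0].per_model) if ranked else 0
    rows = []
    for rank, v in enumerate(ranked, start=1):
        row = {
            "rank": rank,
            "id": v.variant_id if v.variant_id is not None else "",
            "mean_ddba": v.mean_ddba,
        }
        for k in range(n_models):
            row[f"ddba_model{k + 1}"] = v.per_model[k]
        if v.label is not None:
            row["label"] = v.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
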