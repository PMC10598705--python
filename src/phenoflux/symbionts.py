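"""ITS2 copy-number normalization and dominant symbiont type calling.

ITS2 rDNA copy number per cell differs strongly between Symbiodiniaceae
genera (Cladocopium ~2119 vs Durusdinium ~362 copies per cell), so raw
amplicon read proportions over-represent Cladocopium. Dividing counts by
the genus copy number and renormalizing recovers relative cell abundances;
a sample is assigned its dominant type when one type strictly exceeds 70%
of the (by default, normalized) abundance, otherwise it is called mixed.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import pandas as pd

from .cohort import DEFAULT_COPY_NUMBERS, SYMBIONT_GENUS

__all__ = [
    "MIXED",
    "DOMINANCE_THRESHOLD",
    "copy_number_normalize",
    "call_dominant_type",
    "dominant_types_table",
]

MIXED = "mixed"
DOMINANCE_THRESHOLD = 0.70
_OTHER_GENUS_COPIES = 1000.0


def _copies_for(
    types: list[str],
    genus_map: Mapping[str, str],
    copy_numbers: Mapping[str, float],
) -> list[float]:
    missing = [t for t in types if t not in genus_map]
    if missing:
        raise KeyError(f"no genus mapping for ITS2 types: {missing}")
    out = []
    for t in types:
        genus = genus_map[t]
        if genus in copy_numbers:
            c = float(copy_numbers[genus])
        else:
            warnings.warn(
                f"genus {genus!r} has no rDNA copy number; using {_OTHER_GENUS_COPIES}",
                stacklevel=3,
            )
            c = _OTHER_GENUS_COPIES
        if c <= 0:
            raise ValueError(f"copy number for genus {genus!r} must be > 0")
        out.append(c)
    return out


def copy_number_normalize(
    counts: pd.Series | pd.DataFrame,
    genus_map: Optional[Mapping[str, str]] = None,
    copy_numbers: Optional[Mapping[str, float]] = None,
):
    """Convert ITS2 read counts to relative cell abundances.

    abundance_i is proportional to counts_i / copies(genus_i), renormalized
    to sum to 1. Accepts one profile (Series indexed by ITS2 type) or a
    sample x type count table. Scale-invariant in total counts; within a
    single genus the proportions are unchanged.
    """
    genus_map = dict(genus_map) if genus_map is not None else dict(SYMBIONT_GENUS)
    copy_numbers = dict(copy_numbers or DEFAULT_COPY_NUMBERS)
    if isinstance(counts, pd.Series):
        return copy_number_normalize(counts.to_frame().T, genus_map, copy_numbers).iloc[0]
    if (counts.to_numpy() < 0).any():
        raise ValueError("ITS2 counts must be non-negative")
    copies = _copies_for(list(counts.columns), genus_map, copy_numbers)
    weighted = counts.astype(float).div(copies, axis=1)
    totals = weighted.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"profiles with no reads: {bad}")
    return weighted.div(totals, axis=0)


def call_dominant_type(
    abundances: pd.Series, threshold: float = DOMINANCE_THRESHOLD
) -> str:
    """Dominant ITS2 type: the type strictly exceeding the threshold, else mixed."""
    if len(abundances) == 0:
        raise ValueError("empty ITS2 profile")
    total = float(abundances.sum())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {total})")
    top = abundances.idxmax()
    return str(top) if float(abundances[top]) > threshold else MIXED


def dominant_types_table(
    counts: pd.DataFrame,
    genus_map: Optional[Mapping[str, str]] = None,
    copy_numbers: Optional[Mapping[str, float]] = None,
    basis: str = "normalized",
    threshold: float = DOMINANCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample dominant-type calls from a sample x ITS2 type count table.

    ``basis='normalized'`` (default) applies the >70% rule to copy-number
    normalized abundances; ``basis='raw'`` to raw read proportions.
    """
    if basis == "normalized":
        ab = copy_number_normalize(counts, genus_map, copy_numbers)
    elif basis == "raw":
        ab = counts.astype(float).div(counts.sum(axis=1), axis=0)
    else:
        raise ValueError("basis must be 'raw' or 'normalized'")
    calls = ab.apply(lambda row: call_dominant_type(row, threshold), axis=1)
    out = pd.DataFrame({
        "dominant_type": calls,
        "dominant_abundance": ab.max(axis=1),
    })
    return out
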