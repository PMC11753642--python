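"""Serial feature fusion: array-based concatenation of two feature tables.

Two selected feature vectors per sample (one per backbone) are joined
column-wise into a single fused vector; the fused width is d1 + d2 and
values pass through unchanged.  Per-column provenance (which source table
and which original column) is kept so the fusion is auditable and losslessly
reversible.

Fusion is order-sensitive: fuse(A, B) != fuse(B, A) in column layout, which
is why provenance matters.  Sample alignment is the dominant real-world
failure when features for the same images come from two extractors run
separately, so an explicit sample-id check is supported and preferred over
trusting row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["FusedMatrix", "fuse", "split_fused"]


@dataclass
class FusedMatrix:
    """n x (d1 + d2) fused values with per-column provenance.

    ``provenance`` is a list of (source, original_index) pairs, source 1 or
    2, covering every fused column exactly once in order.
    """

    values: np.ndarray
    provenance: List[Tuple[int, int]]
    d1: int
    d2: int

    def provenance_json(self) -> str:
        return json.dumps(
            {
                "d1": self.d1,
                "d2": self.d2,
                "columns": [
                    {"fused_index": i, "source": s, "original_index": j}
                    for i, (s, j) in enumerate(self.provenance)
                ],
            },
            indent=2,
        )


def _coerce(table, sample_id: Optional[str]):
    """Return (values ndarray, ids or None) from a DataFrame or array."""
    if isinstance(table, pd.DataFrame):
        df = table
        ids = None
        if sample_id is not None and sample_id in df.columns:
            ids = df[sample_id].to_numpy()
            df = df.drop(columns=[sample_id])
        return df.to_numpy(dtype=float), ids
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("feature tables must be 2-D")
    return arr, None


def fuse(vec1, vec2, sample_id: Optional[str] = None,
         standardize: bool = False) -> FusedMatrix:
    """Concatenate two feature tables column-wise.

    Accepts 2-D arrays or DataFrames.  If ``sample_id`` names a column
    present in both DataFrames, the ids must match row-for-row; the first
    offending row is reported.  ``standardize`` optionally z-scores each
    column (off by default: plain concatenation is the contract).
    """
    a, ids1 = _coerce(vec1, sample_id)
    b, ids2 = _coerce(vec2, sample_id)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"alignment error: row counts differ ({a.shape[0]} vs {b.shape[0]})"
        )
    if ids1 is not None and ids2 is not None:
        mismatch = np.flatnonzero(ids1 != ids2)
        if mismatch.size:
            r = int(mismatch[0])
            raise ValueError(
                f"alignment error: sample id mismatch at row {r} "
                f"({ids1[r]!r} vs {ids2[r]!r})"
            )
    values = np.hstack([a, b])
    if standardize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    provenance = [(1, j) for j in range(a.shape[1])] + [(2, j) for j in range(b.shape[1])]
    return FusedMatrix(values=values, provenance=provenance,
                       d1=a.shape[1], d2=b.shape[1])


def split_fused(fused: FusedMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Recover the two source tables bit-exactly (inverse of unstandardized
    :func:`fuse`)."""
    return fused.values[:, : fused.d1], fused.values[:, fused.d1 :]
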