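"""Delimited feature-table I/O.

Convention: CSV with a header row of feature names, one label column
(default name "label"), optionally a sample-id column (default "sample_id").
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["read_feature_table", "write_feature_table"]


def read_feature_table(
    path,
    label_col: str = "label",
    id_col: Optional[str] = "sample_id",
) -> Tuple[np.ndarray, np.ndarray, list, Optional[np.ndarray]]:
    """Read (X, y, feature_names, sample_ids) from a CSV feature table."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed feature table {path}: {exc}") from exc
    if label_col not in df.columns:
        raise ValueError(f"{path}: missing label column {label_col!r}")
    y = df[label_col].to_numpy()
    ids = None
    drop = [label_col]
    if id_col is not None and id_col in df.columns:
        ids = df[id_col].to_numpy()
        drop.append(id_col)
    feats = df.drop(columns=drop)
    bad = [c for c in feats.columns if not pd.api.types.is_numeric_dtype(feats[c])]
    if bad:
        raise ValueError(f"{path}: non-numeric feature column(s) {bad}")
    return feats.to_numpy(dtype=float), y, list(feats.columns), ids


def write_feature_table(
    path,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence] = None,
    label_col: str = "label",
    id_col: str = "sample_id",
) -> Path:
    """Write (X, y) to CSV with a header; inverse of read_feature_table."""
    path = Path(path)
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=list(feature_names))
    df[label_col] = np.asarray(y)
    if sample_ids is not None:
        df.insert(0, id_col, np.asarray(sample_ids))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
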