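"""Fisher-z functional connectivity matrices and edge vectorization.

Connectivity between two regions is the Pearson correlation of their BOLD
time series pushed through Fisher's r-to-z transform; each subject yields a
symmetric R x R matrix with a zero diagonal, flattened to an upper-triangle
edge vector for downstream modeling.  Edge ordering is the row-major upper
triangle (i < j) and is a pure function of R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "ParcellationTable",
    "compute_fc",
    "vectorize_edges",
    "devectorize",
    "edge_index_map",
]

_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    z: np.ndarray
    region_labels: list | None = None
    subject_id: str | int | None = None


@dataclass
class ParcellationTable:
    table: pd.DataFrame  # columns: id (1..R), name, macro_region

    def __post_init__(self):
        ids = self.table["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids must be unique")


def compute_fc(
    timeseries: np.ndarray,
    min_timepoints: int = 30,
    region_labels=None,
    subject_id=None,
) -> ConnectivityMatrix:
    """Pearson correlations of ROI series, Fisher r-to-z, zero diagonal.

    Correlations are clipped to ``±(1 - 1e-7)`` before ``atanh`` so duplicate
    series stay finite.  Constant columns and NaNs raise errors naming the
    offending regions/rows.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be T x R")
    T, R = ts.shape
    if T < min_timepoints:
        raise ValueError(f"need at least {min_timepoints} timepoints, got {T}")
    if np.isnan(ts).any():
        rows, cols = np.nonzero(np.isnan(ts))
        raise ValueError(
            f"NaNs in timeseries at (row, col) pairs: {list(zip(rows[:10].tolist(), cols[:10].tolist()))}"
        )
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        names = [region_labels[i] for i in bad] if region_labels else bad
        raise ValueError(f"constant time series for regions: {names}")
    r = np.corrcoef(ts, rowvar=False)
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, region_labels=region_labels, subject_id=subject_id)


def edge_index_map(n_regions: int) -> pd.DataFrame:
    """Edge id -> (i, j) map in row-major upper-triangle order, 0-based."""
    iu = np.triu_indices(n_regions, k=1)
    return pd.DataFrame({"edge": np.arange(iu[0].size), "i": iu[0], "j": iu[1]})


def vectorize_edges(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Flatten a symmetric matrix to its upper triangle (i < j, row-major)."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=atol):
        raise ValueError("matrix is asymmetric beyond tolerance")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def devectorize(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_edges` onto a zero-diagonal symmetric matrix."""
    v = np.asarray(vector, dtype=float)
    e = v.size
    R = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if R * (R - 1) // 2 != e:
        raise ValueError(f"vector length {e} is not a triangular number")
    M = np.zeros((R, R))
    iu = np.triu_indices(R, k=1)
    M[iu] = v
    return M + M.T
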