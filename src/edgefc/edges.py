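"""Co-fluctuation edge time series and edge functional connectivity.

For N z-scored component series there are M = N(N-1)/2 node pairs ("edges").
The edge time series of pair (i, j) is the element-wise product
``z_i(t) * z_j(t)``: positive when both signals deviate from baseline in the
same direction at time t.  Edge functional connectivity (eFC) between two
edges is the uncentered cosine similarity of their co-fluctuation series:

    eFC(e, f) = sum_t c_e(t) c_f(t) / sqrt(sum_t c_e(t)^2 * sum_t c_f(t)^2)

No mean-removal is applied to the edge rows; the formula is evaluated
literally.  The canonical edge order is row-major over the strict upper
triangle (i < j), shared by all downstream tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .panels import TimeSeriesPanel

__all__ = [
    "EdgeIndex",
    "EdgeTimeSeries",
    "EFCMatrix",
    "build_edge_timeseries",
    "compute_efc",
    "compute_nfc",
    "save_matrix",
    "load_matrix",
]


class EdgeIndex:
    """Canonical bijection between node pairs {i, j}, i < j, and edge slots.

    Order is row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,N-1), (1,2), ..., (N-2,N-1).
    """

    def __init__(self, n_nodes: int) -> None:
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        self.n_nodes = int(n_nodes)
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        self.rows = iu
        self.cols = ju
        self.n_edges = iu.size  # == N(N-1)/2

    def position(self, i: int, j: int) -> int:
        """Edge slot of the unordered pair {i, j}."""
        if i == j:
            raise ValueError("self-pairs are not edges")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.n_nodes):
            raise ValueError(f"pair ({i}, {j}) out of range for N={self.n_nodes}")
        n = self.n_nodes
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    def pair(self, e: int) -> tuple[int, int]:
        """Node pair (i, j), i < j, stored at edge slot ``e``."""
        if not (0 <= e < self.n_edges):
            raise IndexError(f"edge position {e} out of range")
        return int(self.rows[e]), int(self.cols[e])

    def __len__(self) -> int:
        return self.n_edges

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EdgeIndex) and other.n_nodes == self.n_nodes


@dataclasses.dataclass
class EdgeTimeSeries:
    """M x T co-fluctuation matrix for one subject."""

    values: np.ndarray
    edge_index: EdgeIndex
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape[0] != self.edge_index.n_edges:
            raise ValueError("row count does not match edge index")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class EFCMatrix:
    """Symmetric M x M edge functional connectivity matrix."""

    values: np.ndarray
    edge_index: EdgeIndex
    subject_id: str = ""

    def __post_init__(self) -> None:
        m = self.edge_index.n_edges
        if self.values.shape != (m, m):
            raise ValueError("eFC matrix shape does not match edge index")


def build_edge_timeseries(panel: TimeSeriesPanel) -> EdgeTimeSeries:
    """Element-wise products of all pairs of z-scored component series.

    Row e = (i, j) holds ``z_i(t) * z_j(t)``; its time mean equals the
    Pearson correlation of components i and j under the population variance
    convention.
    """
    if not panel.zscored:
        raise ValueError("panel must be z-scored before edge construction")
    idx = EdgeIndex(panel.n_components)
    z = panel.values
    values = z[idx.rows] * z[idx.cols]
    return EdgeTimeSeries(values=values, edge_index=idx, subject_id=panel.subject_id)


def compute_efc(
    ets: EdgeTimeSeries,
    dtype: np.dtype | type = np.float64,
    block_size: int | None = None,
) -> EFCMatrix:
    """Edge functional connectivity: uncentered cosine of edge rows.

    ``dtype=np.float32`` and/or ``block_size`` (rows per output block) trade
    precision/peak memory for the full dense M x M product; at N=200
    (M=19,900) the 64-bit dense matrix alone is ~3 GB.
    """
    c = np.asarray(ets.values, dtype=np.float64)
    norms = np.sqrt(np.einsum("et,et->e", c, c))
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        i, j = ets.edge_index.pair(int(zero[0]))
        raise ValueError(
            f"edge ({i}, {j}) has an all-zero co-fluctuation series; "
            "eFC denominator is zero"
        )
    u = (c / norms[:, None]).astype(dtype, copy=False)
    m = u.shape[0]
    if block_size is None:
        out = u @ u.T
    else:
        out = np.empty((m, m), dtype=dtype)
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            out[start:stop] = u[start:stop] @ u.T
    out = (out + out.T) / 2  # enforce exact symmetry against fp drift
    np.fill_diagonal(out, 1.0)
    return EFCMatrix(values=out, edge_index=ets.edge_index, subject_id=ets.subject_id)


def compute_nfc(panel: TimeSeriesPanel) -> np.ndarray:
    """Conventional node FC: Pearson correlation matrix of component series.

    For a z-scored panel (population convention) this is exactly
    ``Z @ Z.T / T``, with unit diagonal.
    """
    if not panel.zscored:
        raise ValueError("panel must be z-scored")
    z = panel.values
    nfc = z @ z.T / panel.n_timepoints
    nfc = (nfc + nfc.T) / 2
    np.fill_diagonal(nfc, 1.0)
    return nfc


def save_matrix(
    obj: EdgeTimeSeries | EFCMatrix, stem: str | Path, kind: str | None = None
) -> None:
    """Persist a matrix as <stem>.npy with a <stem>.json sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), obj.values)
    idx = obj.edge_index
    meta = {
        "kind": kind or type(obj).__name__,
        "subject_id": obj.subject_id,
        "n_nodes": idx.n_nodes,
        "n_edges": idx.n_edges,
        "edge_order": "row-major-upper-triangle",
        "shape": list(obj.values.shape),
        "dtype": str(obj.values.dtype),
    }
    if isinstance(obj, EdgeTimeSeries):
        meta["n_timepoints"] = obj.n_timepoints
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_matrix(stem: str | Path) -> EdgeTimeSeries | EFCMatrix:
    """Load a matrix persisted by :func:`save_matrix`."""
    stem = Path(stem)
    values = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    idx = EdgeIndex(meta["n_nodes"])
    if meta["kind"] == "EdgeTimeSeries":
        return EdgeTimeSeries(values, idx, meta["subject_id"])
    return EFCMatrix(values, idx, meta.get("subject_id", ""))
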