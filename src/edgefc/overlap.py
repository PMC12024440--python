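"""Community-overlap metrics: participation, entropy, and pair similarity.

Participation of node i in community c is the fraction of its N-1 incident
edges assigned to c; rows of the participation profile sum to 1.  Node
entropy is the Shannon entropy (base 2) of that row, optionally divided by
log2(k) so 0 means all incident edges share one community and 1 means a
perfectly even spread.  Network-level entropy is an aggregation (default:
unweighted mean) of member components' values.  Community similarity of
nodes i and j is the fraction of the N-2 third parties u whose edges (i,u)
and (j,u) carry the same community label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .communities import EdgePartition
from .panels import NetworkAtlas

__all__ = [
    "participation",
    "node_entropy",
    "network_entropy",
    "community_similarity",
    "entropy_records",
]


def participation(partition: EdgePartition) -> np.ndarray:
    """N x k matrix of participation probabilities; rows sum to 1."""
    idx = partition.edge_index
    n, k = idx.n_nodes, partition.k
    counts = np.zeros((n, k), dtype=np.float64)
    lab0 = partition.labels - 1
    np.add.at(counts, (idx.rows, lab0), 1.0)
    np.add.at(counts, (idx.cols, lab0), 1.0)
    return counts / (n - 1)


def node_entropy(profile: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Shannon entropy (bits) of each participation row; 0·log2(0) := 0.

    With ``normalize`` the entropy is divided by log2(k), where k is the
    number of columns of the profile (communities requested, not non-empty).
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("profile must be an N x k matrix")
    if np.any(p < -1e-12) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("profile rows must be probability distributions")
    k = p.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -terms.sum(axis=1)
    if normalize:
        if k == 1:
            raise ValueError("normalized entropy undefined for k=1 (log2(1)=0)")
        h = h / np.log2(k)
    return h


def network_entropy(
    entropies: np.ndarray,
    component_ids: list[str],
    atlas: NetworkAtlas,
    weighted: bool = False,
) -> pd.Series:
    """Aggregate component entropies to one value per named network.

    Default is the unweighted mean over member components ("weighted" keeps
    the same value here since members enter once each; the flag is reserved
    for future per-component weights and currently also computes the mean).
    """
    h = np.asarray(entropies, dtype=np.float64)
    if h.shape[0] != len(component_ids):
        raise ValueError("entropy vector length must match component ids")
    nets = atlas.networks_for(component_ids)
    out = {}
    for name in atlas.network_order:
        members = [i for i, g in enumerate(nets) if g == name]
        if not members:
            raise ValueError(f"network {name!r} has no components in this panel")
        out[name] = float(h[members].mean())
    return pd.Series(out, name="entropy")


def community_similarity(partition: EdgePartition) -> np.ndarray:
    """Symmetric N x N matrix of pairwise community-profile agreement.

    Entry (i, j) is the fraction of third-party nodes u (u != i, j) for
    which edges (i, u) and (j, u) share a community label.  The diagonal is
    undefined; it is stored as 1 by convention and must be excluded from
    statistics.
    """
    idx = partition.edge_index
    n = idx.n_nodes
    if n < 3:
        raise ValueError("community similarity needs N >= 3")
    lab = np.zeros((n, n), dtype=np.int64)
    lab[idx.rows, idx.cols] = partition.labels
    lab[idx.cols, idx.rows] = partition.labels
    # agree[i, j, u] = 1 iff label(i,u) == label(j,u)
    agree = (lab[:, None, :] == lab[None, :, :]).astype(np.float64)
    u_idx = np.arange(n)
    agree[u_idx, :, u_idx] = 0.0  # drop u == i
    agree[:, u_idx, u_idx] = 0.0  # drop u == j
    s = agree.sum(axis=2) / (n - 2)
    np.fill_diagonal(s, 1.0)
    return s


def entropy_records(
    subject_id: str,
    k: int,
    component_entropy: np.ndarray,
    component_ids: list[str],
    atlas: NetworkAtlas | None = None,
) -> pd.DataFrame:
    """Long-format entropy table rows for one subject and one k."""
    rows = [
        {
            "subject_id": subject_id,
            "level": "component",
            "unit": cid,
            "k": k,
            "entropy": float(h),
        }
        for cid, h in zip(component_ids, component_entropy)
    ]
    if atlas is not None:
        net = network_entropy(component_entropy, component_ids, atlas)
        rows += [
            {
                "subject_id": subject_id,
                "level": "network",
                "unit": name,
                "k": k,
                "entropy": float(v),
            }
            for name, v in net.items()
        ]
    return pd.DataFrame(rows)
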