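"""Nodal graph metrics used for hub detection.

Four hub measures are computed per node: nodal strength (NS), weighted
betweenness centrality (BC), nodal average path length (APL) and the Onnela
weighted clustering coefficient (CC), plus the binary degree.

Weighted path metrics need a weight-to-length map: stronger connections are
"shorter", so lengths are the reciprocal of the weights (the convention of
the standard connectivity toolboxes).  BC is unnormalized shortest-path
counting with each unordered pair counted once and endpoints excluded.
Nodal APL averages shortest-path lengths over *reachable* targets only;
unreachable pairs are excluded from the mean and surfaced as a reachability
deficit rather than mapped to infinity, so APL stays finite and rankable.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .io import Connectome

logger = logging.getLogger(__name__)

METRICS = ("ns", "bc", "apl", "cc")


def edge_lengths(conn: Connectome) -> np.ndarray:
    """Length matrix L_ij = 1/w_ij; absent edges get +inf; diagonal 0."""
    w = conn.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _length_graph(conn: Connectome) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(conn.n_nodes))
    ii, jj = np.nonzero(np.triu(conn.weights, k=1))
    w = conn.weights
    g.add_edges_from(
        (int(i), int(j), {"weight": w[i, j], "length": 1.0 / w[i, j]}) for i, j in zip(ii, jj)
    )
    return g


def nodal_strength(conn: Connectome) -> np.ndarray:
    return conn.weights.sum(axis=1)


def betweenness(conn: Connectome) -> np.ndarray:
    """Unnormalized weighted betweenness (shortest paths by total length)."""
    g = _length_graph(conn)
    bc = nx.betweenness_centrality(g, normalized=False, weight="length")
    return np.array([bc[i] for i in range(conn.n_nodes)], dtype=float)


def shortest_path_lengths(conn: Connectome) -> np.ndarray:
    """All-pairs weighted shortest-path lengths (inf where unreachable)."""
    return shortest_path(edge_lengths(conn), method="D", directed=False)


def nodal_apl(conn: Connectome) -> np.ndarray:
    """Mean shortest-path length to reachable nodes; NaN for isolated nodes."""
    d = shortest_path_lengths(conn)
    np.fill_diagonal(d, np.inf)  # exclude self-distance from the mean
    reachable = np.isfinite(d)
    n_reach = reachable.sum(axis=1)
    deficit = conn.n_nodes - 1 - n_reach
    if deficit.sum() > 0:
        logger.warning(
            "reachability deficit: %d unreachable pairs excluded from APL", int(deficit.sum())
        )
    with np.errstate(invalid="ignore"):
        apl = np.where(n_reach > 0, np.where(reachable, d, 0.0).sum(axis=1) / n_reach, np.nan)
    return apl


def clustering(conn: Connectome) -> np.ndarray:
    """Onnela weighted clustering: geometric mean of triangle weights,
    normalized by the network-wide maximum weight; 0 where degree < 2."""
    g = _length_graph(conn)
    cc = nx.clustering(g, weight="weight")
    return np.array([cc[i] for i in range(conn.n_nodes)], dtype=float)


def compute_nodal_metrics(conn: Connectome) -> pd.DataFrame:
    """All nodal measures for one network, indexed by roi_id."""
    df = pd.DataFrame(
        {
            "ns": nodal_strength(conn),
            "bc": betweenness(conn),
            "apl": nodal_apl(conn),
            "cc": clustering(conn),
            "degree": conn.degree(),
        },
        index=pd.Index(conn.node_ids, name="roi_id"),
    )
    return df


def cohort_nodal_metrics(cohort) -> pd.DataFrame:
    """Long-format table of nodal metrics for every subject in a cohort.

    Columns: subject_id, roi_id, ns, bc, apl, cc, degree.
    """
    frames = []
    for sid in cohort.subject_ids():
        df = compute_nodal_metrics(cohort.connectomes[sid]).reset_index()
        df.insert(0, "subject_id", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def metric_matrix(table: pd.DataFrame, cohort, metric: str) -> np.ndarray:
    """Pivot a long metric table to (n_subjects, n_rois) in manifest order."""
    wide = table.pivot(index="subject_id", columns="roi_id", values=metric)
    wide = wide.loc[cohort.subject_ids(), list(cohort.node_ids)]
    return wide.to_numpy(dtype=float)
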