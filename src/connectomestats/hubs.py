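"""Consensus hub detection and rich/feeder/local edge classification.

A node is a hub when it is extreme on enough of the four nodal criteria:
top 20% nodal strength, top 20% betweenness, bottom 20% average path
length, bottom 20% clustering.  With the consensus rule (default: at least
2 of 4 criteria) the hub set is robust to any single noisy measure.  Edges
are then classed as rich (hub-hub), feeder (hub-nonhub) or local
(nonhub-nonhub); the three class strengths partition the total network
strength exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GROUPS, Connectome
from .metrics import compute_nodal_metrics
from .richclub import group_average

#: criterion -> (metric column, take highest?)
HUB_CRITERIA = {"ns": True, "bc": True, "apl": False, "cc": False}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class HubReport:
    """Consensus hub call for one network."""

    criteria_hits: pd.Series  # int per roi_id
    is_hub: pd.Series  # bool per roi_id
    criterion_marks: pd.DataFrame  # bool per (roi_id, criterion)
    percentile: float
    min_hits: int

    @property
    def hub_ids(self) -> set:
        return set(self.is_hub.index[self.is_hub])

    def to_frame(self) -> pd.DataFrame:
        df = self.criterion_marks.astype(int).copy()
        df["criteria_hits"] = self.criteria_hits
        df["is_hub"] = self.is_hub.astype(int)
        return df


def consensus_hubs(metrics: pd.DataFrame, min_hits: int = 2, percentile: float = 0.2) -> HubReport:
    """Mark the extreme ``round(percentile*N)`` nodes per criterion.

    Ranking ties are broken toward the smaller roi_id so repeated runs are
    identical.  ``metrics`` is the per-node table from
    :func:`~connectomestats.metrics.compute_nodal_metrics` (index roi_id).
    """
    n = len(metrics)
    if n < 5:
        raise ValueError(f"need at least 5 nodes for percentile hub criteria, got {n}")
    if not 0 < percentile < 0.5:
        raise ValueError("percentile must be in (0, 0.5)")
    m = _round_half_up(percentile * n)
    marks = {}
    for crit, take_highest in HUB_CRITERIA.items():
        vals = metrics[crit]
        order = sorted(
            vals.index, key=lambda rid: ((-vals[rid]) if take_highest else vals[rid], rid)
        )
        chosen = set(order[:m])
        marks[crit] = metrics.index.isin(chosen)
    marks_df = pd.DataFrame(marks, index=metrics.index)
    hits = marks_df.sum(axis=1).astype(int)
    return HubReport(
        criteria_hits=hits,
        is_hub=hits >= min_hits,
        criterion_marks=marks_df,
        percentile=percentile,
        min_hits=min_hits,
    )


def classify_edges(conn: Connectome, hubs: set) -> np.ndarray:
    """Label matrix over node pairs: 'rich', 'feeder', 'local' (upper use only).

    Classification depends only on endpoint hub membership, not on weight.
    """
    is_hub = np.isin(conn.node_ids, list(hubs))
    n_hub_ends = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)
    labels = np.where(n_hub_ends == 2, "rich", np.where(n_hub_ends == 1, "feeder", "local"))
    return labels


def edge_class_sets(conn: Connectome, hubs: set) -> dict:
    """Edges (roi_id pairs) per class, for edges with positive weight."""
    labels = classify_edges(conn, hubs)
    ii, jj = np.nonzero(np.triu(conn.weights, k=1))
    out = {"rich": [], "feeder": [], "local": []}
    for i, j in zip(ii, jj):
        out[labels[i, j]].append((int(conn.node_ids[i]), int(conn.node_ids[j])))
    return out


def _class_sums(conn: Connectome, hubs: set) -> tuple[float, float, float]:
    is_hub = np.isin(conn.node_ids, list(hubs))
    iu = np.triu_indices(conn.n_nodes, k=1)
    w = conn.weights[iu]
    n_hub_ends = is_hub[iu[0]].astype(int) + is_hub[iu[1]].astype(int)
    # one partitioned pass so rich + feeder + local is exactly the total
    sums = np.bincount(2 - n_hub_ends, weights=w, minlength=3)
    return float(sums[0]), float(sums[1]), float(sums[2])


def class_strengths(cohort, hubs_by_group: dict) -> pd.DataFrame:
    """Per-subject rich/feeder/local summed weights.

    Each subject is classified with the fixed hub set of its own group
    (detected on that group's averaged network).
    """
    rows = []
    for _, rec in cohort.manifest.iterrows():
        sid, group = rec["subject_id"], rec["group"]
        rich, feeder, local = _class_sums(cohort.connectomes[sid], hubs_by_group[group])
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "rich": rich,
                "feeder": feeder,
                "local": local,
                "total": rich + feeder + local,
            }
        )
    return pd.DataFrame(rows)


def hubs_per_group(cohort, min_hits: int = 2, percentile: float = 0.2) -> dict:
    """One HubReport per group, from the group-averaged networks."""
    out = {}
    for g in GROUPS:
        avg = group_average(cohort, g)
        out[g] = consensus_hubs(compute_nodal_metrics(avg), min_hits=min_hits, percentile=percentile)
    return out


@dataclass
class ClassStrengthResults:
    """Group comparison of the three connection-class strengths."""

    table: pd.DataFrame  # class, t, p_perm, p_bonf
    strengths: pd.DataFrame
    n_perm: int

    def summary(self) -> str:
        lines = [f"Connection-class strength comparison ({self.n_perm} permutations, Bonferroni x3)"]
        lines.append(self.table.to_string(index=False))
        return "\n".join(lines)


class ClassStrengthTest:
    """Welch-t permutation comparison of rich/feeder/local strengths.

    Age enters as a Freedman-Lane nuisance; p-values are Bonferroni
    corrected across the three classes.
    """

    def __init__(self, cohort, hubs_by_group: dict | None = None, min_hits: int = 2,
                 percentile: float = 0.2):
        self.cohort = cohort
        self.hubs_by_group = hubs_by_group or {
            g: rep.hub_ids for g, rep in hubs_per_group(cohort, min_hits, percentile).items()
        }

    def fit(self, n_perm: int = 20000, rng=None) -> ClassStrengthResults:
        from .inference import perm_group_test

        rng = np.random.default_rng(rng)
        strengths = class_strengths(self.cohort, self.hubs_by_group)
        groups = strengths["group"].to_numpy()
        ages = self.cohort.ages()
        rows = []
        for cls in ("rich", "feeder", "local"):
            t, p = perm_group_test(strengths[cls].to_numpy(), groups, ages, n_perm=n_perm, rng=rng)
            rows.append({"class": cls, "t": t, "p_perm": p, "p_bonf": min(1.0, 3 * p)})
        return ClassStrengthResults(table=pd.DataFrame(rows), strengths=strengths, n_perm=n_perm)
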