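"""Network-based statistic (NBS) for edge-wise group differences.

Edge-wise mass-univariate GLMs (weight ~ intercept + group + age) give a t
statistic per connection; edges whose t exceeds a primary threshold form a
supra-threshold graph whose connected components are the candidate
effects.  Family-wise error over components is controlled by permutation:
group labels are shuffled under a Freedman-Lane scheme (residuals after
regressing out age), the maximal component size (edge count) is recorded
per permutation, and each observed component is referred to that null
distribution.  Both one-directional contrasts (APD>HC and HC>APD) are run,
each against its own null, realizing a two-tailed hypothesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import GROUPS

logger = logging.getLogger(__name__)

DIRECTIONS = ("APD>HC", "HC>APD")


def p_to_t(p: float, df: int) -> float:
    """Two-tailed p to the corresponding |t| threshold at ``df``."""
    return float(stats.t.isf(p / 2.0, df))


def components_above_threshold(edge_t, edge_index, n_nodes, t_threshold):
    """Connected components (>=1 edge) of the supra-threshold edge graph.

    ``edge_t`` are signed t values for the direction under test (kept if
    ``t >= t_threshold``); ``edge_index`` is the (E, 2) array of node
    positions.  Returns a list of (edge_positions, size) sorted by
    descending size.
    """
    keep = np.nonzero(edge_t >= t_threshold)[0]
    if keep.size == 0:
        return []
    ij = edge_index[keep]
    adj = coo_matrix(
        (np.ones(len(keep)), (ij[:, 0], ij[:, 1])), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = connected_components(adj + adj.T, directed=False)
    comp_of_edge = labels[ij[:, 0]]
    comps = []
    for c in np.unique(comp_of_edge):
        members = keep[comp_of_edge == c]
        comps.append((members, len(members)))
    comps.sort(key=lambda x: -x[1])
    return comps


def _glm_t(y: np.ndarray, x: np.ndarray, contrast_col: int) -> np.ndarray:
    """t for one coefficient of y ~ X, vectorized over columns of y.

    Zero-residual-variance columns get t = 0.
    """
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    var_c = sigma2 * xtx_inv[contrast_col, contrast_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_c > 0, beta[contrast_col] / np.sqrt(np.where(var_c > 0, var_c, 1.0)), 0.0)
    t[np.ptp(y, axis=0) == 0] = 0.0  # constant edges carry no signal
    return t


@dataclass
class NBSComponent:
    edges: list  # list of (roi_id, roi_id) pairs
    size: int
    p_fwe: float


@dataclass
class NBSResults:
    """Observed components and permutation FWER p-values, per direction."""

    direction: str
    t_threshold: float
    edge_t: np.ndarray  # signed t per masked edge (positive favors direction)
    edge_index: np.ndarray
    node_ids: np.ndarray
    components: list = field(default_factory=list)
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    n_perm: int = 0

    @property
    def max_component_size(self) -> int:
        return max((c.size for c in self.components), default=0)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.components if c.p_fwe < alpha]

    def summary(self) -> str:
        lines = [
            f"NBS {self.direction}: t threshold {self.t_threshold:.4f}, "
            f"{self.n_perm} permutations, {len(self.components)} component(s)"
        ]
        for c in self.components:
            lines.append(f"  size {c.size} edges, p_fwe = {c.p_fwe:.4f}")
        if not self.components:
            lines.append("  no supra-threshold component")
        return "\n".join(lines)

    def to_records(self) -> list:
        return [
            {"direction": self.direction, "size": c.size, "p_fwe": c.p_fwe, "edges": c.edges}
            for c in self.components
        ]


class NBS:
    """Network-based statistic model for a two-group weighted cohort.

    Parameters
    ----------
    cohort : Cohort
    t_threshold : float
        Primary edge-level threshold on the group-contrast t statistic.
        The default matches a stringent uncorrected edge p under the study
        design; :func:`p_to_t` converts a p threshold at a given df.
    edge_mask_fraction : float
        Only edges nonzero in at least this fraction of all subjects are
        tested; t statistics on near-absent edges are degenerate.
    """

    def __init__(self, cohort, t_threshold: float = 3.9805, edge_mask_fraction: float = 0.5,
                 include_age: bool = True):
        self.cohort = cohort
        self.t_threshold = t_threshold
        self.edge_mask_fraction = edge_mask_fraction
        self.include_age = include_age
        groups = cohort.group_labels()
        sizes = cohort.group_sizes()
        if min(sizes.values()) < 3:
            raise ValueError("need at least 3 subjects per group")
        stack = cohort.weight_stack()
        n = stack.shape[1]
        iu = np.triu_indices(n, k=1)
        present = (stack[:, iu[0], iu[1]] > 0).mean(axis=0) >= edge_mask_fraction
        # never test edges absent everywhere even if the mask fraction is 0
        present &= (stack[:, iu[0], iu[1]] > 0).any(axis=0)
        self.edge_index = np.column_stack([iu[0][present], iu[1][present]])
        self.y = stack[:, iu[0][present], iu[1][present]]
        ages = cohort.ages()
        g = (groups == GROUPS[0]).astype(float)
        if include_age:
            self.design = np.column_stack([np.ones(len(g)), g, ages - ages.mean()])
            self.nuisance = self.design[:, [0, 2]]
        else:
            self.design = np.column_stack([np.ones(len(g)), g])
            self.nuisance = self.design[:, [0]]
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("rank-deficient design (age confounded with group?)")

    def edgewise_t(self, y: np.ndarray | None = None) -> np.ndarray:
        """Group-contrast t (APD minus HC) per masked edge, age-adjusted."""
        return _glm_t(self.y if y is None else y, self.design, contrast_col=1)

    def fit(self, n_perm: int = 10000, rng=None) -> dict:
        """Run both one-directional NBS tests; returns {direction: NBSResults}."""
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(rng)
        n_nodes = self.cohort.n_nodes
        node_ids = self.cohort.node_ids
        t_obs = self.edgewise_t()
        obs_comps = {
            "APD>HC": components_above_threshold(t_obs, self.edge_index, n_nodes, self.t_threshold),
            "HC>APD": components_above_threshold(-t_obs, self.edge_index, n_nodes, self.t_threshold),
        }
        # Freedman-Lane: permute residuals of y ~ nuisance, re-add nuisance fit
        z = self.nuisance
        gamma = np.linalg.lstsq(z, self.y, rcond=None)[0]
        fitted = z @ gamma
        resid = self.y - fitted
        n = self.y.shape[0]
        null_max = {d: np.zeros(n_perm) for d in DIRECTIONS}
        for b in range(n_perm):
            y_star = fitted + resid[rng.permutation(n)]
            t_star = self.edgewise_t(y_star)
            for d, sign in (("APD>HC", 1.0), ("HC>APD", -1.0)):
                comps = components_above_threshold(
                    sign * t_star, self.edge_index, n_nodes, self.t_threshold
                )
                null_max[d][b] = comps[0][1] if comps else 0
        out = {}
        for d, sign in (("APD>HC", 1.0), ("HC>APD", -1.0)):
            components = []
            for members, size in obs_comps[d]:
                p_fwe = (1.0 + np.sum(null_max[d] >= size)) / (n_perm + 1.0)
                pairs = [
                    (int(node_ids[i]), int(node_ids[j])) for i, j in self.edge_index[members]
                ]
                components.append(NBSComponent(edges=pairs, size=size, p_fwe=p_fwe))
            out[d] = NBSResults(
                direction=d,
                t_threshold=self.t_threshold,
                edge_t=sign * t_obs,
                edge_index=self.edge_index,
                node_ids=node_ids,
                components=components,
                null_max_sizes=null_max[d],
                n_perm=n_perm,
            )
        return out
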