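"""Weighted rich-club organization and degree-preserving null models.

The weighted rich-club coefficient at degree level ``k`` asks how much of
the total weight among the "rich" nodes (binary degree strictly greater
than k) is realized, relative to the most weight those many edges could
carry anywhere in the network:

    phi_w(k) = W_>k / sum of the |E_>k| largest edge weights in the network

Because phi_w(k) rises mechanically with k even in random graphs, it is
normalized against an ensemble of comparable random networks produced by
Maslov-Sneppen double-edge swaps in which each edge carries its weight
through the swap.  The rewiring preserves the binary degree sequence and
the multiset of edge weights exactly.  phi_norm(k) > 1 over a contiguous
range of k indicates rich-club organization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import Connectome

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weighted rich-club coefficient


def phi_weighted(conn: Connectome, k: int) -> float:
    """Weighted rich-club coefficient at degree level k (NaN if undefined).

    Undefined when fewer than two nodes exceed degree k or the rich subgraph
    has no edges.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    w = conn.weights
    deg = conn.degree()
    rich = deg > k
    if rich.sum() < 2:
        return np.nan
    sub = w[np.ix_(rich, rich)]
    iu = np.triu_indices_from(sub, k=1)
    sub_weights = sub[iu]
    sub_weights = sub_weights[sub_weights > 0]
    n_edges = sub_weights.size
    if n_edges == 0:
        return np.nan
    all_weights = w[np.triu_indices_from(w, k=1)]
    all_weights = np.sort(all_weights[all_weights > 0])[::-1]
    return float(sub_weights.sum() / all_weights[:n_edges].sum())


def _edge_list(w: np.ndarray):
    ii, jj = np.nonzero(np.triu(w, k=1))
    return np.column_stack([ii, jj]).astype(np.int64), w[ii, jj]


def _curve_from_edges(deg, edges, weights, k_grid, denom_cum):
    """phi_w over a k grid, given a fixed degree sequence and weight multiset.

    ``denom_cum[m]`` is the sum of the m largest edge weights of the network.
    Exploits that the rich node set at level k depends only on degrees, and
    an edge lies inside it iff the smaller endpoint degree exceeds k.
    """
    m = np.minimum(deg[edges[:, 0]], deg[edges[:, 1]])
    order = np.argsort(-m, kind="stable")
    m_sorted = m[order]
    cum_w = np.concatenate([[0.0], np.cumsum(weights[order])])
    # edges with min endpoint degree > k form a prefix of the sorted order
    cnt = np.searchsorted(-m_sorted, -(k_grid + 1), side="right")
    n_rich = np.searchsorted(np.sort(-deg), -(k_grid + 1), side="right")
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = cum_w[cnt] / denom_cum[cnt]
    phi = np.where((n_rich >= 2) & (cnt > 0), phi, np.nan)
    return phi


def rich_club_curve(conn: Connectome, k_grid: np.ndarray | None = None) -> np.ndarray:
    """Vectorized phi_w over k_grid (default 1..max_degree-1)."""
    deg = conn.degree()
    if k_grid is None:
        k_grid = np.arange(1, max(int(deg.max()), 1))
    edges, weights = _edge_list(conn.weights)
    denom_cum = np.concatenate([[0.0], np.cumsum(np.sort(weights)[::-1])])
    return _curve_from_edges(deg, edges, weights, np.asarray(k_grid), denom_cum)


# ---------------------------------------------------------------------------
# Degree-preserving rewiring null model


@njit(cache=True)
def _swap_kernel(edges, adj, n_target, max_tries, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n_edges = edges.shape[0]
    done = 0
    tries = 0
    while done < n_target and tries < max_tries:
        tries += 1
        e1 = np.random.randint(0, n_edges)
        e2 = np.random.randint(0, n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # propose replacing (a,b),(c,d) with (a,d),(c,b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 1] = d
        edges[e2, 1] = b
        edges[e2, 0] = c
        done += 1
    return done


def _rewire_edges(edges, adj, n_target, rng, max_try_factor=100):
    """In-place Maslov-Sneppen swaps on an edge array; returns swaps done."""
    seed = int(rng.integers(0, 2**31 - 1))
    done = _swap_kernel(edges, adj, n_target, max_try_factor * max(n_target, 1), seed)
    return done


def randomize_network(
    conn: Connectome, n_swaps_per_edge: int = 10, rng: np.random.Generator | None = None
) -> Connectome:
    """Degree-preserving randomization with weights riding on the edges.

    Preserves the binary degree sequence and the edge-weight multiset
    exactly; swaps that would create self-loops or multi-edges are rejected
    and retried.
    """
    rng = np.random.default_rng(rng)
    edges, weights = _edge_list(conn.weights)
    if edges.shape[0] < 2:
        raise ValueError("need at least 2 edges to rewire")
    adj = conn.weights > 0
    target = n_swaps_per_edge * edges.shape[0]
    done = _rewire_edges(edges, adj, target, rng)
    if done == 0:
        logger.warning("rewiring achieved 0/%d swaps; returning best effort", target)
    elif done < target:
        logger.warning("rewiring achieved only %d/%d swaps", done, target)
    n = conn.n_nodes
    w = np.zeros((n, n))
    w[edges[:, 0], edges[:, 1]] = weights
    w[edges[:, 1], edges[:, 0]] = weights
    return conn.with_weights(w)


# ---------------------------------------------------------------------------
# Normalized curve


@dataclass
class RichClubCurve:
    """Observed and null-normalized rich-club coefficients over k.

    ``regime`` is the maximal contiguous k interval with phi_norm > 1,
    as an inclusive ``(k_lo, k_hi)`` pair, or None if no such k exists.
    """

    k_grid: np.ndarray
    phi_w: np.ndarray
    phi_rand_mean: np.ndarray
    phi_rand_sd: np.ndarray
    phi_norm: np.ndarray
    p_k: np.ndarray
    regime: tuple | None
    n_null: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "phi_w": self.phi_w,
                "phi_rand_mean": self.phi_rand_mean,
                "phi_rand_sd": self.phi_rand_sd,
                "phi_norm": self.phi_norm,
                "p": self.p_k,
            }
        )

    def plot(self, ax=None, label: str | None = None):
        """Observed, null-mean and normalized curves on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.k_grid, self.phi_w, "ko-", ms=3, label="phi_w")
        ax.plot(self.k_grid, self.phi_rand_mean, "o-", color="gray", ms=3, label="phi_rand")
        ax.plot(self.k_grid, self.phi_norm, "ro-", ms=3, label="phi_norm" + (f" {label}" if label else ""))
        ax.axhline(1.0, color="k", lw=0.5, ls="--")
        ax.set_xlabel("degree level k")
        ax.set_ylabel("rich-club coefficient")
        ax.legend()
        return ax


def extract_regime(k_grid: np.ndarray, phi_norm: np.ndarray) -> tuple | None:
    """Longest contiguous run of k with phi_norm > 1 (first run wins ties)."""
    above = np.nan_to_num(phi_norm, nan=0.0) > 1
    best = None
    best_len = 0
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best = (int(k_grid[i]), int(k_grid[j]))
            i = j + 1
        else:
            i += 1
    return best


def normalized_curve(
    conn: Connectome,
    n_null: int = 1000,
    n_swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
) -> RichClubCurve:
    """Rich-club curve normalized against a rewired null ensemble.

    Per-k empirical p-values use the (1 + exceedances)/(n_null + 1)
    convention; nulls undefined at a level never count as exceedances.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(rng)
    deg = conn.degree()
    max_deg = int(deg.max()) if deg.size else 0
    k_grid = np.arange(1, max(max_deg, 1))
    edges, weights = _edge_list(conn.weights)
    denom_cum = np.concatenate([[0.0], np.cumsum(np.sort(weights)[::-1])])
    phi_obs = _curve_from_edges(deg, edges, weights, k_grid, denom_cum)

    target = n_swaps_per_edge * edges.shape[0]
    null_phis = np.empty((n_null, k_grid.size))
    for i in range(n_null):
        e = edges.copy()
        adj = conn.weights > 0
        _rewire_edges(e, adj, target, rng)
        null_phis[i] = _curve_from_edges(deg, e, weights, k_grid, denom_cum)

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN null levels
        rand_mean = np.nanmean(null_phis, axis=0)
        rand_sd = np.nanstd(null_phis, axis=0)
        phi_norm = phi_obs / rand_mean
    with np.errstate(invalid="ignore"):
        exceed = np.nansum(null_phis >= phi_obs[None, :], axis=0)
    p_k = (1.0 + exceed) / (n_null + 1.0)
    p_k = np.where(np.isnan(phi_obs), np.nan, p_k)
    phi_norm = np.where(np.isnan(phi_obs) | ~(rand_mean > 0), np.nan, phi_norm)
    regime = extract_regime(k_grid, phi_norm)
    return RichClubCurve(
        k_grid=k_grid,
        phi_w=phi_obs,
        phi_rand_mean=rand_mean,
        phi_rand_sd=rand_sd,
        phi_norm=phi_norm,
        p_k=p_k,
        regime=regime,
        n_null=n_null,
    )


# ---------------------------------------------------------------------------
# Group surfaces


def group_average(cohort, group: str) -> Connectome:
    """Element-wise mean of the group's subject weight matrices."""
    sids = cohort.subject_ids(group)
    if not sids:
        raise ValueError(f"group {group!r} is empty")
    stack = cohort.weight_stack(group)
    first = cohort.connectomes[sids[0]]
    return Connectome(weights=stack.mean(axis=0), node_ids=first.node_ids)


@dataclass
class RichClubGroupResults:
    """Per-k Welch t and permutation p for phi_w and phi_norm curves."""

    table: pd.DataFrame  # columns: family, k, t, p_perm, p_bonf, n_used
    k_levels: np.ndarray
    n_perm: int

    def summary(self) -> str:
        lines = ["Rich-club group comparison (Welch t, Freedman-Lane permutation)"]
        lines.append(f"k levels tested: {len(self.k_levels)}; permutations: {self.n_perm}")
        sig = self.table[self.table["p_bonf"] < 0.05]
        if sig.empty:
            lines.append("No k level significant after Bonferroni correction.")
        else:
            lines.append(sig.to_string(index=False))
        return "\n".join(lines)


class RichClubGroupTest:
    """Group comparison of per-subject rich-club curves.

    Curves (phi_w and phi_norm, each subject normalized against its own
    rewired null ensemble) are compared between groups with Welch t-tests
    and Freedman-Lane permutation p-values with age as nuisance, Bonferroni
    corrected across k levels and the two coefficient families.  Levels
    defined in fewer than ``min_defined_fraction`` of subjects are dropped.
    """

    def __init__(self, cohort, n_null: int = 1000, n_swaps_per_edge: int = 10,
                 min_defined_fraction: float = 0.9):
        self.cohort = cohort
        self.n_null = n_null
        self.n_swaps_per_edge = n_swaps_per_edge
        self.min_defined_fraction = min_defined_fraction

    def subject_curves(self, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(k_levels, phi_w, phi_norm) arrays of shape (n_subjects, n_k)."""
        import hashlib

        conns = [self.cohort.connectomes[s] for s in self.cohort.subject_ids()]
        max_deg = max(int(c.degree().max()) for c in conns)
        k_grid = np.arange(1, max(max_deg, 1))
        phi = np.full((len(conns), k_grid.size), np.nan)
        phin = np.full((len(conns), k_grid.size), np.nan)
        base_seed = int(np.random.default_rng(rng).integers(0, 2**31 - 1))
        for i, c in enumerate(conns):
            # null stream keyed by the network content: identical networks
            # receive identical null ensembles (and identical phi_norm)
            digest = int.from_bytes(
                hashlib.blake2b(c.weights.tobytes(), digest_size=4).digest(), "little"
            )
            sub_rng = np.random.default_rng(np.random.SeedSequence([base_seed, digest]))
            curve = normalized_curve(c, self.n_null, self.n_swaps_per_edge, sub_rng)
            m = curve.k_grid.size
            phi[i, :m] = curve.phi_w
            phin[i, :m] = curve.phi_norm
        defined = (~np.isnan(phi)).mean(axis=0) >= self.min_defined_fraction
        n_drop = int((~defined).sum())
        if n_drop:
            logger.info("dropping %d k levels defined in <%.0f%% of subjects",
                        n_drop, 100 * self.min_defined_fraction)
        return k_grid[defined], phi[:, defined], phin[:, defined]

    def fit(self, n_perm: int = 1000, rng=None) -> RichClubGroupResults:
        from .inference import perm_group_test

        rng = np.random.default_rng(rng)
        k_levels, phi, phin = self.subject_curves(rng)
        groups = self.cohort.group_labels()
        ages = self.cohort.ages()
        rows = []
        n_tests = 2 * k_levels.size
        for family, mat in (("phi_w", phi), ("phi_norm", phin)):
            for j, k in enumerate(k_levels):
                col = mat[:, j]
                keep = ~np.isnan(col)
                t, p = perm_group_test(col[keep], groups[keep], ages[keep],
                                       n_perm=n_perm, rng=rng)
                rows.append({
                    "family": family,
                    "k": int(k),
                    "t": t,
                    "p_perm": p,
                    "p_bonf": min(1.0, p * n_tests),
                    "n_used": int(keep.sum()),
                })
        return RichClubGroupResults(table=pd.DataFrame(rows), k_levels=k_levels, n_perm=n_perm)
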