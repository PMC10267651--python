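"""Permutation inference for group differences and brain-behavior coupling.

The engine mirrors permutation GLM practice for two-group designs with a
nuisance covariate: the observed statistic is a Welch (unequal-variance)
two-sample t; the null distribution is built with Freedman-Lane residual
permutation — the outcome is regressed on the demeaned nuisance (age), the
residuals are permuted, the nuisance fit is added back, and the statistic
is recomputed.  Permuting residuals rather than raw values matters here
because age differs between the groups and would otherwise masquerade as a
group effect.  Empirical p-values use (1 + exceedances)/(n_perm + 1), and
multiple comparisons across ROIs and measures are Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS, BEHAVIOR_COLUMNS
from .metrics import METRICS, metric_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Core two-sample machinery


def welch_t(values: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Welch t (group1 minus group2) for columns of ``values``.

    Zero variance in both groups yields t = 0 (flagged upstream as p = 1).
    """
    v = np.atleast_2d(values.T).T  # ensure (n, R)
    y1, y2 = v[mask1], v[~mask1]
    n1, n2 = y1.shape[0], y2.shape[0]
    m1, m2 = y1.mean(axis=0), y2.mean(axis=0)
    s1 = y1.var(axis=0, ddof=1)
    s2 = y2.var(axis=0, ddof=1)
    denom = np.sqrt(s1 / n1 + s2 / n2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
        # zero within-group variance with distinct means: an unbounded effect
        t = np.where((denom == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    return t if values.ndim > 1 else float(t[0])


def _nuisance_split(values: np.ndarray, age: np.ndarray | None):
    """Fitted nuisance part and residuals of values ~ 1 + demeaned age."""
    v = np.atleast_2d(values.T).T
    n = v.shape[0]
    if age is None:
        z = np.ones((n, 1))
    else:
        z = np.column_stack([np.ones(n), np.asarray(age, float) - np.mean(age)])
    gamma, *_ = np.linalg.lstsq(z, v, rcond=None)
    fitted = z @ gamma
    return fitted, v - fitted


def perm_group_test(
    values: np.ndarray,
    groups: np.ndarray,
    age: np.ndarray | None = None,
    n_perm: int = 20000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Welch t with Freedman-Lane permutation p for one scalar per subject.

    Returns ``(t_obs, p)`` with the contrast APD minus HC (two-sided p).
    ``exhaustive=True`` enumerates all distinct group-label partitions
    instead of Monte-Carlo sampling; this is exact when the nuisance is
    absent or constant and is intended for small samples.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask1 = groups == GROUPS[0]
    n = values.size
    if mask1.sum() < 3 or (~mask1).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    t_obs = welch_t(values, mask1)
    if np.var(values) == 0:
        logger.warning("zero variance; t undefined, p set to 1")
        return 0.0, 1.0
    if exhaustive:
        if age is not None and np.ptp(np.asarray(age, float)) > 0:
            raise ValueError("exhaustive mode requires a constant (or absent) nuisance")
        n1 = int(mask1.sum())
        count = 0
        total = 0
        for subset in combinations(range(n), n1):
            m = np.zeros(n, dtype=bool)
            m[list(subset)] = True
            t = welch_t(values, m)
            total += 1
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        return float(t_obs), count / total
    rng = np.random.default_rng(rng)
    fitted, resid = _nuisance_split(values, age)
    exceed = 0
    # tie tolerance: permutations realizing the observed partition must count
    # as exceedances despite reordered floating-point summation
    thresh = abs(t_obs) - 1e-9 * max(1.0, abs(t_obs))
    for _ in range(n_perm):
        y = fitted[:, 0] + resid[rng.permutation(n), 0]
        if abs(welch_t(y, mask1)) >= thresh:
            exceed += 1
    return float(t_obs), (1.0 + exceed) / (n_perm + 1.0)


def _perm_welch_matrix(values, mask1, age, n_perm, rng):
    """Vectorized Freedman-Lane Welch permutation over columns.

    Returns (t_obs (R,), p (R,)).  Shares one permutation sequence across
    columns, which preserves spatial dependence under the null.
    """
    n, n_cols = values.shape
    t_obs = welch_t(values, mask1)
    fitted, resid = _nuisance_split(values, age)
    exceed = np.zeros(n_cols)
    thresh = np.abs(t_obs) - 1e-9 * np.maximum(1.0, np.abs(t_obs))  # tie tolerance
    for _ in range(n_perm):
        y = fitted + resid[rng.permutation(n)]
        exceed += np.abs(welch_t(y, mask1)) >= thresh
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[values.var(axis=0) == 0] = 1.0
    return t_obs, p


# ---------------------------------------------------------------------------
# Nodal metric scan


@dataclass
class NodalGroupResults:
    """Group-difference table per (roi_id, metric), Bonferroni corrected."""

    table: pd.DataFrame
    bonferroni_factor: int
    n_perm: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_bonf"] < alpha]

    def summary(self) -> str:
        lines = [
            "Nodal group differences (Welch t, Freedman-Lane permutation, "
            f"{self.n_perm} permutations, Bonferroni x{self.bonferroni_factor})"
        ]
        sig = self.significant()
        if sig.empty:
            lines.append("No (ROI, metric) pair significant after correction.")
            lines.append(self.table.head(5).to_string(index=False))
        else:
            lines.append(sig.to_string(index=False))
        return "\n".join(lines)


class NodalGroupTest:
    """Permutation group comparison of all nodal metrics across all ROIs.

    Bonferroni correction spans n_roi x n_metrics tests, matching a
    whole-connectome family of hub measures.
    """

    def __init__(self, cohort, metrics_table: pd.DataFrame, metrics=METRICS):
        self.cohort = cohort
        self.metrics_table = metrics_table
        self.metrics = tuple(metrics)

    def fit(self, n_perm: int = 20000, rng=None) -> NodalGroupResults:
        rng = np.random.default_rng(rng)
        groups = self.cohort.group_labels()
        mask1 = groups == GROUPS[0]
        ages = self.cohort.ages()
        node_ids = self.cohort.node_ids
        factor = len(node_ids) * len(self.metrics)
        rows = []
        for metric in self.metrics:
            mat = metric_matrix(self.metrics_table, self.cohort, metric)
            nan_cols = np.isnan(mat).any(axis=0)
            t = np.zeros(mat.shape[1])
            p = np.ones(mat.shape[1])
            clean = ~nan_cols
            if clean.any():
                t[clean], p[clean] = _perm_welch_matrix(mat[:, clean], mask1, ages, n_perm, rng)
            for j in np.nonzero(nan_cols)[0]:
                keep = ~np.isnan(mat[:, j])
                if keep.sum() >= 6 and mask1[keep].sum() >= 3 and (~mask1)[keep].sum() >= 3:
                    t[j], p[j] = perm_group_test(
                        mat[keep, j], groups[keep], ages[keep], n_perm=n_perm, rng=rng
                    )
                else:
                    t[j], p[j] = np.nan, np.nan
            for j, rid in enumerate(node_ids):
                rows.append(
                    {
                        "roi_id": int(rid),
                        "metric": metric,
                        "t": t[j],
                        "p_perm": p[j],
                        "p_bonf": min(1.0, p[j] * factor) if np.isfinite(p[j]) else np.nan,
                        "direction": "APD>HC" if t[j] > 0 else "HC>APD",
                    }
                )
        table = pd.DataFrame(rows).sort_values(["p_bonf", "roi_id"]).reset_index(drop=True)
        return NodalGroupResults(table=table, bonferroni_factor=factor, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Partial correlation and behavior scan


def _residualize(x: np.ndarray, covar: np.ndarray | None) -> np.ndarray:
    fitted, resid = _nuisance_split(x, covar)
    return resid[:, 0] if x.ndim == 1 else resid


def partial_correlation(x, y, covar) -> float:
    """Pearson correlation of x and y after residualizing both on age.

    Degenerate inputs (either residual identically zero) return 0.0 with a
    logged flag rather than NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = _residualize(x, covar)
    ry = _residualize(y, covar)
    sx, sy = np.std(rx), np.std(ry)
    # residuals indistinguishable from zero at float precision are degenerate
    if sx <= 1e-10 * max(np.std(x), 1.0) or sy <= 1e-10 * max(np.std(y), 1.0):
        logger.warning("degenerate partial correlation (zero-variance residual); r set to 0")
        return 0.0
    return float(np.dot(rx - rx.mean(), ry - ry.mean()) / (len(rx) * sx * sy))


@dataclass
class BehaviorScanResults:
    """Partial correlations between a nodal metric and behavior scores."""

    table: pd.DataFrame  # scope, behavior, roi_id, n, r, p_perm, p_bonf
    metric: str
    bonferroni_factor: int
    n_perm: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_bonf"] < alpha]

    def top(self, scope: str, behavior: str) -> pd.Series:
        sub = self.table[(self.table["scope"] == scope) & (self.table["behavior"] == behavior)]
        return sub.loc[sub["r"].abs().idxmax()]

    def summary(self) -> str:
        lines = [
            f"Metric-behavior partial correlations ({self.metric}, age-controlled, "
            f"{self.n_perm} permutations, Bonferroni x{self.bonferroni_factor})"
        ]
        sig = self.significant()
        lines.append(
            "No correlation significant after correction." if sig.empty else sig.to_string(index=False)
        )
        return "\n".join(lines)


class BehaviorCorrelationScan:
    """Scan of (metric, ROI) x behavior partial correlations per group.

    Run per group and pooled: group-specific associations can be invisible
    in the pooled sample and vice versa, so both surfaces are reported.
    Subjects missing a behavior score are dropped pairwise for that score.
    """

    def __init__(self, cohort, metrics_table, metric: str = "apl",
                 behaviors=("spatial_advantage",), pooled: bool = True):
        self.cohort = cohort
        self.metrics_table = metrics_table
        self.metric = metric
        self.behaviors = tuple(behaviors)
        self.scopes = list(GROUPS) + (["pooled"] if pooled else [])

    def fit(self, n_perm: int = 20000, rng=None) -> BehaviorScanResults:
        rng = np.random.default_rng(rng)
        node_ids = self.cohort.node_ids
        factor = len(node_ids) * len(self.behaviors)
        mat_all = metric_matrix(self.metrics_table, self.cohort, self.metric)
        groups = self.cohort.group_labels()
        ages_all = self.cohort.ages()
        rows = []
        for scope in self.scopes:
            in_scope = np.ones(len(groups), bool) if scope == "pooled" else groups == scope
            for behavior in self.behaviors:
                b_all = self.cohort.behavior(behavior)
                keep = in_scope & ~np.isnan(b_all) & ~np.isnan(mat_all).any(axis=1)
                n = int(keep.sum())
                if n < 5:
                    logger.warning("scope %s behavior %s: only %d usable subjects; skipped",
                                   scope, behavior, n)
                    continue
                mat = _residualize(mat_all[keep], ages_all[keep])
                b = _residualize(b_all[keep], ages_all[keep])
                mz = (mat - mat.mean(axis=0)) / np.where(mat.std(axis=0) > 0, mat.std(axis=0), 1.0)
                mz[:, mat.std(axis=0) == 0] = 0.0
                sb = b.std()
                bz = (b - b.mean()) / (sb if sb > 0 else 1.0)
                r_obs = bz @ mz / n
                exceed = np.zeros(len(node_ids))
                thresh = np.abs(r_obs) - 1e-12  # tie tolerance for re-summation
                for _ in range(n_perm):
                    r_perm = bz[rng.permutation(n)] @ mz / n
                    exceed += np.abs(r_perm) >= thresh
                p = (1.0 + exceed) / (n_perm + 1.0)
                for j, rid in enumerate(node_ids):
                    rows.append({
                        "scope": scope,
                        "behavior": behavior,
                        "roi_id": int(rid),
                        "n": n,
                        "r": r_obs[j],
                        "p_perm": p[j],
                        "p_bonf": min(1.0, p[j] * factor),
                    })
        table = pd.DataFrame(rows).sort_values(["scope", "behavior", "p_bonf"]).reset_index(drop=True)
        return BehaviorScanResults(table=table, metric=self.metric,
                                   bonferroni_factor=factor, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Demographics


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    obs = np.asarray(table, dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def demographics_table(manifest: pd.DataFrame, categorical=()) -> pd.DataFrame:
    """Group summaries and tests for age, behaviors and categorical fields.

    Continuous variables get a pooled two-sample t-test; categorical fields
    (extra manifest columns such as gender/handedness) get a Pearson
    chi-square without continuity correction.
    """
    rows = []
    g1 = manifest[manifest["group"] == GROUPS[0]]
    g2 = manifest[manifest["group"] == GROUPS[1]]
    for col in ["age", *[c for c in BEHAVIOR_COLUMNS if manifest[c].notna().any()]]:
        x1 = g1[col].dropna().to_numpy(float)
        x2 = g2[col].dropna().to_numpy(float)
        t, p = stats.ttest_ind(x2, x1, equal_var=True)  # printed as HC vs APD contrast
        rows.append({
            "variable": col, "test": "t",
            f"{GROUPS[0].lower()}_mean": x1.mean(), f"{GROUPS[0].lower()}_sd": x1.std(ddof=1),
            f"{GROUPS[0].lower()}_n": len(x1),
            f"{GROUPS[1].lower()}_mean": x2.mean(), f"{GROUPS[1].lower()}_sd": x2.std(ddof=1),
            f"{GROUPS[1].lower()}_n": len(x2),
            "statistic": float(t), "p_value": float(p),
        })
    for col in categorical:
        crosstab = pd.crosstab(manifest["group"], manifest[col])
        chi2, p = chi_square_counts(crosstab.to_numpy())
        rows.append({"variable": col, "test": "chi2", "statistic": chi2, "p_value": p})
    return pd.DataFrame(rows)
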