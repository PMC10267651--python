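"""Reading, writing and validation of connectomes, parcellations and cohorts.

A *connectome* here is one subject's symmetric, non-negative, weighted
adjacency matrix over a fixed set of atlas regions (ROIs).  Weights are
dimensionless anisotropy-derived edge strengths; a weight of 0 means "no
reconstructed connection".  All public reports index nodes by their 1-based
atlas ``roi_id``, never by matrix position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Relative tolerance under which an asymmetric matrix is repaired by
#: averaging with its transpose; anything larger is rejected as a data error.
SYMMETRY_RTOL = 1e-9

GROUPS = ("APD", "HC")

BEHAVIOR_COLUMNS = (
    "total_advantage",
    "spatial_advantage",
    "talker_advantage",
    "high_cue",
    "low_cue",
)


class ConnectomeFormatError(ValueError):
    """Raised when an input file cannot be parsed into a square numeric table."""


class ConnectomeValidationError(ValueError):
    """Raised when a parsed matrix violates connectome invariants."""


@dataclass(frozen=True)
class Connectome:
    """One subject's weighted undirected brain network.

    Parameters
    ----------
    weights : (N, N) ndarray
        Symmetric non-negative edge weights, zero diagonal.
    node_ids : (N,) ndarray of int
        Strictly increasing atlas ROI identifiers (1-based).
    """

    weights: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        ids = np.asarray(self.node_ids, dtype=int)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_ids", ids)
        validate_matrix(w)
        if ids.shape != (w.shape[0],):
            raise ConnectomeValidationError(
                f"node_ids length {ids.shape} does not match matrix size {w.shape[0]}"
            )
        if np.any(np.diff(ids) <= 0) or np.any(ids < 1):
            raise ConnectomeValidationError("node_ids must be unique, >=1 and strictly increasing")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def degree(self) -> np.ndarray:
        """Binary degree: count of strictly positive incident weights."""
        return (self.weights > 0).sum(axis=1)

    def strength(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def index_of(self, roi_id: int) -> int:
        """Matrix position of an atlas ROI id."""
        pos = np.searchsorted(self.node_ids, roi_id)
        if pos >= len(self.node_ids) or self.node_ids[pos] != roi_id:
            raise KeyError(f"roi_id {roi_id} not present in this connectome")
        return int(pos)

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return Connectome(weights=weights, node_ids=self.node_ids)


def validate_matrix(w: np.ndarray) -> None:
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeFormatError(f"matrix is not square: shape {w.shape}")
    if w.shape[0] < 3:
        raise ConnectomeValidationError(f"need at least 3 nodes, got {w.shape[0]}")
    if not np.all(np.isfinite(w)):
        raise ConnectomeValidationError("matrix contains non-finite entries")
    if np.any(w < 0):
        raise ConnectomeValidationError("matrix contains negative weights")
    scale = np.abs(w).max()
    if scale > 0:
        asym = np.abs(w - w.T).max() / scale
        if asym > SYMMETRY_RTOL:
            raise ConnectomeValidationError(
                f"matrix asymmetric beyond tolerance (relative asymmetry {asym:.3g})"
            )
    if np.any(np.diag(w) != 0):
        raise ConnectomeValidationError("diagonal must be zero")


def _clean_matrix(w: np.ndarray, source: str) -> np.ndarray:
    """Symmetrize sub-tolerance asymmetry and force the diagonal to zero."""
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeFormatError(f"{source}: matrix is not square, shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ConnectomeValidationError(f"{source}: non-finite entries")
    if np.any(w < 0):
        raise ConnectomeValidationError(f"{source}: negative weights")
    scale = np.abs(w).max()
    if scale > 0:
        asym = np.abs(w - w.T).max() / scale
        if asym > SYMMETRY_RTOL:
            raise ConnectomeValidationError(
                f"{source}: asymmetry {asym:.3g} exceeds relative tolerance {SYMMETRY_RTOL:g}"
            )
        if asym > 0:
            w = 0.5 * (w + w.T)
    if np.any(np.diag(w) != 0):
        logger.warning("%s: nonzero diagonal forced to zero", source)
        w = w.copy()
        np.fill_diagonal(w, 0.0)
    return w


def read_connectome(path, dialect: str = "headered-tsv", node_ids=None) -> Connectome:
    """Read a single connectivity matrix.

    ``headered-tsv``: first row and first column carry the roi_ids.
    ``bare-csv``: plain comma-separated square matrix; node ids are taken from
    ``node_ids`` (e.g. the parcellation order) or default to ``1..N``.
    """
    path = Path(path)
    if dialect == "headered-tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise ConnectomeFormatError(f"{path}: cannot parse headered TSV: {exc}") from exc
        ids = df.columns.astype(int).to_numpy()
        row_ids = df.index.astype(int).to_numpy()
        if not np.array_equal(ids, row_ids):
            raise ConnectomeFormatError(f"{path}: row and column roi_ids disagree")
        w = df.to_numpy(dtype=float)
    elif dialect == "bare-csv":
        try:
            w = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
        except Exception as exc:  # noqa: BLE001
            raise ConnectomeFormatError(f"{path}: cannot parse bare CSV: {exc}") from exc
        ids = (
            np.asarray(node_ids, dtype=int)
            if node_ids is not None
            else np.arange(1, w.shape[0] + 1)
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    w = _clean_matrix(w, str(path))
    return Connectome(weights=w, node_ids=ids)


def write_connectome(conn: Connectome, path, dialect: str = "headered-tsv") -> None:
    """Write a matrix so that reading it back reproduces weights bit-for-bit."""
    path = Path(path)
    if dialect == "headered-tsv":
        df = pd.DataFrame(conn.weights, index=conn.node_ids, columns=conn.node_ids)
        df.to_csv(path, sep="\t", float_format="%.17g")
    elif dialect == "bare-csv":
        np.savetxt(path, conn.weights, delimiter=",", fmt="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Parcellation


def read_parcellation(path) -> pd.DataFrame:
    """Parcellation lookup table: roi_id, label, name, x, y, z (MNI mm)."""
    df = pd.read_csv(path, sep="\t")
    required = ["roi_id", "label", "name", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConnectomeFormatError(f"{path}: parcellation missing columns {missing}")
    if df["roi_id"].duplicated().any():
        raise ConnectomeValidationError(f"{path}: duplicate roi_id in parcellation")
    return df[required].astype({"roi_id": int, "x": int, "y": int, "z": int})


def write_parcellation(parc: pd.DataFrame, path) -> None:
    parc.to_csv(path, sep="\t", index=False)


def write_hub_table(report, parc: pd.DataFrame, path) -> pd.DataFrame:
    """Write the hub-region table (atlas label, anatomical name, MNI coords).

    ``report`` is a :class:`~connectomestats.hubs.HubReport`.  Every hub
    roi_id must be present in the parcellation.
    """
    hub_ids = sorted(report.hub_ids)
    known = set(parc["roi_id"])
    unknown = [i for i in hub_ids if i not in known]
    if unknown:
        raise KeyError(f"hub roi_ids {unknown} absent from parcellation")
    lut = parc.set_index("roi_id")
    rows = []
    for rid in hub_ids:
        r = lut.loc[rid]
        rows.append(
            {
                "roi_id": rid,
                "label": r["label"],
                "anatomical_name": r["name"],
                "mni_x": int(r["x"]),
                "mni_y": int(r["y"]),
                "mni_z": int(r["z"]),
                "criteria_hits": int(report.criteria_hits[rid]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "label",
            "anatomical_name",
            "mni_x",
            "mni_y",
            "mni_z",
            "criteria_hits",
        ],
    )
    out.to_csv(path, sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class Cohort:
    """A two-group sample of subjects with connectomes and covariates.

    ``manifest`` holds one row per subject: subject_id, group (APD/HC), age,
    and the five optional behavioral z-scores (NaN where missing).
    ``connectomes`` maps subject_id -> Connectome; all share node_ids.
    """

    manifest: pd.DataFrame
    connectomes: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        bad = set(self.manifest["group"]) - set(GROUPS)
        if bad:
            row = self.manifest[self.manifest["group"].isin(bad)].iloc[0]
            raise ConnectomeValidationError(
                f"unknown group label {row['group']!r} for subject {row['subject_id']!r}"
            )
        for g in GROUPS:
            if not (self.manifest["group"] == g).any():
                raise ConnectomeValidationError(f"group {g} is empty")
        ages = self.manifest["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages <= 0):
            raise ConnectomeValidationError("ages must be finite and positive")
        ref = None
        for sid in self.manifest["subject_id"]:
            if sid not in self.connectomes:
                raise ConnectomeValidationError(f"no connectome for subject {sid!r}")
            ids = self.connectomes[sid].node_ids
            if ref is None:
                ref = ids
            elif not np.array_equal(ref, ids):
                raise ConnectomeValidationError(f"subject {sid!r} has inconsistent node_ids")

    @property
    def node_ids(self) -> np.ndarray:
        first = self.manifest["subject_id"].iloc[0]
        return self.connectomes[first].node_ids

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def subject_ids(self, group: str | None = None) -> list:
        m = self.manifest
        if group is not None:
            m = m[m["group"] == group]
        return list(m["subject_id"])

    def group_sizes(self) -> dict:
        return {g: int((self.manifest["group"] == g).sum()) for g in GROUPS}

    def ages(self, group: str | None = None) -> np.ndarray:
        m = self.manifest
        if group is not None:
            m = m[m["group"] == group]
        return m["age"].to_numpy(dtype=float)

    def group_labels(self) -> np.ndarray:
        return self.manifest["group"].to_numpy()

    def weight_stack(self, group: str | None = None) -> np.ndarray:
        """(n_subjects, N, N) array of weight matrices in manifest order."""
        sids = self.subject_ids(group)
        return np.stack([self.connectomes[s].weights for s in sids])

    def behavior(self, name: str, group: str | None = None) -> np.ndarray:
        if name not in BEHAVIOR_COLUMNS:
            raise KeyError(f"unknown behavior {name!r}")
        m = self.manifest
        if group is not None:
            m = m[m["group"] == group]
        return m[name].to_numpy(dtype=float)


def _read_manifest(manifest_path) -> pd.DataFrame:
    path = Path(manifest_path)
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "group", "age"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConnectomeFormatError(f"{path}: manifest missing columns {missing}")
    for col in BEHAVIOR_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_cohort(manifest_path, matrix_dir, dialect: str = "headered-tsv", node_ids=None) -> Cohort:
    """Load a cohort: manifest plus one matrix file per subject.

    Matrix files are resolved as ``<matrix_dir>/<subject_id>.(tsv|csv)``.
    """
    manifest = _read_manifest(manifest_path)
    matrix_dir = Path(matrix_dir)
    conns = {}
    for sid in manifest["subject_id"]:
        candidates = [matrix_dir / f"{sid}.tsv", matrix_dir / f"{sid}.csv"]
        found = [p for p in candidates if p.exists()]
        if len(found) != 1:
            raise FileNotFoundError(
                f"expected exactly one matrix file for subject {sid!r} in {matrix_dir}, "
                f"found {len(found)}"
            )
        conns[sid] = read_connectome(found[0], dialect=dialect, node_ids=node_ids)
    cohort = Cohort(manifest=manifest, connectomes=conns)
    n_missing = {c: int(manifest[c].isna().sum()) for c in BEHAVIOR_COLUMNS}
    logger.info("cohort loaded: groups %s, missing behaviors %s", cohort.group_sizes(), n_missing)
    return cohort


def write_cohort(cohort: Cohort, out_dir, dialect: str = "headered-tsv") -> None:
    out_dir = Path(out_dir)
    (out_dir / "matrices").mkdir(parents=True, exist_ok=True)
    suffix = "tsv" if dialect == "headered-tsv" else "csv"
    for sid in cohort.subject_ids():
        write_connectome(cohort.connectomes[sid], out_dir / "matrices" / f"{sid}.{suffix}", dialect)
    cohort.manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False, float_format="%.17g")
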