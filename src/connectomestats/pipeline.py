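"""End-to-end pipeline: simulate/load -> metrics -> rich club -> hubs -> NBS -> inference.

One :class:`RunConfig` drives every stage; a single master seed spawns a
named substream per stage, so changing e.g. the number of rich-club nulls
never perturbs the NBS permutations.  Stage outputs are written as TSV
next to a consolidated JSON report; the cohort and the per-subject metric
table act as caches — re-running with the same config and seed reproduces
every number, and deleting downstream outputs reuses the cached upstream
files bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hubs import ClassStrengthTest, hubs_per_group
from .inference import BehaviorCorrelationScan, NodalGroupTest, demographics_table
from .io import GROUPS, read_cohort, read_parcellation, write_hub_table
from .metrics import cohort_nodal_metrics
from .nbs import NBS
from .richclub import RichClubGroupTest, group_average, normalized_curve
from .simulate import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

_STAGE = {"simulate": 0, "null": 1, "nbs": 2, "stats": 3, "richclub_group": 4, "behavior": 5}


@dataclass
class RunConfig:
    """Configuration for a full analysis run."""

    out_dir: str = "run"
    cohort_dir: str | None = None  # None -> simulate a cohort into out_dir
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_null: int = 1000  # null networks for the group-averaged curves
    n_null_subject: int = 100  # null networks per subject for group tests
    n_perm_nbs: int = 10000
    n_perm_stats: int = 20000
    t_threshold: float = 3.9805
    min_hits: int = 2
    hub_percentile: float = 0.2
    edge_mask_fraction: float = 0.5
    behaviors: tuple = ("spatial_advantage",)
    behavior_metric: str = "apl"

    def __post_init__(self):
        for name in ("n_null", "n_null_subject", "n_perm_nbs", "n_perm_stats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.hub_percentile < 0.5):
            raise ValueError("hub_percentile must be in (0, 0.5)")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @classmethod
    def ci_profile(cls, **overrides) -> "RunConfig":
        """Reduced-scale profile so a full run finishes in minutes."""
        sim = SimulationConfig(n_nodes=60, n_per_group=(15, 15))
        defaults = dict(
            simulation=sim, n_null=100, n_null_subject=25, n_perm_nbs=500, n_perm_stats=2000
        )
        defaults.update(overrides)
        return cls(**defaults)

    def config_hash(self) -> str:
        """Fingerprint of the analytic parameters (paths excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k not in ("out_dir", "cohort_dir")}
        blob = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_rng(cfg: RunConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, _STAGE[stage]]))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the consolidated report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "version": __version__,
        }
    }

    # --- cohort -----------------------------------------------------------
    stage = "cohort"
    try:
        if cfg.cohort_dir is not None:
            cohort_dir = Path(cfg.cohort_dir)
            cohort = read_cohort(cohort_dir / "manifest.tsv", cohort_dir / "matrices")
            parc_path = cohort_dir / "parcellation.tsv"
        else:
            cohort_dir = out / "cohort"
            if (cohort_dir / "manifest.tsv").exists():
                cohort = read_cohort(cohort_dir / "manifest.tsv", cohort_dir / "matrices")
            else:
                cohort, _ = generate_cohort(
                    cfg.simulation.replace(seed=cfg.seed), out_dir=cohort_dir
                )
            parc_path = cohort_dir / "parcellation.tsv"
        parc = read_parcellation(parc_path) if parc_path.exists() else None
        report["cohort"] = {"group_sizes": cohort.group_sizes(), "n_nodes": cohort.n_nodes}

        # --- nodal metrics (cached) --------------------------------------
        stage = "metrics"
        metrics_path = out / "metrics.tsv"
        if metrics_path.exists():
            metrics = pd.read_csv(metrics_path, sep="\t")
            metrics["subject_id"] = metrics["subject_id"].astype(str)
        else:
            metrics = cohort_nodal_metrics(cohort)
            metrics.to_csv(metrics_path, sep="\t", index=False, float_format="%.17g")

        # --- rich club ----------------------------------------------------
        stage = "richclub"
        rng = _stage_rng(cfg, "null")
        curves = {}
        for g in GROUPS:
            curves[g] = normalized_curve(group_average(cohort, g), n_null=cfg.n_null, rng=rng)
        pd.concat(
            [c.to_frame().assign(group=g) for g, c in curves.items()], ignore_index=True
        ).to_csv(out / "richclub.tsv", sep="\t", index=False)
        rc_test = RichClubGroupTest(cohort, n_null=cfg.n_null_subject).fit(
            n_perm=cfg.n_perm_stats, rng=_stage_rng(cfg, "richclub_group")
        )
        rc_test.table.to_csv(out / "richclub_group_tests.tsv", sep="\t", index=False)
        report["richclub"] = {
            g: {"regime": curves[g].regime, "n_null": cfg.n_null} for g in GROUPS
        }
        report["richclub"]["group_test_min_p_bonf"] = float(rc_test.table["p_bonf"].min())

        # --- hubs and connection classes ----------------------------------
        stage = "hubs"
        hub_reports = hubs_per_group(cohort, min_hits=cfg.min_hits, percentile=cfg.hub_percentile)
        hubs_by_group = {g: r.hub_ids for g, r in hub_reports.items()}
        if parc is not None:
            for g, rep in hub_reports.items():
                write_hub_table(rep, parc, out / f"hubs_{g}.tsv")
        cls_res = ClassStrengthTest(cohort, hubs_by_group).fit(
            n_perm=cfg.n_perm_stats, rng=_stage_rng(cfg, "stats")
        )
        cls_res.strengths.to_csv(
            out / "class_strengths.tsv", sep="\t", index=False, float_format="%.17g"
        )
        cls_res.table.to_csv(out / "class_strength_tests.tsv", sep="\t", index=False)
        report["hubs"] = {
            g: sorted(hubs_by_group[g]) for g in GROUPS
        }
        report["hubs"]["intersection"] = sorted(hubs_by_group["APD"] & hubs_by_group["HC"])
        report["hubs"]["sets_equal"] = hubs_by_group["APD"] == hubs_by_group["HC"]
        report["class_strengths"] = cls_res.table.to_dict("records")

        # --- NBS -----------------------------------------------------------
        stage = "nbs"
        nbs_res = NBS(
            cohort, t_threshold=cfg.t_threshold, edge_mask_fraction=cfg.edge_mask_fraction
        ).fit(n_perm=cfg.n_perm_nbs, rng=_stage_rng(cfg, "nbs"))
        report["nbs"] = {d: r.to_records() for d, r in nbs_res.items()}
        (out / "nbs.json").write_text(json.dumps(report["nbs"], indent=2) + "\n")

        # --- nodal group tests ---------------------------------------------
        stage = "inference"
        nodal = NodalGroupTest(cohort, metrics).fit(
            n_perm=cfg.n_perm_stats, rng=_stage_rng(cfg, "stats")
        )
        nodal.table.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        report["nodal_tests"] = {
            "bonferroni_factor": nodal.bonferroni_factor,
            "significant": nodal.significant().to_dict("records"),
        }

        # --- behavior correlations -----------------------------------------
        stage = "behavior"
        scan = BehaviorCorrelationScan(
            cohort, metrics, metric=cfg.behavior_metric, behaviors=cfg.behaviors
        ).fit(n_perm=cfg.n_perm_stats, rng=_stage_rng(cfg, "behavior"))
        scan.table.to_csv(out / "correlations.tsv", sep="\t", index=False)
        report["behavior"] = {"significant": scan.significant().to_dict("records")}

        # --- demographics ---------------------------------------------------
        stage = "demographics"
        demo = demographics_table(cohort.manifest)
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
        report["demographics"] = demo.to_dict("records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonify) + "\n")
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
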