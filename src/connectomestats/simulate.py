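"""Synthetic two-group connectome cohorts with planted structure.

The generator emulates the study design this package analyzes: two groups
of ~29 school-aged children, each subject a symmetric QA-like weighted
connectivity matrix over an atlas of N regions.  Four features are
planted so every downstream analysis has a known answer:

* a rich club — a hub block with denser wiring (``p_rich``) and stronger
  weights (``rich_weight_multiplier``) than feeder/local connections;
* consensus hub nodes (the hub block itself);
* a localized group effect — all edges incident to ``effect_node`` are
  attenuated in one group, which raises that node's average path length
  and perturbs betweenness rankings;
* a one-group metric-behavior correlation — the ``spatial_advantage``
  score of ``behavior_group`` subjects is drawn with target correlation
  ``behavior_target_r`` against their nodal APL at a reporter node.

Edge weights are lognormal: anisotropy-weighted connectome edges are
positive and right-skewed, and the lognormal is the simplest matching
family.  Subject-to-subject variability combines independent edge dropout
and multiplicative lognormal noise.  Ages are uniform with the control
group shifted one year older, reproducing the age confound the inference
engine must absorb.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .io import (
    BEHAVIOR_COLUMNS,
    Cohort,
    Connectome,
    write_cohort,
    write_parcellation,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Defaults are the desk-scale study emulation (N=90 regions, 29+29
    subjects); :meth:`study_scale` switches to the full 246-region atlas
    size.  Probabilities must satisfy ``p_rich >= p_feeder >= p_local`` so
    the planted topology actually is a rich club.
    """

    n_nodes: int = 90
    n_per_group: tuple = (29, 29)
    hub_fraction: float = 0.2
    p_rich: float = 0.9
    p_feeder: float = 0.4
    p_local: float = 0.1
    weight_lognorm_mu: float = -1.0
    weight_lognorm_sigma: float = 0.5
    rich_weight_multiplier: float = 3.0
    subject_noise_sigma: float = 0.15
    edge_dropout: float = 0.05
    effect_node: int | None = None  # None -> middle of the non-hub range
    effect_group: str = "APD"
    effect_attenuation: float = 0.5
    # optional edge-level effect: these (roi_id, roi_id) pairs are attenuated
    # in effect_group subjects (for planting NBS-style components)
    effect_edges: tuple = ()
    effect_edge_attenuation: float = 1.0
    behavior_target_r: float = 0.62
    behavior_group: str = "HC"
    reporter_node: int | None = None  # None -> effect_node
    n_behavior_missing: tuple = (2, 1)  # (APD, HC) subjects without scores
    age_range: tuple = (8.0, 13.0)
    age_shift_hc: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.hub_fraction < 1):
            raise ValueError("hub_fraction must be in (0, 1)")
        probs = (self.p_rich, self.p_feeder, self.p_local)
        if not all(0 <= p <= 1 for p in probs):
            raise ValueError("edge probabilities must be in [0, 1]")
        if not (self.p_rich >= self.p_feeder >= self.p_local):
            raise ValueError("need p_rich >= p_feeder >= p_local for a planted rich club")
        if self.rich_weight_multiplier < 1:
            raise ValueError("rich_weight_multiplier must be >= 1")
        if not (0 <= self.edge_dropout < 1):
            raise ValueError("edge_dropout must be in [0, 1)")
        if not (0 < self.effect_attenuation <= 1):
            raise ValueError("effect_attenuation must be in (0, 1]")
        if not (-1 < self.behavior_target_r < 1):
            raise ValueError("behavior_target_r must be in (-1, 1)")
        if self.subject_noise_sigma < 0:
            raise ValueError("subject_noise_sigma must be >= 0")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("both groups need at least one subject")

    @property
    def n_hubs(self) -> int:
        return int(np.floor(self.hub_fraction * self.n_nodes + 0.5))

    def resolved_effect_node(self) -> int:
        if self.effect_node is not None:
            return self.effect_node
        h = self.n_hubs
        return h + int(np.floor((self.n_nodes - h) / 2 + 0.5))

    def resolved_reporter_node(self) -> int:
        return self.reporter_node if self.reporter_node is not None else self.resolved_effect_node()

    @classmethod
    def study_scale(cls, **overrides) -> "SimulationConfig":
        """Full atlas-sized configuration (246 regions)."""
        return cls(**{"n_nodes": 246, **overrides})

    def replace(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    planted_hub_ids: set
    effect_node: int
    effect_group: str
    behavior_group: str
    reporter_node: int
    template: Connectome = field(repr=False, default=None)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_hub_ids": sorted(int(i) for i in self.planted_hub_ids),
                "effect_node": int(self.effect_node),
                "effect_group": self.effect_group,
                "behavior_group": self.behavior_group,
                "reporter_node": int(self.reporter_node),
            },
            indent=2,
        )


def _rng_for(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    """Named substream so stages stay reproducible independently."""
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), *key]))


def make_group_template(cfg: SimulationConfig, rng=None) -> tuple[Connectome, GroundTruth]:
    """Draw the three-block Bernoulli topology with lognormal weights.

    Hub-hub pairs connect with ``p_rich``, hub-nonhub with ``p_feeder``,
    nonhub-nonhub with ``p_local``; hub-hub weights are multiplied by
    ``rich_weight_multiplier``.  If the draw is disconnected, a minimal
    chain of extra edges joins the components (logged).
    """
    n = cfg.n_nodes
    h = cfg.n_hubs
    exp_deg_hub = (h - 1) * cfg.p_rich + (n - h) * cfg.p_feeder
    exp_deg_non = h * cfg.p_feeder + (n - h - 1) * cfg.p_local
    if min(exp_deg_hub, exp_deg_non) < 1:
        raise ValueError(
            "expected degree below 1 (disconnected regime); "
            f"hub {exp_deg_hub:.2f}, non-hub {exp_deg_non:.2f}"
        )
    rng = _rng_for(cfg, 0) if rng is None else rng
    node_ids = np.arange(1, n + 1)
    is_hub = np.zeros(n, bool)
    is_hub[:h] = True  # planted hubs occupy the first hub_fraction of ids

    p = np.where(
        is_hub[:, None] & is_hub[None, :],
        cfg.p_rich,
        np.where(is_hub[:, None] | is_hub[None, :], cfg.p_feeder, cfg.p_local),
    )
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < p[iu]
    weights = np.exp(rng.normal(cfg.weight_lognorm_mu, cfg.weight_lognorm_sigma, len(iu[0])))
    weights[is_hub[iu[0]] & is_hub[iu[1]]] *= cfg.rich_weight_multiplier
    w = np.zeros((n, n))
    w[iu[0][present], iu[1][present]] = weights[present]
    w += w.T

    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        logger.warning("template disconnected (%d components); adding spanning chain", n_comp)
        reps = [np.nonzero(labels == c)[0][0] for c in range(n_comp)]
        for a, b in zip(reps[:-1], reps[1:]):
            wt = float(np.exp(rng.normal(cfg.weight_lognorm_mu, cfg.weight_lognorm_sigma)))
            w[a, b] = w[b, a] = wt
    template = Connectome(weights=w, node_ids=node_ids)
    truth = GroundTruth(
        planted_hub_ids=set(node_ids[is_hub].tolist()),
        effect_node=cfg.resolved_effect_node(),
        effect_group=cfg.effect_group,
        behavior_group=cfg.behavior_group,
        reporter_node=cfg.resolved_reporter_node(),
        template=template,
    )
    return template, truth


def sample_subject(
    template: Connectome, cfg: SimulationConfig, group: str, rng: np.random.Generator
) -> Connectome:
    """One subject's matrix: dropout, multiplicative noise, group effect."""
    n = template.n_nodes
    iu = np.triu_indices(n, k=1)
    w = template.weights[iu].copy()
    exist = w > 0
    if cfg.edge_dropout > 0:
        w[exist & (rng.random(len(w)) < cfg.edge_dropout)] = 0.0
    if cfg.subject_noise_sigma > 0:
        w[w > 0] *= np.exp(rng.normal(0.0, cfg.subject_noise_sigma, int((w > 0).sum())))
    if group == cfg.effect_group and cfg.effect_attenuation < 1:
        pos = template.index_of(cfg.resolved_effect_node())
        incident = (iu[0] == pos) | (iu[1] == pos)
        w[incident] *= cfg.effect_attenuation
    if group == cfg.effect_group and cfg.effect_edges and cfg.effect_edge_attenuation < 1:
        pos_pairs = {
            tuple(sorted((template.index_of(a), template.index_of(b))))
            for a, b in cfg.effect_edges
        }
        sel = np.array([(i, j) in pos_pairs for i, j in zip(iu[0], iu[1])])
        w[sel] *= cfg.effect_edge_attenuation
    out = np.zeros((n, n))
    out[iu] = w
    out += out.T
    return Connectome(weights=out, node_ids=template.node_ids)


def sample_behavior(
    apl_reporter: np.ndarray,
    groups: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Behavior score with target correlation against reporter-node APL.

    For ``behavior_group`` subjects, score = rho*z(APL) + sqrt(1-rho^2)*eps;
    the other group gets pure standard normal noise.  A subject whose
    reporter-node APL is undefined (the node lost all its edges to dropout)
    contributes z = 0, which slightly dilutes the realized correlation;
    this is logged.
    """
    apl_reporter = np.asarray(apl_reporter, float)
    scores = rng.normal(size=len(groups))
    sel = groups == cfg.behavior_group
    rho = cfg.behavior_target_r
    x = apl_reporter[sel]
    missing = np.isnan(x)
    if missing.any():
        logger.warning(
            "reporter-node APL undefined for %d subject(s); z set to 0", int(missing.sum())
        )
    ok = x[~missing]
    sd = ok.std() if ok.size else 1.0
    z = np.zeros_like(x)
    z[~missing] = (ok - ok.mean()) / (sd if sd > 0 else 1.0)
    scores[sel] = rho * z + np.sqrt(1.0 - rho**2) * scores[sel]
    return scores


def pick_connected_edges(template: Connectome, n_edges: int, rng) -> tuple:
    """A connected set of existing edges (roi_id pairs), grown by BFS.

    Useful for planting localized edge effects whose supra-threshold trace
    should form a single connected component.
    """
    w = template.weights
    n = template.n_nodes
    start = int(rng.integers(n))
    chosen = []
    visited = {start}
    frontier = [start]
    while frontier and len(chosen) < n_edges:
        node = frontier.pop(0)
        nbrs = np.nonzero(w[node] > 0)[0]
        rng.shuffle(nbrs)
        for nb in nbrs:
            if len(chosen) >= n_edges:
                break
            pair = (int(template.node_ids[min(node, nb)]), int(template.node_ids[max(node, nb)]))
            if pair not in chosen:
                chosen.append(pair)
                if nb not in visited:
                    visited.add(int(nb))
                    frontier.append(int(nb))
    if len(chosen) < n_edges:
        raise ValueError(f"could not grow {n_edges} connected edges from node {start}")
    return tuple(chosen)


def _stub_parcellation(n_nodes: int) -> pd.DataFrame:
    rids = np.arange(1, n_nodes + 1)
    return pd.DataFrame(
        {
            "roi_id": rids,
            "label": [f"R{r:03d}" for r in rids],
            "name": [f"Synthetic region {r}" for r in rids],
            # deterministic fake MNI-style coordinates on a coarse lattice
            "x": (rids * 17) % 141 - 70,
            "y": (rids * 29) % 211 - 105,
            "z": (rids * 11) % 151 - 70,
        }
    )


def generate_cohort(cfg: SimulationConfig, out_dir=None) -> tuple[Cohort, GroundTruth]:
    """Full cohort: matrices, manifest with ages and behaviors, ground truth.

    Fully reproducible from ``cfg.seed``; each subject has its own RNG
    substream keyed by index, so the draw order never depends on how the
    cohort is consumed.  If ``out_dir`` is given, matrices, manifest,
    parcellation stub and ``truth.json`` are written there.
    """
    from .metrics import nodal_apl  # local import to avoid a cycle

    template, truth = make_group_template(cfg)
    groups = np.array(["APD"] * cfg.n_per_group[0] + ["HC"] * cfg.n_per_group[1])
    sids = [
        f"{g}{i + 1:02d}"
        for g, n in zip(("APD", "HC"), cfg.n_per_group)
        for i in range(n)
    ]
    age_rng = _rng_for(cfg, 1)
    lo, hi = cfg.age_range
    ages = age_rng.uniform(lo, hi, len(sids))
    ages[groups == "HC"] += cfg.age_shift_hc

    conns = {}
    apl_reporter = np.empty(len(sids))
    rep_pos = template.index_of(cfg.resolved_reporter_node())
    for i, (sid, g) in enumerate(zip(sids, groups)):
        conn = sample_subject(template, cfg, g, _rng_for(cfg, 10, i))
        conns[sid] = conn
        apl_reporter[i] = nodal_apl(conn)[rep_pos]

    behavior_rng = _rng_for(cfg, 2)
    spatial = sample_behavior(apl_reporter, groups, cfg, behavior_rng)
    others = {
        c: behavior_rng.normal(size=len(sids))
        for c in BEHAVIOR_COLUMNS
        if c != "spatial_advantage"
    }
    manifest = pd.DataFrame({"subject_id": sids, "group": groups, "age": ages})
    manifest["spatial_advantage"] = spatial
    for c in BEHAVIOR_COLUMNS:
        if c != "spatial_advantage":
            manifest[c] = others[c]
    # the last n subjects of each group miss the behavioral battery
    for g, n_missing in zip(("APD", "HC"), cfg.n_behavior_missing):
        if n_missing > 0:
            idx = manifest.index[manifest["group"] == g][-n_missing:]
            manifest.loc[idx, list(BEHAVIOR_COLUMNS)] = np.nan
    manifest = manifest[["subject_id", "group", "age", *BEHAVIOR_COLUMNS]]

    cohort = Cohort(manifest=manifest, connectomes=conns)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out_dir)
        write_parcellation(_stub_parcellation(cfg.n_nodes), out_dir / "parcellation.tsv")
        (out_dir / "truth.json").write_text(truth.to_json() + "\n")
        (out_dir / "config.json").write_text(
            json.dumps(asdict(cfg), indent=2, default=list) + "\n"
        )
    return cohort, truth
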