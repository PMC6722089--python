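"""File formats, run configuration and the end-to-end pipeline runner.

All tabular artefacts are comma-separated UTF-8 with mandatory headers;
graphs are written both as GraphML and as an edge-list CSV.  A pipeline
run echoes its fully-resolved configuration and a log into the output
directory so any result can be reproduced from the artefacts alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .characterise import (LOW_GRADE, bayes_factor, cluster_profiles,
                           enrichment_pvalue)
from .pipeline import TemporalEngagementClusterer
from .series import EventSeries
from .simulate import ARCHETYPES, make_curriculum, sample_grades, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "read_events",
    "write_events",
    "ClickSeries",
    "clicks_to_trajectory",
    "read_clicks",
    "write_matrix",
    "read_matrix",
    "RunConfig",
    "run_pipeline",
]

EVENT_COLUMNS = ["learner_id", "task_index", "completion_time_days"]


def read_events(path, n_total_tasks: int | None = None) -> list[EventSeries]:
    """Read a long-format event CSV into per-learner series.

    Validates the header, rejects duplicate (learner, task) rows and
    negative times with the offending CSV line numbers, and orders each
    learner's times by task index.  ``n_total_tasks`` defaults to the
    largest task index seen plus one.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["learner_id", "task_index"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate (learner_id, task_index) rows "
                         f"at lines {lines[:10]}")
    neg = df["completion_time_days"] < 0
    if neg.any():
        lines = (df.index[neg] + 2).tolist()
        raise ValueError(f"{path}: negative completion times at lines {lines[:10]}")
    if n_total_tasks is None:
        n_total_tasks = int(df["task_index"].max()) + 1 if len(df) else 0
    out = []
    for lid, g in df.groupby("learner_id", sort=True):
        g = g.sort_values("task_index")
        out.append(EventSeries(str(lid),
                               g["completion_time_days"].to_numpy(float),
                               n_total_tasks))
    return out


def write_events(series: list[EventSeries], path) -> None:
    rows = []
    for s in series:
        # task indices are not retained inside EventSeries; write the
        # rank order, which round-trips the times exactly
        for i, t in enumerate(s.times):
            rows.append((s.learner_id, i, t))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class ClickSeries:
    """Per-day interaction counts for one learner (page-click data)."""

    learner_id: str
    days: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, float)
        counts = np.asarray(self.counts)
        if days.size != counts.size:
            raise ValueError("days and counts must have equal length")
        if np.any(counts < 0) or not np.allclose(counts, counts.astype(int)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "counts", counts.astype(int))


def clicks_to_trajectory(clicks: ClickSeries) -> EventSeries:
    """Expand day-level click counts into a pseudo-event time vector.

    Each click becomes one event at its (coarse-grained) day, so the
    identical DTW pipeline applies to interaction-count data where time
    stamps record page visits rather than task completions.  An
    all-zero series yields an empty trajectory (flagged by a warning).
    """
    times = np.repeat(clicks.days, clicks.counts)
    if times.size == 0:
        logger.warning("learner %s has zero clicks", clicks.learner_id)
    return EventSeries(clicks.learner_id, times, int(times.size))


def read_clicks(path) -> list[ClickSeries]:
    """Read a (learner_id, day, count) CSV of interaction counts."""
    df = pd.read_csv(path)
    for c in ("learner_id", "day", "count"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    out = []
    for lid, g in df.groupby("learner_id", sort=True):
        g = g.sort_values("day")
        out.append(ClickSeries(str(lid), g["day"].to_numpy(float),
                               g["count"].to_numpy()))
    return out


def write_matrix(m: np.ndarray, ids, path) -> None:
    pd.DataFrame(np.asarray(m), index=list(ids), columns=list(ids)).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]


# ---------------------------------------------------------------------------
# run configuration and the end-to-end pipeline


@dataclass
class RunConfig:
    """Fully-defaulted configuration of one pipeline run."""

    out_dir: str = "tempoclust_run"
    events_path: str | None = None  # None: simulate a cohort
    # simulation
    n_tasks: int = 376
    n_terms: int = 3
    term_length_days: float = 70.0
    archetypes: dict = field(default_factory=lambda: {
        "early_bird": 20, "on_time": 20, "low_engager": 20, "crammer": 20})
    # kernel
    sigma: float | None = None
    sigma_rule: str = "median_distance"
    # graph
    gamma: float = 0.5
    k: int = 1
    pi_mode: str = "uniform"
    # scan
    t_min: float = 1e-2
    t_max: float = 1e2
    n_t: int = 100
    n_restarts: int = 100
    theta_plateau: float = 0.1
    l_min: int = 5
    # characterisation
    session_tol_days: float = 0.0
    gpr_restarts: int = 2
    low_grade: float = LOW_GRADE
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate (optional) -> similarity -> graph -> scan -> select
    -> characterise, writing every artefact into ``config.out_dir``.

    A fixed seed makes the whole output directory reproducible.
    Returns the output directory path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("tempoclust")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    stage = "setup"
    try:
        stage = "simulate"
        truth = None
        grades = None
        if config.events_path is None:
            curriculum = make_curriculum(config.n_tasks, config.n_terms,
                                         config.term_length_days)
            specs = [(ARCHETYPES[name], count)
                     for name, count in config.archetypes.items()]
            cohort = simulate_cohort(curriculum, specs, seed=config.seed)
            cohort.write_csv(out / "events.csv", out / "labels.csv")
            truth = cohort.labels
            grades = sample_grades(truth, seed=config.seed + 1)
            series = [s for s in cohort.to_event_series(config.n_tasks)
                      if len(s) > 0]
        else:
            series = [s for s in read_events(config.events_path) if len(s) > 0]
        logger.info("cohort: %d learners", len(series))

        stage = "cluster"
        model = TemporalEngagementClusterer(
            sigma=config.sigma, sigma_rule=config.sigma_rule,
            gamma=config.gamma, k=config.k, t_min=config.t_min,
            t_max=config.t_max, n_t=config.n_t, n_restarts=config.n_restarts,
            theta_plateau=config.theta_plateau, l_min=config.l_min,
            pi_mode=config.pi_mode, random_state=config.seed)
        model.fit(series)
        ids = model.learner_ids_
        logger.info("sigma=%.6g gamma=%.3g k=%d pi=%s ell=%d t=[%g, %g] seed=%d",
                    model.kernel_.sigma_, config.gamma, config.k,
                    config.pi_mode, config.n_restarts, config.t_min,
                    config.t_max, config.seed)

        stage = "write-matrices"
        write_matrix(model.kernel_.distances_, ids, out / "distances.csv")
        write_matrix(model.kernel_.similarity_, ids, out / "similarity.csv")
        g = model.grapher_.graph_
        nxg = g.to_networkx()
        nx.write_graphml(nxg, out / "graph.graphml")
        pd.DataFrame(
            [(ids[i], ids[j], d["weight"]) for i, j, d in nxg.edges(data=True)],
            columns=["source", "target", "weight"],
        ).to_csv(out / "edges.csv", index=False)

        stage = "write-scan"
        scan = model.scan_
        parts = []
        for it, t in enumerate(scan.t_grid):
            for lid, com in zip(ids, scan.best_labels[it]):
                parts.append((lid, t, int(com)))
        pd.DataFrame(parts, columns=["learner_id", "t", "community"]
                     ).to_csv(out / "partitions.csv", index=False)
        pd.DataFrame({"t": scan.t_grid, "vi": scan.vi_t,
                      "stability": scan.stability,
                      "n_communities": scan.n_communities}
                     ).to_csv(out / "vi_t.csv", index=False)
        write_matrix(scan.vi_cross, [f"{t:.6g}" for t in scan.t_grid],
                     out / "vi_cross.csv")

        stage = "select"
        report = model.report_
        robust = {
            "theta_plateau": report.theta_plateau,
            "l_min": report.l_min,
            "containment": report.containment,
            "candidates": [
                {
                    "t_window": list(c.t_window),
                    "t_selected": c.t_selected,
                    "n_communities": c.n_communities,
                    "plateau_length": c.plateau_length,
                    "vi_dip_depth": c.vi_dip_depth,
                    "labels": {lid: int(l) for lid, l in zip(ids, c.labels)},
                }
                for c in report.candidates
            ],
        }
        (out / "robust_report.json").write_text(
            json.dumps(robust, indent=2), encoding="utf-8")

        stage = "characterise"
        labels = model.labels_
        profiles = cluster_profiles(series, labels,
                                    tol_days=config.session_tol_days,
                                    n_restarts=config.gpr_restarts,
                                    random_state=config.seed)
        clusters = [[s for s, l in zip(series, labels) if l == c and len(s)]
                    for c in np.unique(labels)]
        clusters = [c for c in clusters if c]
        flat = [s for c in clusters for s in c]
        bf = (bayes_factor(clusters, flat, n_restarts=config.gpr_restarts,
                           random_state=config.seed)
              if len(clusters) > 1 else None)
        enrich = []
        if truth is not None and grades is not None:
            low = {lid for lid, gr in grades.items() if gr < config.low_grade}
            by_id = model.labels_by_id()
            pop = len(by_id)
            pop_hits = sum(1 for lid in by_id if lid in low)
            for c in np.unique(labels):
                members = [lid for lid, l in by_id.items() if l == c]
                hits = sum(1 for lid in members if lid in low)
                p = enrichment_pvalue(len(members), hits, pop, pop_hits)
                enrich.append({"cluster": int(c), "size": len(members),
                               "low_performers": hits, "p_raw": p,
                               "p_bonferroni": min(1.0, p * len(np.unique(labels)))})
        cluster_report = {
            "n_clusters": int(len(np.unique(labels))),
            "t_selected": model.clusterer_.t_selected_,
            "profiles": [
                {"cluster": p.cluster,
                 "size": len(p.member_ids),
                 "mean_massed_session_length": p.mean_massed_session_length,
                 "completion_fraction": p.completion_fraction,
                 "log_marginal_likelihood": p.log_marginal_likelihood}
                for p in profiles
            ],
            "bayes": ({"log_K": bf.log_K, "K": bf.K} if bf else None),
            "enrichment": enrich,
        }
        (out / "cluster_report.json").write_text(
            json.dumps(cluster_report, indent=2), encoding="utf-8")

        resolved = dataclasses.asdict(config)
        (out / "config_resolved.json").write_text(
            json.dumps(resolved, indent=2), encoding="utf-8")
        logger.info("pipeline complete: %s", out)
        return out
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
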