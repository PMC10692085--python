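"""End-to-end orchestration: simulate -> preprocess -> embed -> cluster
-> validate -> train, with a single JSON run report.

Every stage seed is derived deterministically from one global seed, so a
fixed configuration reproduces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, embedding, models, stats, synthgen, trajio

log = logging.getLogger("strangertest")


@dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``input_dir`` (a directory of detection JSONs plus
    ratings.csv / cbarq.csv) or ``cohort`` (a synthetic cohort config)
    must be provided.
    """

    cohort: synthgen.CohortConfig | None = None
    input_dir: str | None = None
    out_dir: str | None = None
    min_coverage: float = 0.80
    post_fill_coverage: float = 0.95
    target_fps: float = 24.0
    smooth_window: int = 5
    embedding_grid: tuple = embedding.DEFAULT_GRID
    epochs: int = 200
    k_max: int = 8
    budget: int = 200
    include_negative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must lie in (0, 1]")
        if not 0 < self.post_fill_coverage <= 1:
            raise ValueError("post_fill_coverage must lie in (0, 1]")
        if self.cohort is None and self.input_dir is None:
            raise ValueError("provide either a cohort config or an input directory")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31))


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report (JSON-able)."""
    report: dict = {"config": _config_echo(config), "exclusions": {}}

    # --- acquire detections + tables -------------------------------------
    if config.cohort is not None:
        cohort_cfg = dataclasses.replace(config.cohort,
                                         seed=config.stage_seed("simulate"))
        cohort = synthgen.generate_cohort(cohort_cfg)
        trials, ratings, cbarq = cohort.trials, cohort.ratings, cohort.cbarq
    else:
        import pandas as pd

        in_dir = Path(config.input_dir)
        trials = [trajio.read_detections(p) for p in sorted(in_dir.glob("trial*.json"))]
        ratings = pd.read_csv(in_dir / "ratings.csv")
        cbarq = pd.read_csv(in_dir / "cbarq.csv")
    report["n_raw"] = len(trials)

    # --- preprocess ------------------------------------------------------
    retained, gate = trajio.quality_filter(trials, config.min_coverage)
    excluded = gate.loc[~gate["retained"], "trial_id"].tolist()
    report["exclusions"]["quality_gate"] = excluded
    for t in excluded:
        log.info("quality gate excluded %s", t)
    processed = [trajio.resample(trajio.fill_gaps(t, config.smooth_window),
                                 config.target_fps) for t in retained]
    post_cov = min(trajio.detection_coverage(t) for t in processed)
    if post_cov < config.post_fill_coverage:
        raise RuntimeError(f"post-fill coverage {post_cov:.3f} below "
                           f"{config.post_fill_coverage}")
    report["post_fill_coverage"] = post_cov

    # --- expert scores ---------------------------------------------------
    maj = stats.majority_labels(ratings)
    report["agreement"] = dataclasses.asdict(stats.agreement_report(
        maj[["rater1", "rater2", "rater3"]].to_numpy()))
    ties = maj.loc[maj["label"].isna(), "trial_id"].tolist()
    report["exclusions"]["vote_ties"] = ties
    labels = dict(zip(maj["trial_id"], maj["label"]))
    if not config.include_negative:
        negatives = [t for t, v in labels.items() if v == "-"]
        report["exclusions"]["negative_score"] = negatives
        drop = set(negatives) | set(ties)
    else:
        drop = set(ties)
    processed = [t for t in processed if t.trial_id not in drop]

    dataset = trajio.build_dataset(processed)
    report["n_retained"] = dataset.n
    report["m_time"] = dataset.m_time

    # --- embed -----------------------------------------------------------
    model, _ = embedding.train_autoencoder(
        dataset, grid=config.embedding_grid, seed=config.stage_seed("embed"),
        epochs=config.epochs)
    emb = embedding.encode(model, dataset)

    # --- cluster ---------------------------------------------------------
    result = clustering.cluster_embeddings(
        emb.vectors, emb.trial_ids, k_max=config.k_max,
        seed=config.stage_seed("cluster"))
    report["exclusions"]["outliers"] = result.excluded_outliers
    report["k_selected"] = result.k_selected
    report["n_clustered"] = len(result.assignments)
    report["inertia_curve"] = {str(k): v for k, v in result.inertia_curve.items()}

    kept_labels = {t: labels[t] for t in result.assignments}
    table = clustering.crosstab(result.assignments, kept_labels)
    report["crosstab"] = {str(c): {str(i): int(v) for i, v in table[c].items()}
                          for c in table.columns}

    # --- validate against C-BARQ ----------------------------------------
    if result.k_selected == 2:
        assignments = result.assignments
    else:
        # pairwise design: compare the k=2 partition regardless of k*
        lab2, _, _ = clustering.kmeans_fit(
            emb.vectors[[emb.trial_ids.index(t) for t in result.assignments]],
            2, seed=config.stage_seed("cluster"))
        assignments = dict(zip(result.assignments, (int(c) for c in lab2)))
    cmp_table = stats.compare_clusters_cbarq(cbarq, assignments)
    report["cbarq_comparison"] = cmp_table.to_dict("records")

    # --- supervised models ----------------------------------------------
    idx = [emb.trial_ids.index(t) for t in sorted(assignments)]
    X = emb.vectors[idx]
    y = np.array([labels[t] for t in sorted(assignments)])
    _, clf_report = models.pipeline_search(
        X, y, models.SearchConfig(task="classification", budget=config.budget,
                                  seed=config.stage_seed("train")))
    report["classifier"] = {"cv_accuracy": clf_report.cv_score,
                            **clf_report.metrics,
                            "pipeline": clf_report.pipeline_description["estimator"]}
    cb = cbarq.set_index("trial_id").loc[sorted(assignments)].reset_index()
    reg_table = models.regress_cbarq(
        X, cb, models.SearchConfig(task="regression", budget=config.budget,
                                   seed=config.stage_seed("train")))
    report["regression"] = reg_table.to_dict("records")

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, stable floats)."""
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    return json.dumps(report, sort_keys=True, indent=2, default=default,
                      allow_nan=True)


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["embedding_grid"] = [dict(g) for g in config.embedding_grid]
    return d
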