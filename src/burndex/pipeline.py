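"""End-to-end orchestration: preprocess -> cluster -> patterns -> index.

A single :class:`PipelineConfig` drives the whole indicator-identification
workflow from one of three input sources: a per-rat cohort CSV, a synthetic
cohort simulated from a group-summary table, or the summary table alone
(median mode -- profiles come straight from the printed group medians and
the per-rat selection stages are skipped).  One master seed determines
every stage seed through stable hashing of the stage name, so runs are
reproducible bit-for-bit and stages cannot silently share randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocess as pp
from .cohort_data import (
    CohortError,
    CohortTable,
    GroupSummaryTable,
    load_summary_fixture,
    packaged_summary,
    read_cohort,
    write_cohort,
)
from .dose_clustering import ClusterConfig, choose_k, kmeans_profiles, scan_k
from .pattern_analysis import centroid_matrix, cross_vessel_membership, membership_census, svd_patterns
from .severity_index import GAParams, RegressorSpec, SelectionResult, select_variables, train_index
from .synthetic_cohort import SimulationSpec, gen_cohort

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """A stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one full run; exactly one input source is set."""

    cohort_path: str | None = None
    summary_path: str | None = None  # None -> packaged summary fixture
    mode: str = "medians"  # "cohort" | "simulate" | "medians"
    seed: int = 0
    out_dir: str | None = None

    # preprocessing
    max_missing_frac: float = pp.MAX_MISSING_FRACTION
    profile_statistic: str = "mean"

    # simulation (only used in simulate mode)
    missing_rate: float = 0.05
    outlier_rate: float = 0.02

    # clustering
    k_min: int = 2
    k_max: int = 8
    replicates: int = 10
    silhouette_gain_threshold: float = 0.05

    # pattern counting
    svd_tol: float = 1e-2
    residual_energy_tol: float = 0.02

    # selection
    models: tuple[str, ...] = ("linear", "mlp")
    budget: str | int = "auto"
    ga: GAParams = field(default_factory=GAParams)

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "simulate", "medians"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cohort" and not self.cohort_path:
            raise ValueError("cohort mode requires cohort_path")
        if self.mode != "cohort" and self.cohort_path:
            raise ValueError("cohort_path is only valid in cohort mode")


def _summary(cfg: PipelineConfig) -> GroupSummaryTable:
    if cfg.summary_path:
        return load_summary_fixture(cfg.summary_path)
    return packaged_summary()


def _round_floats(obj):
    """Canonicalize floats for a byte-stable manifest."""
    if isinstance(obj, float):
        return round(obj, 12)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.floating):
        return round(float(obj), 12)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and optionally writes) a manifest.

    Stage order: mask -> filter -> impute -> profiles -> k scan/selection ->
    clustering -> pattern counting (sets the variable budget) -> per-model
    wrapper selection -> final index training.  Any stage error aborts with
    the stage name attached; the manifest carries every stage seed and the
    headline results so a run can be replayed exactly.
    """
    manifest: dict = {
        "config": _round_floats(
            {k: v for k, v in asdict(cfg).items() if k != "ga"} | {"ga": asdict(cfg.ga)}
        ),
        "stage_seeds": {},
        "stages": [],
        "results": {},
    }
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        manifest["stages"].append(name)
        s = stage_seed(cfg.seed, name)
        manifest["stage_seeds"][name] = s
        return s

    try:
        # ---- input ---------------------------------------------------
        table: CohortTable | None = None
        if cfg.mode == "cohort":
            stage("load_cohort")
            table = read_cohort(cfg.cohort_path)
        elif cfg.mode == "simulate":
            sim_seed = stage("simulate")
            summary = _summary(cfg)
            table = gen_cohort(
                SimulationSpec(
                    summary,
                    missing_rate=cfg.missing_rate,
                    outlier_rate=cfg.outlier_rate,
                    seed=sim_seed,
                )
            )
        else:
            stage("load_summary")
            summary = _summary(cfg)

        # ---- preprocessing -> profiles -------------------------------
        if table is not None:
            stage("preprocess")
            table, rep_mask = pp.mask_outliers(table)
            table, rep_filter = pp.filter_rats(table, cfg.max_missing_frac)
            table, rep_impute = pp.impute_group_median(table)
            report = rep_mask.merge(rep_filter).merge(rep_impute)
            manifest["results"]["preprocess"] = report.to_dict()
            profiles = pp.group_profiles(table, cfg.profile_statistic)
            if out_dir:
                write_cohort(table, out_dir / "clean_cohort.csv")
        else:
            stage("profiles_from_summary")
            profiles = pp.profiles_from_summary(summary)

        # ---- clustering ----------------------------------------------
        cluster_seed = stage("cluster")
        ccfg = ClusterConfig(
            k_min=cfg.k_min,
            k_max=cfg.k_max,
            replicates=cfg.replicates,
            seed=cluster_seed,
            silhouette_gain_threshold=cfg.silhouette_gain_threshold,
        )
        scan = scan_k(profiles, ccfg)
        k_star = choose_k(scan, cfg.silhouette_gain_threshold)
        best = scan.results[k_star]
        manifest["results"]["k_scan"] = _round_floats(
            {
                "within_ss": scan.within_ss,
                "mean_silhouette": scan.mean_silhouette,
            }
        )
        manifest["results"]["k_star"] = k_star
        manifest["results"]["mean_silhouette"] = _round_floats(best.mean_silhouette)

        # ---- independent patterns ------------------------------------
        stage("patterns")
        cm = centroid_matrix(profiles, best.assignment)
        pat = svd_patterns(cm, cfg.svd_tol, cfg.residual_energy_tol)
        crossings = cross_vessel_membership(best.assignment)
        manifest["results"]["patterns"] = _round_floats(
            {
                "singular_values": pat.singular_values.tolist(),
                "n_independent": pat.n_independent,
                "explained_fraction_top_n": pat.explained_fraction_by(pat.n_independent),
                "cross_vessel": [list(c) for c in crossings],
            }
        )
        budget = pat.n_independent if cfg.budget == "auto" else int(cfg.budget)
        manifest["results"]["budget"] = budget
        if out_dir:
            census = membership_census(best.assignment)
            census.to_csv(out_dir / "membership_census.csv")

        # ---- selection and index (needs per-rat data) ----------------
        if table is not None:
            sel_seed = stage("select")
            selections: dict[str, SelectionResult] = {}
            for kind in cfg.models:
                spec = RegressorSpec(kind, seed=sel_seed)
                selections[kind] = select_variables(
                    spec, table, budget, cfg.ga, seed=sel_seed
                )
            ranked = sorted(selections.values(), key=lambda r: r.cv.accuracy_mean)
            manifest["results"]["selection"] = _round_floats(
                {
                    r.model.kind: {
                        "variables": [v.column for v in r.variables],
                        "cv": r.cv.to_dict(),
                    }
                    for r in ranked
                }
            )
            stage("train_index")
            winner = ranked[-1]
            index = train_index(winner.model, table, winner.variables)
            manifest["results"]["index"] = _round_floats(
                {
                    "model": winner.model.kind,
                    "variables": [v.column for v in winner.variables],
                    "training_rae": index.training_rae,
                    "cv_accuracy_mean": winner.cv.accuracy_mean,
                }
            )
    except Exception as err:
        manifest["error"] = {"stage": manifest["stages"][-1] if manifest["stages"] else None,
                             "message": str(err)}
        if out_dir:
            (out_dir / "manifest.json").write_text(
                json.dumps(_round_floats(manifest), indent=2, sort_keys=True)
            )
        raise

    if out_dir:
        (out_dir / "manifest.json").write_text(
            json.dumps(_round_floats(manifest), indent=2, sort_keys=True)
        )
    return manifest
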