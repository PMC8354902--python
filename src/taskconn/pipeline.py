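"""End-to-end orchestration: simulate -> connectivity -> features -> classify.

Stage seeds are derived deterministically from the master seed so each
stage is independently reproducible, and a hash of the full configuration
is stamped into every report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    CVConfig,
    CVResult,
    module_group_test,
    nested_cv_classify,
    permutation_test,
    rank_weights,
    select_groups,
    site_correct,
    subsampling_curve,
)
from .cohort import Cohort, CohortConfig, simulate_cohort, write_cohort
from .measures import FeatureTable, build_feature_models, task_activation_subject
from .phasic import estimate_phasic_subject
from .tonic import DEFAULT_LAMBDA_GRID, estimate_tonic_subject

log = logging.getLogger("taskconn")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold: float = 0.05
    lambda_grid: tuple[float, ...] = tuple(DEFAULT_LAMBDA_GRID)
    cv: CVConfig = field(default_factory=CVConfig)
    group_pairs: tuple[tuple[str, str], ...] = (
        ("BPD", "NPC"), ("NPC", "CLC"), ("BPD", "CLC"))
    run_permutation: bool = False
    subsample_sizes: tuple[int, ...] = ()
    out_dir: str = "taskconn_out"
    master_seed: int = 0


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def extract_features(
    cohort: Cohort,
    threshold: float | None = 0.05,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    correct_sites: bool = True,
) -> dict[str, FeatureTable]:
    """Run phasic, tonic and activation estimation for every subject and
    assemble (optionally site-corrected) feature tables."""
    labels = tuple(cohort.node_labels)
    phasic, tonic, activation = {}, {}, {}
    for sub in cohort.subjects:
        sid = sub.subject_id
        ts = cohort.timeseries.get(sid)
        dms = cohort.design_matrices[sid]
        try:
            phasic[sid] = estimate_phasic_subject(ts, dms, labels, threshold)
            tonic[sid] = estimate_tonic_subject(ts, dms, labels,
                                                np.asarray(lambda_grid))
            activation[sid] = task_activation_subject(ts, dms)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for subject {sid}: {exc}") from exc
    groups = pd.Series({s.subject_id: s.group for s in cohort.subjects})
    sites = pd.Series({s.subject_id: s.site for s in cohort.subjects})
    tables = build_feature_models(phasic, tonic, activation,
                                  cohort.modules, groups, sites)
    if correct_sites:
        tables = {t: site_correct(tab) for t, tab in tables.items()}
    return tables


def _result_report(res: CVResult) -> dict:
    return {
        "mean_balanced_accuracy": res.mean_balanced_accuracy,
        "ci": [res.ci_lower, res.ci_upper],
        "mean_sensitivity": float(res.sensitivities.mean()),
        "mean_specificity": float(res.specificities.mean()),
        "mean_auc": float(res.aucs.mean()),
        "model_selection_proportions": res.model_selection_counts,
        "inner_mean_balanced_accuracy": res.inner_mean_balanced_accuracy,
    }


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True) -> dict:
    """Execute the full pipeline; returns (and optionally writes) a report."""
    t0 = time.time()
    out = Path(config.out_dir)
    handler = None
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "pipeline.log")
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    chash = config_hash(config)
    cohort_cfg = replace(config.cohort,
                         seed=stage_seed(config.master_seed, "simulate"))
    log.info("simulating cohort (%d subjects)",
             sum(cohort_cfg.group_sizes.values()))
    cohort = simulate_cohort(cohort_cfg)
    log.info("extracting features")
    models = extract_features(cohort, config.threshold,
                              np.asarray(config.lambda_grid))
    report: dict = {"config_hash": chash, "comparisons": {}}
    for pair in config.group_pairs:
        log.info("classifying %s vs %s", *pair)
        sub_models, y = select_groups(models, pair)
        cv = replace(config.cv,
                     seed=stage_seed(config.master_seed, f"cv:{pair}"))
        res = nested_cv_classify(sub_models, y, cv)
        entry = _result_report(res)
        best = max(res.model_selection_counts,
                   key=res.model_selection_counts.get)
        entry["best_model"] = best
        entry["top_ranked_features"] = [
            {"node": n, "weight": w, "rank": r}
            for n, w, r in rank_weights(res, best)[:10]]
        strength_tab, _ = select_groups(
            {"tonic_strength": models["tonic_strength"]}, pair)
        entry["module_tests"] = module_group_test(
            strength_tab["tonic_strength"], cohort.modules, pair
        ).to_dict(orient="index")
        if config.run_permutation:
            perm = permutation_test(sub_models, y, cv,
                                    observed=res.mean_balanced_accuracy)
            entry["permutation_p"] = perm.p_value
        if config.subsample_sizes:
            curve = subsampling_curve(sub_models, y,
                                      list(config.subsample_sizes), cv)
            entry["subsampling_curve"] = curve.reset_index().to_dict(
                orient="records")
        report["comparisons"][f"{pair[0]}_vs_{pair[1]}"] = entry
    report["elapsed_s"] = time.time() - t0
    if write_artifacts:
        (out / "report.json").write_text(
            json.dumps(_to_jsonable(report), indent=1))
        write_cohort(out / "cohort", cohort, overwrite=True)
        for tag, tab in models.items():
            tab.write(out / f"features_{tag}.tsv")
        manifest = {"config_hash": chash,
                    "stage_seeds": {s: stage_seed(config.master_seed, s)
                                    for s in ("simulate", "cv")},
                    "artifacts": sorted(p.name for p in out.iterdir())}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if handler is not None:
        log.removeHandler(handler)
        handler.close()
    return report
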