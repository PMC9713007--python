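"""End-to-end orchestration: simulate -> connectome -> metrics -> inference.

Every stage derives its randomness from the single run seed through named
`numpy` SeedSequence substreams, so rerunning with the same configuration
reproduces byte-identical outputs, and changing one stage's substream does
not perturb the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import cross_validate_svm, permutation_test_accuracy
from .config import RunConfig
from .connectome import connectivity_from_timeseries, sparsity_grid, threshold_by_sparsity
from .graph_metrics import assemble_auc_features, compute_metric_curves
from .group_inference import clinical_correlations, default_families, maxstat_perm_glm
from .io import (
    read_timeseries_dir,
    write_cohort,
    write_connectivity,
    write_json,
    write_metric_curves,
)
from .nbs import Design, nbs_test
from .synthetic_cohort import simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed"]

_STAGES = ("simulate", "connectome", "metrics", "nbs", "stats", "classify")


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Named per-stage substream of the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    return np.random.SeedSequence(global_seed, spawn_key=(_STAGES.index(stage),))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _result_to_json(res) -> dict:
    return {
        "direction": res.direction,
        "p_primary": res.p_primary,
        "t_critical": res.t_critical,
        "n_perm": res.n_perm,
        "components": [
            {
                "n_edges": c.n_edges,
                "n_nodes": c.n_nodes,
                "p_perm": c.p_perm,
                "edges": [
                    [res.node_labels[i], res.node_labels[j]] for i, j in c.edges
                ],
            }
            for c in res.components
        ],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, writing all artifacts under ``out_dir``.

    Returns the run manifest (also written to ``manifest.json``); on stage
    failure the partial manifest is persisted before the exception is
    re-raised with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }
    current = "simulate"
    try:
        t0 = time.perf_counter()
        if config.in_dir is None:
            cohort_cfg = dataclasses.replace(
                config.cohort,
                seed=int(stage_seed(config.seed, "simulate").generate_state(1)[0] % 2**31),
            )
            cohort = simulate_cohort(cohort_cfg)
            write_cohort(cohort, out / "cohort")
            subjects = list(cohort.subjects)
            pheno = cohort.phenotypes
        else:
            subjects = read_timeseries_dir(Path(config.in_dir) / "timeseries")
            pheno = pd.read_csv(Path(config.in_dir) / "phenotypes.csv")
        pheno = pheno.set_index("subject_id").loc[[s.subject_id for s in subjects]].reset_index()
        logger.info("simulate stage: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["simulate"] = {"n_subjects": len(subjects)}

        current = "connectome"
        t0 = time.perf_counter()
        conn_dir = out / "connectome"
        matrices = []
        for s in subjects:
            cm = connectivity_from_timeseries(s, config.alpha)
            matrices.append(cm)
            write_connectivity(cm, conn_dir)
        logger.info("connectome stage: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["connectome"] = {"alpha": config.alpha}

        current = "metrics"
        t0 = time.perf_counter()
        grid = sparsity_grid(config.grid_lo, config.grid_hi, config.grid_step)
        metric_seeds = stage_seed(config.seed, "metrics").spawn(len(matrices))
        subject_curves = {}
        for cm, child in zip(matrices, metric_seeds):
            graphs = [threshold_by_sparsity(cm, s) for s in grid]
            subject_curves[cm.subject_id] = compute_metric_curves(
                graphs, grid, cm.subject_id, config.reference, child
            )
        write_metric_curves(subject_curves, out / "metrics" / "curves.tsv")
        features = assemble_auc_features(subject_curves, config.include_e_loc)
        features.to_csv(out / "metrics" / "auc_features.csv", float_format="%.12g")
        logger.info("metrics stage: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["metrics"] = {
            "grid_points": len(grid),
            "n_features": int(features.shape[1]),
        }

        current = "nbs"
        t0 = time.perf_counter()
        group = (pheno["group"] == "patient").to_numpy(int)
        covs = (
            pheno[list(config.nbs_covariates)].to_numpy(float)
            if config.nbs_covariates else None
        )
        design = Design.two_group(group, covs)
        (out / "nbs").mkdir(parents=True, exist_ok=True)
        nbs_out = {}
        nbs_seed = stage_seed(config.seed, "nbs")
        for direction, child in zip(config.nbs_directions, nbs_seed.spawn(len(config.nbs_directions))):
            res = nbs_test(
                matrices, design,
                p_primary=config.nbs_p_primary,
                n_perm=config.nbs_n_perm,
                direction=direction,
                seed=child,
                paper_convention=config.paper_convention,
            )
            nbs_out[direction] = _result_to_json(res)
            for k, comp in enumerate(res.significant):
                rows = pd.DataFrame(
                    [(res.node_labels[i], res.node_labels[j]) for i, j in comp.edges],
                    columns=["node_i", "node_j"],
                )
                rows.to_csv(out / "nbs" / f"{direction}_component{k + 1}.tsv",
                            sep="\t", index=False)
        write_json(nbs_out, out / "nbs" / "nbs_results.json")
        logger.info("nbs stage: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["nbs"] = {"n_perm": config.nbs_n_perm}

        current = "stats"
        t0 = time.perf_counter()
        families = default_families(list(features.columns))
        global_fams = {k: v for k, v in families.items() if ":" not in v[0]}
        local_fams = {k: v for k, v in families.items() if ":" in v[0]}
        stats_seed = stage_seed(config.seed, "stats")
        ss_glob, ss_loc = stats_seed.spawn(2)
        frames = []
        if global_fams:
            cols = [c for fam in global_fams.values() for c in fam]
            frames.append(maxstat_perm_glm(
                features[cols], design, global_fams,
                n_perm=config.stats_n_perm_global, seed=ss_glob,
                paper_convention=config.paper_convention,
            ).to_frame())
        if local_fams:
            cols = [c for fam in local_fams.values() for c in fam]
            frames.append(maxstat_perm_glm(
                features[cols], design, local_fams,
                n_perm=config.stats_n_perm_local, seed=ss_loc,
                paper_convention=config.paper_convention,
            ).to_frame())
        glm_table = pd.concat(frames, ignore_index=True)
        (out / "stats").mkdir(parents=True, exist_ok=True)
        glm_table.to_csv(out / "stats" / "perm_glm.csv", index=False, float_format="%.12g")

        clin_vars = [v for v in config.clinical_vars if v in pheno.columns]
        attrs = [a for a in features.columns if ":" not in a]
        clin = clinical_correlations(
            features.reset_index(drop=True), pheno, attrs, clin_vars,
            list(config.control_covariates),
        )
        clin.to_csv(out / "stats" / "clinical_correlations.csv", index=False,
                    float_format="%.12g")
        logger.info("stats stage: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["stats"] = {"n_tests": int(len(glm_table))}

        current = "classify"
        t0 = time.perf_counter()
        cls_cfg = dataclasses.replace(
            config.classify,
            seed=int(stage_seed(config.seed, "classify").generate_state(1)[0] % 2**31),
            paper_convention=config.paper_convention,
        )
        report = cross_validate_svm(features, pheno["group"].to_numpy(),
                                    cls_cfg, positive_label="patient")
        p_perm = permutation_test_accuracy(features, pheno["group"].to_numpy(),
                                           cls_cfg, positive_label="patient")
        write_json(
            {
                "selected_features": list(report.selected_features),
                "metrics": report.summary(),
                "p_perm": p_perm,
                "config": dataclasses.asdict(cls_cfg),
            },
            out / "classify" / "report.json",
        )
        fold_df = pd.DataFrame([dataclasses.asdict(f) for f in report.folds])
        fold_df.to_csv(out / "classify" / "fold_metrics.csv", index=False,
                       float_format="%.12g")
        logger.info("classify stage: %.2fs", time.perf_counter() - t0)
        manifest["stages"]["classify"] = {
            "accuracy": report.accuracy_mean,
            "p_perm": p_perm,
        }
    except Exception as err:
        manifest["failed_stage"] = current
        manifest["error"] = str(err)
        write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed in stage {current!r}: {err}") from err

    manifest["inputs_hash"] = _hash_file(out / "cohort" / "phenotypes.csv") if config.in_dir is None else _hash_file(Path(config.in_dir) / "phenotypes.csv")
    write_json(manifest, out / "manifest.json")
    return manifest
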