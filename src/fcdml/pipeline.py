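"""End-to-end orchestration: cohort -> preprocess -> FCD -> features -> models.

`run_pipeline` executes the full analysis on a synthetic (or previously
written) cohort, writes all intermediates and a reproducibility report,
and is deterministic given the config's root seed: every stage draws its
randomness from a seed derived from the root by a fixed scheme
(:func:`fcdml.config.stage_seed`).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import fcd as fcdmod
from . import io as fio
from . import models as mod
from . import preprocess as pre
from . import synthetic as syn
from .config import PipelineConfig, stage_seed
from .types import ClusterTable

log = logging.getLogger("fcdml")

__all__ = ["run_pipeline", "roc_points"]


def roc_points(decision_values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) from pooled decision values."""
    d = np.asarray(decision_values, float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-d)
    tp = np.concatenate([[0], np.cumsum(y[order] == 1)])
    fp = np.concatenate([[0], np.cumsum(y[order] == 0)])
    return pd.DataFrame(
        {"fpr": fp / max(fp[-1], 1), "tpr": tp / max(tp[-1], 1)}
    )


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run the full analysis and return the reproducibility report."""
    config.validate()
    outdir = Path(config.output_dir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "stages": {},
        "durations_s": {},
    }

    # ------------------------------------------------------------ cohort
    t0 = time.time()
    if config.input_dir:
        cohort = syn.read_cohort(config.input_dir)
        cohort_desc = {"source": str(config.input_dir)}
    else:
        ccfg = dataclasses.replace(
            config.cohort, seed=stage_seed(config.seed, "simulate")
        )
        cohort = syn.generate_cohort(ccfg)
        cohort_desc = {"source": "synthetic", "seed": ccfg.seed}
    report["stages"]["cohort"] = {
        **cohort_desc,
        "n_runs": len(cohort.runs),
        "n_mask_voxels": cohort.mask.n_voxels,
    }
    report["durations_s"]["cohort"] = time.time() - t0
    log.info("cohort ready: %d runs, %d mask voxels",
             len(cohort.runs), cohort.mask.n_voxels)

    # ------------------------------------------- preprocess + FCD per run
    t0 = time.time()
    pcfg, fcfg = config.preprocess, config.fcd
    maps = {}  # (subject_id, session) -> {kind: FCDMap}
    fd_means = {}
    qc_rows = []
    for run, motion in zip(cohort.runs, cohort.motion):
        prun, fd, kept, qc = pre.preprocess_run(
            run, motion, cohort.mask, cohort.csf_mask, cohort.wm_mask, pcfg
        )
        fd_means[(run.subject_id, run.session)] = float(np.mean(fd.values))
        qc_rows.append(
            dict(subject_id=run.subject_id, session=run.session,
                 decision=qc[0], reason=qc[1],
                 n_frames_kept=int(kept.size))
        )
        maps[(run.subject_id, run.session)] = fcdmod.compute_fcd_maps(
            prun,
            cohort.mask,
            r_threshold=fcfg.r_threshold,
            lfcd_mode=fcfg.lfcd_mode,
            fwhm_mm=fcfg.fwhm_mm,
            voxel_size_mm=config.cohort.voxel_size_mm,
        )
    report["stages"]["preprocess"] = {
        "params": dataclasses.asdict(pcfg),
        "qc": qc_rows,
        "order": "discard -> FD -> nuisance regression -> bandpass"
                 + (" -> scrub" if pcfg.scrub else ""),
    }
    report["stages"]["fcd"] = {"params": dataclasses.asdict(fcfg)}
    report["durations_s"]["preprocess_fcd"] = time.time() - t0
    log.info("preprocess+FCD done for %d runs", len(cohort.runs))

    labels = cohort.labels
    pre_rows = labels[labels.session == "pre"]
    a_ids = pre_rows[pre_rows.group == "A"].subject_id.tolist()
    b_ids = pre_rows[pre_rows.group == "B"].subject_id.tolist()

    # ------------------------------------------------- motion group tests
    fd_a = [fd_means[(s, "pre")] for s in a_ids]
    fd_b = [fd_means[(s, "pre")] for s in b_ids]
    t_fd, p_fd = pre_motion = pre.group_motion_tests(fd_a, fd_b)
    motion_report = {"baseline_t": t_fd, "baseline_p": p_fd,
                     "mean_fd_a": float(np.mean(fd_a)),
                     "mean_fd_b": float(np.mean(fd_b))}
    post_ids = [s for s in b_ids if (s, "post") in fd_means]
    if post_ids:
        fd_post = [fd_means[(s, "post")] for s in post_ids]
        fd_pre_b = [fd_means[(s, "pre")] for s in post_ids]
        t2, p2 = pre.group_motion_tests(fd_pre_b, fd_post, paired=True)
        motion_report.update(prepost_t=t2, prepost_p=p2)
    report["stages"]["motion_tests"] = motion_report

    # ----------------------------------------------------- demographics
    demo = feat.demographic_tests(labels)
    report["stages"]["demographics"] = demo.to_dict(orient="records")

    # ------------------------------------------------- feature selection
    t0 = time.time()
    fecfg = config.features
    records = []
    offset = 0
    stat_maps = {}
    for kind in ("gFCD", "lFCD", "lrFCD"):
        maps_b = [maps[(s, "pre")][kind] for s in b_ids]
        maps_a = [maps[(s, "pre")][kind] for s in a_ids]
        stat = feat.voxelwise_ttest(maps_b, maps_a, cohort.mask)
        stat_maps[kind] = stat
        table = feat.extract_clusters(
            stat,
            p_threshold=fecfg.p_threshold,
            min_extent=fecfg.min_extent,
            connectivity=fecfg.connectivity,
            fcd_kind=kind,
            id_offset=offset,
        )
        offset += len(table)
        records.extend(table.records)
    clusters = ClusterTable(records)
    report["stages"]["features"] = {
        "params": dataclasses.asdict(fecfg),
        "n_clusters": len(clusters),
        "cluster_table": clusters.to_frame().to_dict(orient="records"),
    }
    report["durations_s"]["features"] = time.time() - t0
    log.info("feature selection: %d discriminative clusters", len(clusters))

    # --------------------------------------------------------- models
    t0 = time.time()
    mcfg = config.models
    svc_summary = {"skipped": "no discriminative clusters"}
    svr_summary = {"skipped": "no discriminative clusters"}
    fisher = None
    if len(clusters) > 0:
        subj_order = a_ids + b_ids
        pre_maps = {s: maps[(s, "pre")] for s in subj_order}
        fm = feat.build_feature_matrix(
            pre_maps, clusters, mode=fecfg.mode, subject_order=subj_order
        )
        y = np.array([0] * len(a_ids) + [1] * len(b_ids))
        fisher = feat.fisher_score(fm, y)
        svc = mod.loocv_svc(
            fm, y,
            c_grid=mcfg.c_grid, gamma_grid=mcfg.gamma_grid,
            inner_cv=mcfg.inner_cv_folds, standardize=mcfg.standardize,
            seed=stage_seed(config.seed, "svc"),
        )
        svc_p = None
        if mcfg.n_perm > 0:
            svc_p, _ = mod.permutation_test_classifier(
                fm, y, n_perm=mcfg.n_perm,
                seed=stage_seed(config.seed, "svc-perm"),
                c_grid=mcfg.c_grid, gamma_grid=mcfg.gamma_grid,
                inner_cv=mcfg.inner_cv_folds, standardize=mcfg.standardize,
            )
        svc_summary = {
            "mean_accuracy": svc.mean_accuracy,
            "sensitivity": svc.sensitivity,
            "specificity": svc.specificity,
            "auc": svc.auc,
            "permutation_p": svc_p,
            "n_permutations": mcfg.n_perm,
            "decision_values": svc.decision_values.tolist(),
            "fisher_scores": [float(v) for v in fisher],
        }

        # treatment-efficacy model on the treated group's change ratios
        post_ok = [s for s in b_ids if (s, "post") in maps]
        if len(post_ok) >= 6:
            fm_pre = feat.build_feature_matrix(
                {s: maps[(s, "pre")] for s in post_ok}, clusters,
                mode=fecfg.mode, subject_order=post_ok,
            )
            fm_post = feat.build_feature_matrix(
                {s: maps[(s, "post")] for s in post_ok}, clusters,
                mode=fecfg.mode, subject_order=post_ok,
            )
            rows = labels[(labels.group == "B") & (labels.session == "pre")]
            rows = rows.set_index("subject_id").loc[post_ok]
            ratios, improvement = mod.change_ratios(
                fm_pre, fm_post,
                rows.score_pre.to_numpy(), rows.score_post.to_numpy(),
            )
            svr = mod.loocv_svr(
                ratios, improvement,
                c_grid=mcfg.c_grid, gamma_grid=mcfg.gamma_grid,
                inner_cv=mcfg.inner_cv_folds, standardize=mcfg.standardize,
                epsilon=mcfg.svr_epsilon,
                seed=stage_seed(config.seed, "svr"),
            )
            svr_p = None
            if mcfg.n_perm > 0:
                svr_p, _ = mod.permutation_test_regressor(
                    ratios, improvement, n_perm=mcfg.n_perm,
                    seed=stage_seed(config.seed, "svr-perm"),
                    c_grid=mcfg.c_grid, gamma_grid=mcfg.gamma_grid,
                    inner_cv=mcfg.inner_cv_folds, standardize=mcfg.standardize,
                    epsilon=mcfg.svr_epsilon,
                )
            mi = None
            if len(post_ok) >= 8:
                mi = feat.mutual_information_scores(
                    ratios, improvement, seed=stage_seed(config.seed, "mi")
                )
            svr_summary = {
                "pearson_r": svr.pearson_r,
                "permutation_p": svr_p,
                "n_permutations": mcfg.n_perm,
                "predicted": svr.predicted.tolist(),
                "actual": svr.actual.tolist(),
                "mutual_information": None if mi is None else [float(v) for v in mi],
            }
        else:
            svr_summary = {"skipped": "fewer than 6 treated subjects with post session"}
    report["stages"]["svc"] = svc_summary
    report["stages"]["svr"] = svr_summary
    report["durations_s"]["models"] = time.time() - t0

    # ------------------------------------------------------------ report
    deterministic_payload = {
        "cluster_table": report["stages"]["features"]["cluster_table"],
        "svc": {k: v for k, v in svc_summary.items() if k != "skipped"},
        "svr": {k: v for k, v in svr_summary.items() if k != "skipped"},
        "demographics": report["stages"]["demographics"],
        "motion_tests": report["stages"]["motion_tests"],
    }
    report["results_checksum"] = fio.checksum_obj(deterministic_payload)

    if write_outputs:
        clusters.to_frame().to_csv(outdir / "cluster_table.csv", index=False)
        demo.to_csv(outdir / "demographics.csv", index=False)
        if len(clusters) > 0:
            fm_df = pd.DataFrame(
                fm.values,
                index=fm.subject_ids,
                columns=[
                    f"{p['fcd_kind']}_c{p['cluster_id']}" for p in fm.feature_provenance
                ],
            )
            fm_df.to_csv(outdir / "feature_matrix.csv")
            if "decision_values" in svc_summary:
                roc_points(
                    np.asarray(svc_summary["decision_values"]),
                    np.array([0] * len(a_ids) + [1] * len(b_ids)),
                ).to_csv(outdir / "roc_points.csv", index=False)
        if config.keep_intermediates:
            mapdir = outdir / "fcd_maps"
            mapdir.mkdir(exist_ok=True)
            for (sid, ses), kindmaps in maps.items():
                for kind, m in kindmaps.items():
                    fio.write_fcd_map(
                        m, mapdir / f"{sid}_ses-{ses}_{kind}.nii.gz"
                    )
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, default=fio._jsonify)
        )
        fio.write_sidecar(outdir / "report.json", {"config": config.to_dict()})
    return report
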