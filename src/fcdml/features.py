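"""Discriminative feature selection from FCD maps.

Voxelwise two-sample t tests select group-discriminative voxels at an
uncorrected p threshold; suprathreshold voxels are grouped into spatial
clusters (increases and decreases separately) with a minimum-extent
filter, and the subject-level feature matrix summarizes each cluster
(cluster-mean by default). Features are ranked by Fisher score for the
classification model and by a k-nearest-neighbor mutual-information
estimate for the regression model.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import (
    BrainMask,
    ClusterRecord,
    ClusterTable,
    FCDMap,
    FeatureMatrix,
    StatMap,
)

__all__ = [
    "voxelwise_ttest",
    "extract_clusters",
    "build_feature_matrix",
    "fisher_score",
    "mutual_information_scores",
    "demographic_tests",
]


def voxelwise_ttest(
    maps_a: Sequence[FCDMap], maps_b: Sequence[FCDMap], mask: BrainMask
) -> StatMap:
    """Pooled-variance two-sample t test at every in-mask voxel.

    Contrast is mean(a) − mean(b) with df = n_a + n_b − 2 and two-sided
    p values. Voxels with zero pooled variance get t = 0, p = 1 by
    convention (no evidence either way), never an error.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    kinds = {m.kind for m in list(maps_a) + list(maps_b)}
    if len(kinds) != 1:
        raise ValueError(f"mixed FCD kinds in one test: {sorted(kinds)}")
    A = np.stack([m.data[mask.data] for m in maps_a]).astype(np.float64)
    B = np.stack([m.data[mask.data] for m in maps_b]).astype(np.float64)
    na, nb = A.shape[0], B.shape[0]
    df = na + nb - 2
    ma, mb = A.mean(0), B.mean(0)
    ssa = ((A - ma) ** 2).sum(0)
    ssb = ((B - mb) ** 2).sum(0)
    pooled = (ssa + ssb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(ma)
    p = np.ones_like(ma)
    ok = se > 0
    t[ok] = (ma[ok] - mb[ok]) / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    t_map = np.zeros(mask.data.shape)
    p_map = np.ones(mask.data.shape)
    t_map[mask.data] = t
    p_map[mask.data] = p
    return StatMap(
        t_values=t_map,
        p_values=p_map,
        df=df,
        contrast=f"{kinds.pop()}: mean(a) - mean(b)",
        affine=mask.affine,
    )


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


def extract_clusters(
    stat: StatMap,
    p_threshold: float = 0.005,
    min_extent: int = 20,
    connectivity: int = 26,
    fcd_kind: str = "gFCD",
    id_offset: int = 0,
) -> ClusterTable:
    """Group suprathreshold voxels into signed spatial clusters.

    Voxels with p < p_threshold are labelled by spatial connectivity,
    separately for positive and negative t values; clusters smaller than
    ``min_extent`` are dropped. The peak is the max-|t| voxel, reported
    in world (mm) coordinates through the affine. An empty table is a
    valid outcome.
    """
    if not 0 < p_threshold < 1 or min_extent < 1:
        raise ValueError("invalid thresholds")
    struct = _structure(connectivity)
    records: list[ClusterRecord] = []
    cid = id_offset
    for sign, name in ((1, "increase"), (-1, "decrease")):
        supra = (stat.p_values < p_threshold) & (np.sign(stat.t_values) == sign)
        labels, n = ndimage.label(supra, structure=struct)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            if vox.shape[0] < min_extent:
                continue
            tvals = stat.t_values[tuple(vox.T)]
            peak_i = int(np.argmax(np.abs(tvals)))
            peak_vox = vox[peak_i]
            world = stat.affine @ np.append(peak_vox, 1.0)
            records.append(
                ClusterRecord(
                    cluster_id=cid,
                    fcd_kind=fcd_kind,
                    extent=vox.shape[0],
                    peak_coordinate=tuple(float(w) for w in world[:3]),
                    peak_t=float(tvals[peak_i]),
                    sign=name,
                    voxel_index_list=vox,
                )
            )
            cid += 1
    # stable, reproducible order: descending extent, then descending |peak t|
    records.sort(key=lambda r: (-r.extent, -abs(r.peak_t)))
    for i, r in enumerate(records):
        r.cluster_id = id_offset + i
    return ClusterTable(records)


def build_feature_matrix(
    maps_by_subject: dict[str, dict[str, FCDMap]],
    clusters: ClusterTable,
    mode: str = "cluster-mean",
    subject_order: Optional[Sequence[str]] = None,
) -> FeatureMatrix:
    """Subjects x features matrix from per-subject FCD maps.

    ``maps_by_subject`` maps subject id -> {fcd_kind -> FCDMap} (smoothed
    maps, one session). Column order is stable and recorded: map kind
    (gFCD, lFCD, lrFCD), then descending extent, then descending |peak t|.
    """
    if len(clusters) == 0:
        raise ValueError("cluster table is empty; no features to build")
    if mode not in ("cluster-mean", "voxel"):
        raise ValueError(f"unknown feature mode {mode!r}")
    subjects = list(subject_order) if subject_order else sorted(maps_by_subject)
    ordered = sorted(
        clusters.records,
        key=lambda r: (FCDMap.KINDS.index(r.fcd_kind), -r.extent, -abs(r.peak_t)),
    )
    cols = []
    provenance = []
    for rec in ordered:
        for sid in subjects:
            if rec.fcd_kind not in maps_by_subject[sid]:
                raise ValueError(f"subject {sid} lacks a {rec.fcd_kind} map")
        if mode == "cluster-mean":
            col = [
                maps_by_subject[sid][rec.fcd_kind]
                .data[tuple(rec.voxel_index_list.T)]
                .mean()
                for sid in subjects
            ]
            cols.append(col)
            provenance.append(
                {
                    "fcd_kind": rec.fcd_kind,
                    "cluster_id": rec.cluster_id,
                    "extent": rec.extent,
                    "peak_t": rec.peak_t,
                    "sign": rec.sign,
                }
            )
        else:
            for v in rec.voxel_index_list:
                cols.append(
                    [
                        float(maps_by_subject[sid][rec.fcd_kind].data[tuple(v)])
                        for sid in subjects
                    ]
                )
                provenance.append(
                    {
                        "fcd_kind": rec.fcd_kind,
                        "cluster_id": rec.cluster_id,
                        "voxel": tuple(int(x) for x in v),
                    }
                )
    values = np.asarray(cols, dtype=float).T
    return FeatureMatrix(values, list(subjects), provenance, mode)


def fisher_score(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence,
    variance: str = "population",
) -> np.ndarray:
    """Fisher discriminability score per feature.

    FS(i) = [n1 (m1i − mi)^2 + n2 (m2i − mi)^2] / [n1 s1i^2 + n2 s2i^2]

    with mi the grand mean, m{g}i the group means, and s{g}i^2 the
    group variances (population form by default, i.e. divide by n).
    The score is non-negative and invariant to affine rescaling of a
    feature; a feature with zero variance in both groups but different
    means scores +inf (perfectly separating, flagged by the caller).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels)
    groups = np.unique(y)
    if groups.size != 2:
        raise ValueError("fisher_score requires exactly two groups")
    ddof = 0 if variance == "population" else 1
    g1, g2 = (X[y == g] for g in groups)
    n1, n2 = len(g1), len(g2)
    m = X.mean(0)
    m1, m2 = g1.mean(0), g2.mean(0)
    v1, v2 = g1.var(0, ddof=ddof), g2.var(0, ddof=ddof)
    num = n1 * (m1 - m) ** 2 + n2 * (m2 - m) ** 2
    den = n1 * v1 + n2 * v2
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return fs


def mutual_information_scores(
    features: FeatureMatrix | np.ndarray,
    target: np.ndarray,
    n_neighbors: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """kNN mutual information of each feature with a continuous target.

    Non-negative by construction (the estimator is clipped at 0);
    constant features score 0. Deterministic given the tie-breaking seed.
    """
    from sklearn.feature_selection import mutual_info_regression

    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] < 8:
        raise ValueError("need at least 8 subjects for MI estimation")
    if X.shape[0] != y.size:
        raise ValueError("target length must match subject count")
    mi = mutual_info_regression(
        X, y, n_neighbors=n_neighbors, random_state=seed
    )
    return np.clip(mi, 0.0, None)


def demographic_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Group-comparison report over a subject table.

    Two-sample t tests for continuous columns between groups at baseline,
    a chi-squared test for categorical columns, and a paired t test for
    pre/post scores within the treated group — the standard demographics
    table of a two-group treatment study.
    """
    pre = table[table.session == "pre"] if "session" in table else table
    a = pre[pre.group == "A"]
    b = pre[pre.group == "B"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in pre.columns:
        if col in ("subject_id", "group", "session"):
            continue
        col_a = a[col].dropna()
        col_b = b[col].dropna()
        if np.issubdtype(pre[col].dtype, np.number):
            if len(col_a) >= 2 and len(col_b) >= 2:
                if np.isclose(col_a.std(), 0) and np.isclose(col_b.std(), 0):
                    t, p = (0.0, 1.0) if np.isclose(col_a.mean(), col_b.mean()) else (np.inf, 0.0)
                else:
                    t, p = stats.ttest_ind(col_a, col_b)
                rows.append(
                    dict(variable=col, test="two-sample t", statistic=float(t),
                         p_value=float(p), mean_a=float(col_a.mean()),
                         mean_b=float(col_b.mean()))
                )
        else:
            if pre[col].nunique() == 1:
                # identical single-category distributions carry no signal
                rows.append(dict(variable=col, test="chi-squared", statistic=0.0,
                                 p_value=1.0, mean_a=np.nan, mean_b=np.nan))
                continue
            contingency = pd.crosstab(pre.group, pre[col])
            if (contingency.values.sum(0) == 0).any():
                raise ValueError(f"degenerate contingency table for {col!r}")
            chi2, p, _, _ = stats.chi2_contingency(contingency)
            rows.append(dict(variable=col, test="chi-squared",
                             statistic=float(chi2), p_value=float(p),
                             mean_a=np.nan, mean_b=np.nan))
    # paired pre/post comparison within the treated group
    if {"score_pre", "score_post"} <= set(table.columns):
        bb = table[(table.group == "B") & (table.session == "pre")]
        pre_s = bb.score_pre.to_numpy(float)
        post_s = bb.score_post.to_numpy(float)
        ok = ~(np.isnan(pre_s) | np.isnan(post_s))
        if ok.sum() >= 2:
            d = pre_s[ok] - post_s[ok]
            if np.allclose(d.std(), 0):
                t, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf * np.sign(d.mean()), np.nextafter(0, 1))
            else:
                t, p = stats.ttest_rel(pre_s[ok], post_s[ok])
            rows.append(
                dict(variable="score_pre_vs_post (group B)", test="paired t",
                     statistic=float(t), p_value=float(p),
                     mean_a=float(pre_s[ok].mean()), mean_b=float(post_s[ok].mean()))
            )
    return pd.DataFrame(rows)
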