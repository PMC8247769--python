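"""Core in-memory containers shared across the pipeline.

Arrays are kept as plain numpy arrays plus the minimal grid metadata
(affine, voxel size, TR) needed to interpret them; NIfTI serialization
lives in :mod:`fcdml.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class BoldRun:
    """One subject-session 4D time series (x, y, z, t)."""

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    subject_id: str
    session: str = "pre"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun.data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BoldRun needs at least 2 frames")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=data)


@dataclass
class BrainMask:
    """3D boolean analysis mask on the same grid as the runs."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BrainMask.data must be 3D")
        if not self.data.any():
            raise ValueError("BrainMask must contain at least one voxel")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, other_shape: tuple[int, int, int], other_affine: np.ndarray) -> None:
        if self.data.shape != tuple(other_shape):
            raise ValueError(
                f"grid mismatch: mask {self.data.shape} vs data {tuple(other_shape)}"
            )
        if not np.allclose(self.affine, other_affine, atol=1e-6):
            raise ValueError("grid mismatch: mask affine differs from data affine")


@dataclass
class MotionParams:
    """T x 6 rigid-body motion parameters: 3 translations (mm), 3 rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("MotionParams.values must be T x 6")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class FDSeries:
    """Per-frame framewise displacement in mm; first frame is 0 by convention."""

    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FDSeries.values must be 1D")
        if (self.values < 0).any():
            raise ValueError("FD values must be non-negative")


@dataclass
class ConfoundMatrix:
    """T x K nuisance regressor matrix (24 motion terms + CSF + WM = 26 full model)."""

    columns: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("ConfoundMatrix.columns must be 2D")
        if self.columns.shape[1] != len(self.column_names):
            raise ValueError("column_names length must match column count")

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]


@dataclass
class FCDMap:
    """Per-voxel functional connectivity density map of one kind.

    Raw maps hold integer suprathreshold-connection counts; smoothed maps
    are real-valued. Values are zero outside the analysis mask.
    """

    data: np.ndarray
    kind: str  # "gFCD" | "lFCD" | "lrFCD"
    r_threshold: float
    affine: np.ndarray
    subject_id: str
    session: str = "pre"
    smoothed_fwhm_mm: Optional[float] = None

    KINDS = ("gFCD", "lFCD", "lrFCD")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("FCDMap.data must be 3D")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown FCD kind {self.kind!r}")


@dataclass
class StatMap:
    """Voxelwise two-sample t map with two-sided p values."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    contrast: str
    affine: np.ndarray


@dataclass
class ClusterRecord:
    cluster_id: int
    fcd_kind: str
    extent: int
    peak_coordinate: tuple[float, float, float]  # world mm
    peak_t: float
    sign: str  # "increase" | "decrease"
    voxel_index_list: np.ndarray  # (extent, 3) voxel indices


@dataclass
class ClusterTable:
    """Suprathreshold cluster records defining the discriminative features."""

    records: list[ClusterRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "cluster_id": r.cluster_id,
                    "fcd_kind": r.fcd_kind,
                    "cluster_voxels": r.extent,
                    "peak_x_mm": r.peak_coordinate[0],
                    "peak_y_mm": r.peak_coordinate[1],
                    "peak_z_mm": r.peak_coordinate[2],
                    "peak_t": r.peak_t,
                    "sign": r.sign,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id",
                "fcd_kind",
                "cluster_voxels",
                "peak_x_mm",
                "peak_y_mm",
                "peak_z_mm",
                "peak_t",
                "sign",
            ],
        )


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with per-column provenance."""

    values: np.ndarray
    subject_ids: list[str]
    feature_provenance: list[dict]
    mode: str  # "cluster-mean" | "voxel"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix.values must be 2D")
        if np.isnan(self.values).any():
            raise ValueError("FeatureMatrix must not contain missing values")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        if self.values.shape[1] != len(self.feature_provenance):
            raise ValueError("column count must match feature_provenance")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SVCResult:
    predicted_labels: np.ndarray
    decision_values: np.ndarray
    true_labels: np.ndarray
    mean_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    best_hyperparams: list[dict]
    permutation_p: Optional[float] = None
    n_permutations: int = 0


@dataclass
class SVRResult:
    predicted: np.ndarray
    actual: np.ndarray
    pearson_r: float
    best_hyperparams: list[dict]
    permutation_p: Optional[float] = None
    n_permutations: int = 0


@dataclass
class SyntheticCohort:
    """Generated runs plus the planted ground truth used to validate the pipeline."""

    runs: list[BoldRun]
    mask: BrainMask
    csf_mask: BrainMask
    wm_mask: BrainMask
    motion: list[MotionParams]
    labels: pd.DataFrame  # subject_id, group, session, score_pre, score_post
    truth_effect_mask: np.ndarray  # 3D bool, union of planted regions
    truth_clusters: list[dict]  # per planted cluster: voxel indices, sign
    truth_improvement: np.ndarray  # per treated subject, (pre-post)/pre
    truth_change_score: Optional[np.ndarray] = None  # planted coupling-change magnitude

    def runs_for(self, group: Optional[str] = None, session: Optional[str] = None):
        out = []
        for run, mot in zip(self.runs, self.motion):
            row = self.labels[
                (self.labels.subject_id == run.subject_id)
                & (self.labels.session == run.session)
            ].iloc[0]
            if group is not None and row.group != group:
                continue
            if session is not None and run.session != session:
                continue
            out.append((run, mot))
        return out
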