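"""Post-realignment preprocessing of resting-state runs.

Implements the fixed chain: initial-volume discarding, framewise
displacement (FD) from rigid-body motion parameters, motion QC, nuisance
regression (24 motion-derived regressors + CSF + WM means), zero-phase
bandpass filtering, and optional FD-based frame scrubbing. Motion
parameters are consumed, never estimated: the chain starts after
realignment, with all runs already on a common grid.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal

from .types import BoldRun, BrainMask, ConfoundMatrix, FDSeries, MotionParams

__all__ = [
    "discard_initial_volumes",
    "build_friston24",
    "compute_fd",
    "qc_exclude",
    "extract_tissue_signals",
    "build_confound_matrix",
    "regress_nuisance",
    "bandpass_filter",
    "scrub_frames",
    "group_motion_tests",
    "preprocess_run",
]


def discard_initial_volumes(
    run: BoldRun, n_discard: int, motion: Optional[MotionParams] = None
):
    """Drop the first ``n_discard`` frames of a run (and its motion rows).

    Discarding the initial frames removes the pre-steady-state volumes
    acquired while longitudinal magnetization settles.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= run.n_frames:
        raise ValueError(
            f"cannot discard {n_discard} of {run.n_frames} frames"
        )
    out = run.with_data(run.data[..., n_discard:])
    if motion is None:
        return out
    if motion.n_frames != run.n_frames:
        raise ValueError("motion rows must match run frame count")
    return out, MotionParams(motion.values[n_discard:])


def build_friston24(motion: MotionParams) -> ConfoundMatrix:
    """Expand 6 motion parameters into the 24-regressor autoregressive model.

    Columns are [p, p(t-1), p^2, p(t-1)^2] for each of the 6 parameters;
    the lag-1 rows at t=0 are zero-filled.
    """
    p = motion.values
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    lag = np.zeros_like(p)
    lag[1:] = p[:-1]
    cols = np.hstack([p, lag, p**2, lag**2])
    names = (
        [f"mot{i}" for i in range(6)]
        + [f"mot{i}_lag1" for i in range(6)]
        + [f"mot{i}_sq" for i in range(6)]
        + [f"mot{i}_lag1_sq" for i in range(6)]
    )
    return ConfoundMatrix(cols, names)


def _rigid_matrix(params: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx, ty, tz, rx, ry, rz); rotations in rad."""
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rz @ Ry @ Rx
    M[:3, 3] = (tx, ty, tz)
    return M


def compute_fd(
    motion: MotionParams, method: str = "jenkinson", head_radius_mm: float = 50.0
) -> FDSeries:
    """Framewise displacement per frame, in mm; FD(0) = 0.

    ``power``: sum of absolute backward differences of the 6 parameters,
    rotations converted to arc length on a sphere of ``head_radius_mm``.

    ``jenkinson``: root-mean-square displacement of points within a sphere
    of ``head_radius_mm`` under the frame-to-frame differential rigid
    transform (the voxel-wise RMS family of motion measures).
    """
    p = motion.values
    T = p.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames")
    fd = np.zeros(T)
    if method == "power":
        d = np.abs(np.diff(p, axis=0))
        fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    elif method == "jenkinson":
        mats = [_rigid_matrix(p[t]) for t in range(T)]
        for t in range(1, T):
            dM = mats[t] @ np.linalg.inv(mats[t - 1]) - np.eye(4)
            A = dM[:3, :3]
            b = dM[:3, 3]
            # mean squared displacement over a solid sphere of radius R:
            # <|A x + b|^2> = R^2/5 * tr(A^T A) + |b|^2
            fd[t] = np.sqrt(
                head_radius_mm**2 / 5.0 * np.trace(A.T @ A) + b @ b
            )
    else:
        raise ValueError(f"unknown FD method {method!r}")
    return FDSeries(fd, method)


def qc_exclude(
    motion: MotionParams, max_rot_deg: float = 2.0, max_trans_mm: float = 2.0
) -> tuple[str, str]:
    """Motion QC: exclude a run when head position strays too far.

    Exclusion is triggered when any frame's displacement relative to the
    reference (first frame) strictly exceeds ``max_trans_mm`` on any
    translation axis or ``max_rot_deg`` on any rotation axis.
    Returns (decision, reason) with decision "keep" or "exclude".
    """
    rel = motion.values - motion.values[0]
    trans = np.abs(rel[:, :3]).max()
    rot_deg = np.degrees(np.abs(rel[:, 3:]).max())
    if trans > max_trans_mm:
        return "exclude", "translation"
    if rot_deg > max_rot_deg:
        return "exclude", "rotation"
    return "keep", ""


def extract_tissue_signals(
    run: BoldRun, csf_mask: BrainMask, wm_mask: BrainMask
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame spatial mean signal within the CSF and WM masks."""
    out = []
    for m in (csf_mask, wm_mask):
        m.check_grid(run.shape3d, run.affine)
        if not m.data.any():
            raise ValueError("empty tissue mask")
        out.append(run.data[m.data].mean(axis=0))
    return out[0], out[1]


def build_confound_matrix(
    motion: MotionParams,
    run: Optional[BoldRun] = None,
    csf_mask: Optional[BrainMask] = None,
    wm_mask: Optional[BrainMask] = None,
) -> ConfoundMatrix:
    """Assemble the full nuisance model: 24 motion regressors + CSF + WM."""
    base = build_friston24(motion)
    cols = [base.columns]
    names = list(base.column_names)
    if run is not None and csf_mask is not None and wm_mask is not None:
        csf, wm = extract_tissue_signals(run, csf_mask, wm_mask)
        cols.append(np.column_stack([csf, wm]))
        names += ["csf", "wm"]
    return ConfoundMatrix(np.hstack(cols), names)


def regress_nuisance(
    run: BoldRun, confounds: ConfoundMatrix, mask: BrainMask
) -> BoldRun:
    """Replace in-mask voxel series by OLS residuals against the confounds.

    An intercept is handled internally; rank-deficient designs fall back
    to the least-norm solution, so collinear confounds never fail.
    Residuals are orthogonal to every confound column up to numerical
    tolerance.
    """
    if confounds.n_frames != run.n_frames:
        raise ValueError("confound rows must equal run frame count")
    mask.check_grid(run.shape3d, run.affine)
    T = run.n_frames
    design = np.column_stack([np.ones(T), confounds.columns])
    Y = run.data[mask.data].T.astype(np.float64)  # T x N
    # pseudoinverse = least-norm OLS, robust to rank deficiency
    beta = np.linalg.pinv(design) @ Y
    resid = Y - design @ beta
    out = run.data.astype(np.float64, copy=True)
    out[mask.data] = resid.T
    return run.with_data(out)


def bandpass_filter(
    run: BoldRun,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    mask: Optional[BrainMask] = None,
    order: int = 4,
) -> BoldRun:
    """Zero-phase Butterworth bandpass of every (in-mask) voxel series.

    Retains slow spontaneous fluctuations while removing scanner drift
    (below ``low_hz``) and respiratory/cardiac-band noise (above
    ``high_hz``).
    """
    nyq = 0.5 / run.tr_seconds
    if not 0 <= low_hz < high_hz < nyq:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyq:g}) Hz"
        )
    sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    if mask is None:
        flat = run.data.reshape(-1, run.n_frames)
        filtered = signal.sosfiltfilt(sos, flat, axis=1)
        out = filtered.reshape(run.data.shape)
    else:
        mask.check_grid(run.shape3d, run.affine)
        out = run.data.astype(np.float64, copy=True)
        out[mask.data] = signal.sosfiltfilt(sos, run.data[mask.data], axis=1)
    return run.with_data(out)


def scrub_frames(
    run: BoldRun,
    fd: FDSeries,
    threshold_mm: float = 0.5,
    min_frames: int = 100,
) -> tuple[BoldRun, np.ndarray]:
    """Remove frames whose FD strictly exceeds ``threshold_mm``.

    Returns the censored run and the kept frame indices (mapping output
    frames back to input frames). Raises when fewer than ``min_frames``
    survive, flagging the run as unusable rather than silently degraded.
    """
    if len(fd.values) != run.n_frames:
        raise ValueError("FD length must equal frame count")
    kept = np.flatnonzero(fd.values <= threshold_mm)
    if kept.size < min_frames:
        raise ValueError(
            f"only {kept.size} frames survive scrubbing (minimum {min_frames})"
        )
    return run.with_data(run.data[..., kept]), kept


def group_motion_tests(
    fd_means_a: np.ndarray, fd_means_b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-sample (or paired) t test on per-subject mean FD values.

    Used to confirm that head motion does not differ between groups at
    baseline nor between pre- and post-treatment sessions.
    """
    from scipy import stats

    a = np.asarray(fd_means_a, dtype=float)
    b = np.asarray(fd_means_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal lengths")
        d = a - b
        if np.allclose(d.std(), 0):
            if np.allclose(d, 0):
                return 0.0, 1.0
            return np.inf * np.sign(d.mean()), np.nextafter(0, 1)
        t, p = stats.ttest_rel(a, b)
    else:
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
            if np.isclose(a.mean(), b.mean()):
                return 0.0, 1.0
            raise ValueError("zero variance in both groups with unequal means")
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def preprocess_run(
    run: BoldRun,
    motion: MotionParams,
    mask: BrainMask,
    csf_mask: Optional[BrainMask] = None,
    wm_mask: Optional[BrainMask] = None,
    config=None,
):
    """Full preprocessing chain for one run.

    Order is fixed and logged by the pipeline: discard -> FD (from motion)
    -> nuisance regression -> bandpass -> optional scrub. Returns
    ``(run, fd, kept_indices, qc)`` where ``kept_indices`` indexes the
    post-discard frames.
    """
    from .config import PreprocessConfig

    cfg = config or PreprocessConfig()
    cfg.validate()
    qc = qc_exclude(motion, cfg.qc_max_rot_deg, cfg.qc_max_trans_mm)
    run, motion = discard_initial_volumes(run, cfg.n_discard, motion)
    fd = compute_fd(motion, cfg.fd_method, cfg.head_radius_mm)
    confounds = build_confound_matrix(motion, run, csf_mask, wm_mask)
    run = regress_nuisance(run, confounds, mask)
    run = bandpass_filter(run, cfg.bandpass_low_hz, cfg.bandpass_high_hz, mask=mask)
    if cfg.scrub:
        run, kept = scrub_frames(
            run, fd, cfg.fd_threshold_mm, cfg.min_frames_after_scrub
        )
    else:
        kept = np.arange(run.n_frames)
    return run, fd, kept, qc
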