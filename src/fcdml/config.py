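"""Configuration objects for the synthetic cohort generator and the pipeline.

All tunables of every stage live here so that a single validated config
fully determines a run; the CLI and `run_pipeline` both consume these.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Optional

import numpy as np


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic resting-state cohort.

    Defaults emulate the target study design: a control group of 30 and a
    treated group of 27 subjects, 255 frames at TR = 2 s on a 3 mm
    isotropic grid, with spatially localized group differences in
    connection density and a post-treatment session in the treated group.
    """

    n_group_a: int = 30  # controls, one session
    n_group_b: int = 27  # treated, pre + post sessions
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_frames: int = 255
    tr_seconds: float = 2.0
    n_effect_clusters: int = 3
    effect_size_d: float = 1.2  # standardized between-group coupling difference
    hub_radius_vox: float = 2.0
    motion_spike_rate: float = 0.02  # probability per frame
    treatment_signal_r: float = 0.7  # target corr(coupling change, improvement)
    noise_sd: float = 20.0  # BOLD fluctuation amplitude, signal units
    seed: int = 0

    # Generator-internal knobs (fixed study conditions, rarely changed).
    base_r: float = 0.6  # operating-point pairwise correlation of coupled voxels
    coupling_sd: float = 0.05  # between-subject sd of the coupling weight
    treatment_effect_scale: float = 0.05  # sd of the post-session coupling change
    blob_size_vox: int = 4  # spatial coherence scale of background communities
    community_size_vox: int = 16  # voxels sharing one background latent
    baseline_offset: float = 1000.0
    score_pre_mean_treated: float = 62.89
    score_pre_sd_treated: float = 11.57
    score_mean_control: float = 29.90
    score_sd_control: float = 7.18
    improvement_mean: float = 0.26
    improvement_sd: float = 0.12

    def validate(self) -> None:
        if min(self.n_group_a, self.n_group_b) < 1:
            raise ValueError("group sizes must be positive")
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 4:
            raise ValueError("grid_shape must be 3 integers >= 4")
        if self.n_frames < 2 or self.tr_seconds <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("n_frames, tr_seconds, voxel_size_mm must be positive")
        if not 0.0 <= self.motion_spike_rate <= 1.0:
            raise ValueError("motion_spike_rate must be in [0, 1]")
        if abs(self.treatment_signal_r) > 1.0:
            raise ValueError("|treatment_signal_r| must be <= 1")
        if self.n_effect_clusters < 0 or self.hub_radius_vox <= 0:
            raise ValueError("n_effect_clusters >= 0 and hub_radius_vox > 0 required")
        if not 0.0 < self.base_r < 1.0:
            raise ValueError("base_r must be in (0, 1)")
        # effect clusters must fit inside the grid
        if 2 * self.hub_radius_vox + 2 > min(self.grid_shape):
            raise ValueError("effect clusters do not fit inside the grid")


@dataclass
class PreprocessConfig:
    n_discard: int = 5
    fd_method: str = "jenkinson"  # "jenkinson" | "power"
    fd_threshold_mm: float = 0.5
    head_radius_mm: float = 50.0
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    scrub: bool = True
    qc_max_rot_deg: float = 2.0
    qc_max_trans_mm: float = 2.0
    min_frames_after_scrub: int = 100

    def validate(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.fd_method not in ("jenkinson", "power"):
            raise ValueError(f"unknown FD method {self.fd_method!r}")
        if not 0 <= self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 <= low < high for the bandpass")


@dataclass
class FCDConfig:
    r_threshold: float = 0.6
    fwhm_mm: float = 6.0
    lfcd_mode: str = "grow"  # "grow" | "neighbors"
    block_size: int = 2048

    def validate(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must be in (0, 1)")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.lfcd_mode not in ("grow", "neighbors"):
            raise ValueError(f"unknown lfcd_mode {self.lfcd_mode!r}")


@dataclass
class FeatureConfig:
    p_threshold: float = 0.005
    min_extent: int = 20
    connectivity: int = 26
    mode: str = "cluster-mean"  # "cluster-mean" | "voxel"
    selection: str = "full"  # "full" | "nested" (nested: documented leakage-free variant)

    def validate(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.mode not in ("cluster-mean", "voxel"):
            raise ValueError(f"unknown feature mode {self.mode!r}")


DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**k) for k in range(-15, 4, 2))


@dataclass
class ModelConfig:
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    inner_cv_folds: int = 5
    n_perm: int = 1000
    standardize: bool = True
    svr_epsilon: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if len(self.c_grid) == 0 or len(self.gamma_grid) == 0:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass
class PipelineConfig:
    """Full pipeline configuration; unknown keys are rejected on load."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcd: FCDConfig = field(default_factory=FCDConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    output_dir: str = "fcdml_out"
    input_dir: Optional[str] = None  # if set, read a written cohort instead of simulating
    keep_intermediates: bool = True

    def validate(self) -> None:
        for sub in (self.cohort, self.preprocess, self.fcd, self.features, self.models):
            sub.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        sections = {
            "cohort": CohortConfig,
            "preprocess": PreprocessConfig,
            "fcd": FCDConfig,
            "features": FeatureConfig,
            "models": ModelConfig,
        }
        for name, klass in sections.items():
            sub = d.pop(name, {}) or {}
            allowed = {f.name for f in fields(klass)}
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            if "grid_shape" in sub:
                sub["grid_shape"] = tuple(sub["grid_shape"])
            for g in ("c_grid", "gamma_grid"):
                if g in sub:
                    sub[g] = tuple(float(v) for v in sub[g])
            kwargs[name] = klass(**sub)
        top_allowed = {"seed", "output_dir", "input_dir", "keep_intermediates"}
        unknown = set(d) - top_allowed
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one root seed.

    Deterministic scheme: SeedSequence spawned with a stable stage key so
    that all randomness in a pipeline run flows from a single root seed.
    """
    key = int.from_bytes(stage.encode("utf8"), "little") % (2**30)
    ss = np.random.SeedSequence([int(root_seed) % (2**31), key])
    return int(ss.generate_state(1)[0] % (2**31))
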