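"""Synthetic resting-state cohorts with planted connectivity-density structure.

The generator emulates the study design the pipeline targets: a control
group (one session) and a treated group (pre- and post-treatment
sessions), 4D runs on a common 3 mm grid, rigid-body motion traces with
occasional spike frames, and a symptom score that improves after
treatment.

Because FCD is a correlation-count statistic, group differences are
planted in *covariance*, not in means. Background connectivity is
organized into latent "communities": small spatial blobs (a few voxels,
the local coherence scale) are scattered at random into communities of
~32 voxels that share one latent signal, and every coupled voxel mixes
its community latent at a per-subject weight

    x_v(t) = u_v * L_comm(t) + sqrt(1 - u_v^2) * e_v(t),

so the correlation between two community members is u_i * u_j. The
baseline weight u0 = sqrt(base_r) puts pairwise correlations exactly at
the FCD threshold, where the suprathreshold-edge probability is 1/2 and
per-subject edge counts fluctuate smoothly and symmetrically around
half the community size. Because the blobs of a community are scattered,
count fluctuations are spatially independent beyond the blob scale:
smoothing then averages independent contributions and the voxelwise
group t test on null cohorts is calibrated, while contiguous
false-positive clusters above a ~20-voxel extent are improbable.

Planted effect clusters are pairs of distant spheres sharing their own
latent (so the effect lives in local and long-range connections alike);
the treated group's mean coupling weight inside them is shifted by
``effect_size_d * coupling_sd / 2`` (both edge endpoints shift, so the
standardized between-group difference of the resulting raw counts is
approximately ``effect_size_d``). Post-treatment sessions move each
treated subject's in-cluster weight back toward baseline by an amount
correlated with that subject's symptom improvement at
``treatment_signal_r``.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig
from .types import BoldRun, BrainMask, MotionParams, SyntheticCohort

__all__ = [
    "generate_cohort",
    "generate_motion_params",
    "write_cohort",
    "read_cohort",
    "build_masks",
]

_U_CLIP = (0.05, 0.95)


def _random_phase_series(n_series: int, T: int, rng) -> np.ndarray:
    """Unit-variance series with a flat (deterministic) power spectrum.

    Latent signals are synthesized in the frequency domain with constant
    modulus and random phases, so every latent realization carries
    exactly the same power into the analysis band. This keeps the
    suprathreshold-edge probability of a community from being modulated
    wholesale by the chance band power of its latent (which would induce
    strong community-wide dependence of the counts across subjects).
    Marginals are Gaussian to good approximation (sums of many random
    phase sinusoids).
    """
    n_bins = T // 2 + 1
    phases = rng.uniform(0.0, 2.0 * np.pi, (n_series, n_bins))
    spec = np.exp(1j * phases)
    spec[:, 0] = 0.0  # no DC component
    if T % 2 == 0:
        spec[:, -1] = np.sign(np.cos(phases[:, -1]))  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=T, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x.astype(np.float32)


def _grid_affine(shape, voxel_size):
    """RAS affine with the world origin at the grid center."""
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    center = (np.asarray(shape) - 1) / 2.0
    aff[:3, 3] = -center * voxel_size
    return aff


def build_masks(config: CohortConfig):
    """Ellipsoidal brain with a central core split into CSF and WM.

    The analysis mask is the ellipsoid minus the core; for the default
    24-voxel grid this yields roughly 5,000 analysis voxels.
    """
    shape = np.asarray(config.grid_shape)
    aff = _grid_affine(shape, config.voxel_size_mm)
    center = (shape - 1) / 2.0
    semi = 0.46 * shape
    ii = np.indices(tuple(shape)).astype(float)
    dist_ell = sum(((ii[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    radial = np.sqrt(sum((ii[k] - center[k]) ** 2 for k in range(3)))
    brain = dist_ell <= 1.0
    core_r = 0.19 * shape.min()
    csf_r = 0.10 * shape.min()
    csf = brain & (radial <= csf_r)
    wm = brain & (radial <= core_r) & ~csf
    analysis = brain & ~csf & ~wm
    return (
        BrainMask(analysis, aff),
        BrainMask(csf, aff),
        BrainMask(wm, aff),
    )


def _voronoi_cells(mask_idx: np.ndarray, n_cells: int, rng) -> np.ndarray:
    """Partition mask voxels into compact cells by nearest random seed."""
    n = mask_idx.shape[0]
    seeds = mask_idx[rng.choice(n, size=n_cells, replace=False)].astype(float)
    # nearest-seed assignment, blocked to bound memory
    assign = np.empty(n, dtype=np.int64)
    for start in range(0, n, 4096):
        stop = min(start + 4096, n)
        d2 = ((mask_idx[start:stop, None, :] - seeds[None, :, :]) ** 2).sum(-1)
        assign[start:stop] = d2.argmin(1)
    return assign


def _background_communities(mask_idx: np.ndarray, blob_size: int,
                            community_size: int, rng) -> np.ndarray:
    """Assign every mask voxel to a latent community.

    Voxels are first grouped into compact spatial blobs (Voronoi cells of
    ~``blob_size`` voxels); blobs are then shuffled and chunked into
    communities of ~``community_size`` voxels. Members of one community
    share a latent signal wherever they sit in the brain, so most
    connections are long-range and count fluctuations are spatially
    independent beyond the blob scale.
    """
    n = mask_idx.shape[0]
    n_blobs = max(2, n // max(1, blob_size))
    blob_of = _voronoi_cells(mask_idx, n_blobs, rng)
    order = rng.permutation(n_blobs)
    blobs_per_comm = max(1, round(community_size / max(1, blob_size)))
    comm_of_blob = np.empty(n_blobs, dtype=np.int64)
    for i, b in enumerate(order):
        comm_of_blob[b] = i // blobs_per_comm
    return comm_of_blob[blob_of]


def _place_effect_spheres(config: CohortConfig, mask: BrainMask, rng):
    """Place ``n_effect_clusters`` pairs of non-overlapping spheres.

    Each planted cluster is a pair of distant spheres sharing a latent,
    so the effect appears in local (within-sphere) and long-range
    (cross-sphere) connections alike. Raises when the requested clusters
    cannot fit into the mask.
    """
    r = config.hub_radius_vox
    shape = np.asarray(config.grid_shape)
    idx = np.argwhere(mask.data)
    ii = np.indices(tuple(shape)).astype(float)

    sphere_vol = 4.0 / 3.0 * np.pi * r**3
    if config.n_effect_clusters * 2 * sphere_vol > mask.n_voxels:
        raise ValueError("effect clusters exceed the mask volume")

    def sphere_voxels(center):
        d = np.sqrt(sum((ii[k] - center[k]) ** 2 for k in range(3)))
        return (d <= r) & mask.data

    # candidate centers: sphere fully inside analysis mask
    taken = np.zeros(tuple(shape), dtype=bool)
    placed = []
    min_sep = 2 * r + 2
    attempts = 0
    while len(placed) < 2 * config.n_effect_clusters:
        attempts += 1
        if attempts > 5000:
            raise ValueError("could not place effect clusters in the mask")
        c = idx[rng.integers(idx.shape[0])]
        vox = sphere_voxels(c)
        # fully inside, and the sphere must not clip the mask border badly
        d = np.sqrt(sum((ii[k] - c[k]) ** 2 for k in range(3)))
        if ((d <= r) & ~mask.data).any():
            continue
        if any(np.linalg.norm(c - p["center"]) < min_sep for p in placed):
            continue
        if len(placed) % 2 == 1:  # partner: keep it distant from its hub
            hub = placed[-1]
            if np.linalg.norm(c - hub["center"]) < 3 * r:
                continue
        placed.append({"center": c.astype(float), "voxels": np.argwhere(vox)})
        taken |= vox
    clusters = []
    for k in range(config.n_effect_clusters):
        hub, partner = placed[2 * k], placed[2 * k + 1]
        clusters.append(
            {
                "cluster_id": k,
                "sign": 1 if k % 2 == 0 else -1,
                "hub_voxels": hub["voxels"],
                "partner_voxels": partner["voxels"],
            }
        )
    return clusters


def generate_motion_params(
    n_frames: int, spike_rate: float, seed: int, tr_seconds: float = 2.0
) -> MotionParams:
    """Smooth low-amplitude drift plus isolated displacement spikes.

    Drift is a small-increment random walk (translations ~0.01 mm/frame,
    rotations ~1e-4 rad/frame, giving a mean framewise displacement near
    0.04 mm, the magnitude typical of compliant adult participants).
    Spikes are sudden translation steps of 0.6-1.0 mm whose framewise
    displacement is guaranteed to exceed the 0.5 mm scrubbing threshold
    under both FD formulas; step direction alternates toward zero so the
    cumulative excursion stays well below the 2 mm QC limit. Expected
    spike count = spike_rate * n_frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    vals = np.zeros((n_frames, 6))
    incr = np.column_stack(
        [rng.normal(0, 0.01, (n_frames - 1, 3)), rng.normal(0, 1e-4, (n_frames - 1, 3))]
    )
    vals[1:] = np.cumsum(incr, axis=0)
    spike_frames = np.flatnonzero(rng.random(n_frames) < spike_rate)
    spike_frames = spike_frames[spike_frames > 0]
    offset = 0.0
    for t in spike_frames:
        mag = rng.uniform(0.6, 1.0)
        sign = -np.sign(offset) if offset != 0 else (1.0 if rng.random() < 0.5 else -1.0)
        offset += sign * mag
        vals[t:, 0] += sign * mag  # sustained step on the x translation
    return MotionParams(vals)


def _improvement_scores(config: CohortConfig, rng):
    """Per-treated-subject symptom scores and improvement fractions."""
    nb = config.n_group_b
    pre = rng.normal(config.score_pre_mean_treated, config.score_pre_sd_treated, nb)
    pre = np.clip(pre, 50.5, 95.0)  # diagnosis requires a high baseline score
    imp = rng.normal(config.improvement_mean, config.improvement_sd, nb)
    imp = np.clip(imp, 0.02, 0.75)
    post = pre * (1.0 - imp)
    return pre, post, imp


def _change_scores(imp: np.ndarray, target_r: float, n_clusters: int, rng):
    """Per-cluster latent treatment-response scores.

    Each planted cluster gets its own change score whose population
    correlation with the improvement fraction is ``target_r``; the
    residual components are independent draws per cluster, so no
    artificial common factor ties the cluster changes together beyond
    the improvement signal itself. The residuals are deliberately NOT
    orthogonalized against the improvement in-sample: exact zero
    sample correlation would make every leave-one-out training fold
    systematically anti-correlated, planting an artifactual negative
    signal in null cohorts.
    """
    n = imp.size
    z_imp = (imp - imp.mean()) / max(imp.std(), 1e-12)
    cols = []
    for _ in range(max(1, n_clusters)):
        zeta = rng.standard_normal(n)
        cols.append(target_r * z_imp + np.sqrt(max(0.0, 1.0 - target_r**2)) * zeta)
    return np.column_stack(cols)  # (n_subjects, n_clusters)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mask, csf_mask, wm_mask = build_masks(config)
    shape = tuple(config.grid_shape)
    aff = mask.affine
    mask_idx = np.argwhere(mask.data)
    n_mask = mask_idx.shape[0]

    # --- background communities (scattered blobs sharing a latent) ---
    latent_of = _background_communities(
        mask_idx, config.blob_size_vox, config.community_size_vox, rng
    )
    n_bg_pairs = int(latent_of.max()) + 1

    # --- planted effect clusters override background membership ---
    clusters = (
        _place_effect_spheres(config, mask, rng)
        if config.n_effect_clusters > 0
        else []
    )
    lut = -np.ones(shape, dtype=np.int64)
    lut[tuple(mask_idx.T)] = np.arange(n_mask)
    sign_of_voxel = np.zeros(n_mask)
    truth_effect_mask = np.zeros(shape, dtype=bool)
    for c in clusters:
        lat = n_bg_pairs + c["cluster_id"]
        for key in ("hub_voxels", "partner_voxels"):
            flat = lut[tuple(c[key].T)]
            latent_of[flat] = lat
            sign_of_voxel[flat] = c["sign"]
            truth_effect_mask[tuple(c[key].T)] = True
    n_latents = n_bg_pairs + len(clusters)

    # --- per-subject coupling weights ---
    u0 = np.sqrt(config.base_r)
    delta = config.effect_size_d * config.coupling_sd / 2.0
    subjects_a = [f"sub-A{i+1:02d}" for i in range(config.n_group_a)]
    subjects_b = [f"sub-B{i+1:02d}" for i in range(config.n_group_b)]

    eta_a = rng.normal(0.0, config.coupling_sd, (config.n_group_a, n_mask))
    eta_b = rng.normal(0.0, config.coupling_sd, (config.n_group_b, n_mask))
    u_a = np.clip(u0 + eta_a, *_U_CLIP)
    u_b_pre = np.clip(u0 + sign_of_voxel * delta + eta_b, *_U_CLIP)

    # --- treatment response (group B post session) ---
    score_pre_b, score_post_b, improvement = _improvement_scores(config, rng)
    change = _change_scores(
        improvement, config.treatment_signal_r, len(clusters), rng
    )
    u_b_post = u_b_pre.copy()
    for c in clusters:
        k = c["cluster_id"]
        vox = np.concatenate(
            [lut[tuple(c["hub_voxels"].T)], lut[tuple(c["partner_voxels"].T)]]
        )
        shift = -config.treatment_effect_scale * c["sign"] * change[:, k]
        u_b_post[:, vox] = np.clip(u_b_pre[:, vox] + shift[:, None], *_U_CLIP)
    score_a = rng.normal(
        config.score_mean_control, config.score_sd_control, config.n_group_a
    )

    # --- tissue voxels that carry unstructured noise ---
    csf_idx = np.argwhere(csf_mask.data)
    wm_idx = np.argwhere(wm_mask.data)

    def make_run(subject_id: str, session: str, u_row: np.ndarray) -> BoldRun:
        T = config.n_frames
        latents = _random_phase_series(n_latents, T, rng)
        noise = rng.standard_normal((n_mask, T), dtype=np.float32)
        u = u_row.astype(np.float32)[:, None]
        sig = u * latents[latent_of] + np.sqrt(1.0 - u**2) * noise
        data = np.zeros(shape + (T,), dtype=np.float32)
        data[tuple(mask_idx.T)] = config.baseline_offset + config.noise_sd * sig
        for tidx in (csf_idx, wm_idx):
            if tidx.size:
                data[tuple(tidx.T)] = (
                    config.baseline_offset
                    + config.noise_sd
                    * rng.standard_normal((tidx.shape[0], T), dtype=np.float32)
                )
        return BoldRun(
            data,
            tr_seconds=config.tr_seconds,
            voxel_size_mm=(config.voxel_size_mm,) * 3,
            affine=aff,
            subject_id=subject_id,
            session=session,
        )

    runs: list[BoldRun] = []
    motion: list[MotionParams] = []
    rows = []
    for i, sid in enumerate(subjects_a):
        runs.append(make_run(sid, "pre", u_a[i]))
        motion.append(
            generate_motion_params(
                config.n_frames,
                config.motion_spike_rate,
                int(rng.integers(2**31)),
                config.tr_seconds,
            )
        )
        rows.append(
            dict(subject_id=sid, group="A", session="pre",
                 score_pre=score_a[i], score_post=np.nan)
        )
    for i, sid in enumerate(subjects_b):
        for session, u_row in (("pre", u_b_pre[i]), ("post", u_b_post[i])):
            runs.append(make_run(sid, session, u_row))
            motion.append(
                generate_motion_params(
                    config.n_frames,
                    config.motion_spike_rate,
                    int(rng.integers(2**31)),
                    config.tr_seconds,
                )
            )
            rows.append(
                dict(subject_id=sid, group="B", session=session,
                     score_pre=score_pre_b[i], score_post=score_post_b[i])
            )

    labels = pd.DataFrame(rows)
    truth_clusters = [
        {
            "cluster_id": c["cluster_id"],
            "sign": c["sign"],
            "hub_voxels": c["hub_voxels"],
            "partner_voxels": c["partner_voxels"],
        }
        for c in clusters
    ]
    return SyntheticCohort(
        runs=runs,
        mask=mask,
        csf_mask=csf_mask,
        wm_mask=wm_mask,
        motion=motion,
        labels=labels,
        truth_effect_mask=truth_effect_mask,
        truth_clusters=truth_clusters,
        truth_improvement=improvement,
        truth_change_score=config.treatment_effect_scale * change,
    )


# ---------------------------------------------------------------------------
# on-disk round trip


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(cohort: SyntheticCohort, directory) -> Path:
    """Write a cohort to disk; returns the manifest path.

    Layout: one NIfTI per run, one tissue labelmap (0 outside, 1 analysis
    mask, 2 WM, 3 CSF), one 6-column motion text file per run, one
    subject table. The manifest has one row per run (bold + motion paths
    and checksums) plus one row for the labelmap and one for the subject
    table.
    """
    import nibabel as nib

    if not cohort.runs:
        raise ValueError("cannot write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tissues = np.zeros(cohort.mask.data.shape, dtype=np.int16)
    tissues[cohort.mask.data] = 1
    tissues[cohort.wm_mask.data] = 2
    tissues[cohort.csf_mask.data] = 3
    mask_path = directory / "tissues.nii.gz"
    nib.save(nib.Nifti1Image(tissues, cohort.mask.affine), mask_path)

    table_path = directory / "subjects.csv"
    cohort.labels.to_csv(table_path, index=False)

    rows = []
    for run, mot in zip(cohort.runs, cohort.motion):
        stem = f"{run.subject_id}_ses-{run.session}"
        bold_path = directory / f"{stem}_bold.nii.gz"
        img = nib.Nifti1Image(run.data, run.affine)
        img.header.set_zooms(run.voxel_size_mm + (run.tr_seconds,))
        nib.save(img, bold_path)
        mot_path = directory / f"{stem}_motion.txt"
        np.savetxt(mot_path, mot.values, fmt="%.10g")
        rows.append(
            dict(
                kind="run",
                subject_id=run.subject_id,
                session=run.session,
                path=bold_path.name,
                sha256=_sha256(bold_path),
                motion_path=mot_path.name,
                motion_sha256=_sha256(mot_path),
            )
        )
    rows.append(dict(kind="mask", subject_id="", session="", path=mask_path.name,
                     sha256=_sha256(mask_path), motion_path="", motion_sha256=""))
    rows.append(dict(kind="subject_table", subject_id="", session="",
                     path=table_path.name, sha256=_sha256(table_path),
                     motion_path="", motion_sha256=""))
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    truth = {
        "truth_improvement": [float(v) for v in cohort.truth_improvement],
        "n_truth_clusters": len(cohort.truth_clusters),
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2))
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv").fillna("")
    timg = nib.load(directory / "tissues.nii.gz")
    tissues = np.asarray(timg.dataobj)
    aff = timg.affine
    mask = BrainMask(tissues == 1, aff)
    wm = BrainMask(tissues == 2, aff)
    csf = BrainMask(tissues == 3, aff)
    labels = pd.read_csv(directory / "subjects.csv")
    runs, motion = [], []
    for _, row in manifest[manifest.kind == "run"].iterrows():
        img = nib.load(directory / row.path)
        zooms = img.header.get_zooms()
        runs.append(
            BoldRun(
                np.asarray(img.dataobj),
                tr_seconds=float(zooms[3]) if len(zooms) > 3 else 2.0,
                voxel_size_mm=tuple(float(z) for z in zooms[:3]),
                affine=img.affine,
                subject_id=str(row.subject_id),
                session=str(row.session),
            )
        )
        motion.append(MotionParams(np.loadtxt(directory / row.motion_path)))
    truth = json.loads((directory / "truth.json").read_text())
    return SyntheticCohort(
        runs=runs,
        mask=mask,
        csf_mask=csf,
        wm_mask=wm,
        motion=motion,
        labels=labels,
        truth_effect_mask=np.zeros(mask.data.shape, dtype=bool),
        truth_clusters=[],
        truth_improvement=np.asarray(truth["truth_improvement"]),
    )
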