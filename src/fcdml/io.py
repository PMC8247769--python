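"""NIfTI-1 reading/writing and provenance sidecars."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
import nibabel as nib
import numpy as np

from .types import BoldRun, BrainMask, FCDMap

__all__ = [
    "read_bold",
    "read_mask",
    "write_bold",
    "write_mask",
    "write_fcd_map",
    "read_motion",
    "write_sidecar",
    "checksum_file",
    "checksum_obj",
]


def read_bold(path, subject_id: str = "", session: str = "pre") -> BoldRun:
    """Load a 4D NIfTI run; 3D files are rejected (use :func:`read_mask`)."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise ValueError(f"{path} is {len(img.shape)}D; a BOLD run must be 4D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldRun(
        np.asarray(img.dataobj),
        tr_seconds=tr,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        affine=img.affine,
        subject_id=subject_id or Path(path).name.split("_")[0],
        session=session,
    )


def read_mask(path) -> BrainMask:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path} is {len(img.shape)}D; a mask must be 3D")
    return BrainMask(np.asarray(img.dataobj) > 0, img.affine)


def write_bold(run: BoldRun, path) -> Path:
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), run.affine)
    img.header.set_zooms(run.voxel_size_mm + (run.tr_seconds,))
    nib.save(img, str(path))
    return Path(path)


def write_mask(mask: BrainMask, path) -> Path:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))
    return Path(path)


def write_fcd_map(fcd_map: FCDMap, path, sidecar: bool = True) -> Path:
    """Write an FCD map with kind/threshold/FWHM recorded in header + sidecar."""
    img = nib.Nifti1Image(fcd_map.data.astype(np.float32), fcd_map.affine)
    desc = f"{fcd_map.kind} r>{fcd_map.r_threshold:g} fwhm={fcd_map.smoothed_fwhm_mm or 0:g}mm"
    img.header["descrip"] = desc.encode()[:79]
    nib.save(img, str(path))
    if sidecar:
        write_sidecar(
            path,
            {
                "kind": fcd_map.kind,
                "r_threshold": fcd_map.r_threshold,
                "smoothed_fwhm_mm": fcd_map.smoothed_fwhm_mm,
                "subject_id": fcd_map.subject_id,
                "session": fcd_map.session,
            },
        )
    return Path(path)


def read_motion(path) -> np.ndarray:
    return np.loadtxt(str(path))


def write_sidecar(data_path, params: dict) -> Path:
    """JSON sidecar next to a data file, recording parameters/provenance."""
    p = Path(str(data_path))
    side = p.with_name(p.name.split(".")[0] + ".json")
    side.write_text(json.dumps(params, indent=2, default=_jsonify))
    return side


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def checksum_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def checksum_obj(obj) -> str:
    """Checksum of a canonical JSON rendering of a (nested) result object."""
    text = json.dumps(obj, sort_keys=True, default=_jsonify)
    return hashlib.sha256(text.encode()).hexdigest()
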