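"""Disk formats: multi-page TIFF stacks with JSON sidecars, CSV map export.

Every stack written by the simulator or pipeline is a plain multi-page
TIFF accompanied by ``<name>.json`` carrying provenance (frame order,
wavelength, seed, ground truth where known), so an acquisition folder is
self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .calibration import CalibrationResult
from .mueller import DecompositionResult, IntensityStack, MuellerMap
from .pshg import PSHGStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_pshg_stack",
    "read_pshg_stack",
    "write_mueller_map",
    "read_mueller_map",
    "write_decomposition",
    "write_calibration",
    "read_calibration",
    "write_scalar_csv",
    "read_scalar_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(path: Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    _sidecar_path(path).write_text(json.dumps(payload, indent=2, default=default))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    return json.loads(sc.read_text()) if sc.exists() else {}


# ---------------------------------------------------------------------------
# intensity stacks


def write_stack(path, stack: IntensityStack, extra: dict | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "kind": "intensity_stack",
        "frame_order": stack.frame_order,
        "wavelength_nm": stack.wavelength_nm,
        "n_frames": int(stack.frames.shape[0]),
        **stack.meta,
        **(extra or {}),
    }
    _write_sidecar(path, meta)
    return path


def read_stack(path) -> IntensityStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path)
    return IntensityStack(
        frames=frames,
        frame_order=meta.get("frame_order", "psg-major"),
        wavelength_nm=meta.get("wavelength_nm", 550.0),
        meta=meta,
    )


def write_pshg_stack(path, stack: PSHGStack, extra: dict | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "kind": "pshg_stack",
        "excitation_angles_deg": stack.excitation_angles_deg,
        "pixel_size_nm": stack.pixel_size_nm,
        "binning": stack.binning,
        **(extra or {}),
    }
    _write_sidecar(path, meta)
    return path


def read_pshg_stack(path) -> PSHGStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path)
    angles = meta.get("excitation_angles_deg")
    if angles is None:
        angles = np.linspace(0.0, 180.0, frames.shape[0], endpoint=False)
    return PSHGStack(
        frames=frames,
        excitation_angles_deg=np.asarray(angles, dtype=float),
        pixel_size_nm=meta.get("pixel_size_nm", 170.0),
        binning=meta.get("binning", 1),
    )


# ---------------------------------------------------------------------------
# Mueller maps and decompositions


def write_mueller_map(path, mm: MuellerMap) -> Path:
    """16 planes (matrix elements row-major) + one m11 plane + one mask plane."""
    path = Path(path)
    h, w = mm.shape
    planes = np.concatenate(
        [
            mm.matrices.reshape(h, w, 16).transpose(2, 0, 1),
            mm.m11[None],
            mm.mask.astype(float)[None],
        ]
    )
    tifffile.imwrite(path, planes.astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {
            "kind": "mueller_map",
            "wavelength_nm": mm.wavelength_nm,
            "n_valid": int(mm.mask.sum()),
            "n_pixels": int(mm.mask.size),
        },
    )
    return path


def read_mueller_map(path) -> MuellerMap:
    path = Path(path)
    planes = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path)
    matrices = planes[:16].transpose(1, 2, 0).reshape(*planes.shape[1:], 4, 4)
    return MuellerMap(
        matrices=matrices,
        m11=planes[16],
        wavelength_nm=meta.get("wavelength_nm", 550.0),
        mask=planes[17] > 0.5,
    )


def write_decomposition(path, dec: DecompositionResult) -> Path:
    """Scalar maps as planes: delta, retardance, diattenuation, mask."""
    path = Path(path)
    mask = (
        dec.mask
        if dec.mask is not None
        else np.isfinite(dec.delta)
    )
    planes = np.stack(
        [dec.delta, dec.retardance, dec.diattenuation, mask.astype(float)]
    )
    tifffile.imwrite(path, planes.astype(np.float32), photometric="minisblack")
    _write_sidecar(
        path,
        {
            "kind": "decomposition",
            "planes": ["delta", "retardance_deg", "diattenuation", "mask"],
            "clamp_count": dec.clamp_count,
            "d_clamp_count": dec.d_clamp_count,
            "n_valid": int(np.count_nonzero(mask)),
        },
    )
    return path


# ---------------------------------------------------------------------------
# calibration results


def write_calibration(path, cal: CalibrationResult) -> Path:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {"W": cal.W, "A": cal.A, "residual": np.asarray(cal.residual)}
    if cal.mask is not None:
        arrays["mask"] = cal.mask
    np.savez(path, **arrays)
    _write_sidecar(
        path,
        {
            "kind": "calibration",
            "scale_convention": cal.scale_convention,
            "refined_refs": [
                {
                    "kind": r.kind,
                    "orientation_deg": r.orientation_deg,
                    "retardance_deg": r.retardance_deg,
                    "transmittance": r.transmittance,
                }
                for r in cal.refined_refs
            ],
        },
    )
    return path


def read_calibration(path) -> CalibrationResult:
    path = Path(path)
    data = np.load(path)
    meta = _read_sidecar(path)
    residual = data["residual"]
    return CalibrationResult(
        W=data["W"],
        A=data["A"],
        residual=float(residual) if residual.ndim == 0 else residual,
        scale_convention=meta.get("scale_convention", "W[0,0]=1"),
        mask=data["mask"] if "mask" in data else None,
    )


# ---------------------------------------------------------------------------
# scalar maps as CSV matrices


def write_scalar_csv(path, scalar_map: np.ndarray) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(scalar_map, dtype=float), delimiter=",")
    return path


def read_scalar_csv(path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", ndmin=2)
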