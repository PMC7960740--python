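"""End-to-end orchestration: simulate a study folder, then analyze it.

``run_simulate`` writes a self-describing dataset (calibration stacks,
per-condition sample stacks, a contraction pair, a pSHG stack) under a
seeded manifest.  ``run_full`` replays the analysis chain on such a
folder: calibrate -> reconstruct -> decompose -> ROI statistics ->
group comparison -> contraction and pSHG readouts, emitting a tidy CSV,
a JSON report, and map images.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .assay import analyze_contraction, central_roi, group_compare, roi_stats, ROI
from .calibration import calibrate_field, default_reference_set
from .mueller import decompose_map, reconstruct
from .pshg import circular_variance, entropy, fit_orientation, orientation_histogram
from .synthetic import (
    AcquisitionConfig,
    ContractionScene,
    PshgScene,
    make_scene,
    scene_to_mueller,
    simulate_acquisition,
    simulate_calibration_set,
    simulate_contraction_pair,
    simulate_pshg_stack,
)

__all__ = ["PipelineConfig", "run_simulate", "run_full"]

log = logging.getLogger("muellerpol")

VALID_WAVELENGTHS = tuple(range(450, 701, 50))


@dataclass
class PipelineConfig:
    """Configuration shared by the simulator and the analysis chain."""

    height: int = 64
    width: int = 48
    wavelength_nm: float = 550.0
    seed: int = 0
    noise_model: str = "poisson"  # none | poisson | gaussian
    photon_budget: float = 10_000.0
    length_scale: float = 20.0
    roi: str | tuple[int, int, int, int] = "auto-central"
    roi_fraction: float = 0.5
    delta_bins: int = 100
    retardance_bins: int = 180
    alpha: float = 0.05
    calibration_mode: str = "global"  # global | per_pixel
    n_samples: int = 3
    # per-condition ground-truth ranges for the synthetic study
    conditions: dict = field(
        default_factory=lambda: {
            "control": {"delta": [0.2, 0.4], "retardance": [5.0, 15.0]},
            "contracted": {"delta": [0.2, 0.4], "retardance": [30.0, 60.0]},
        }
    )

    def __post_init__(self) -> None:
        if int(self.wavelength_nm) not in VALID_WAVELENGTHS:
            raise ValueError(
                f"wavelength must be one of {VALID_WAVELENGTHS} nm"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def resolve_roi(self, shape: tuple[int, int]) -> ROI:
        if self.roi == "auto-central":
            return central_roi(shape, self.roi_fraction)
        x0, y0, x1, y1 = self.roi
        return ROI(x0=x0, y0=y0, x1=x1, y1=y1)


def _item_seed(base: int, index: int) -> int:
    return int((base * 100_003 + 7919 * index + 1) % (2**31))


# ---------------------------------------------------------------------------
# simulation side


def run_simulate(cfg: PipelineConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` with a seeded manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "files": {},
    }
    refs = default_reference_set()

    acq = AcquisitionConfig(
        photon_budget=cfg.photon_budget,
        noise_model=cfg.noise_model,
        seed=_item_seed(cfg.seed, 0),
        wavelength_nm=cfg.wavelength_nm,
    )
    cal_set = simulate_calibration_set(acq, refs, shape=(cfg.height, cfg.width))
    mio.write_stack(outdir / "cal_B0.tif", cal_set.B0)
    cal_files = {"B0": "cal_B0.tif", "references": []}
    for i, (stack, ref) in enumerate(zip(cal_set.B_list, cal_set.references)):
        name = f"cal_ref{i}.tif"
        mio.write_stack(
            outdir / name,
            stack,
            extra={
                "reference": {
                    "kind": ref.kind,
                    "orientation_deg": ref.orientation_deg,
                    "retardance_deg": ref.retardance_deg,
                    "transmittance": ref.transmittance,
                }
            },
        )
        cal_files["references"].append(name)
    manifest["files"]["calibration"] = cal_files

    roi = cfg.resolve_roi((cfg.height, cfg.width))
    samples = []
    idx = 1
    for cond, ranges in cfg.conditions.items():
        for k in range(cfg.n_samples):
            seed = _item_seed(cfg.seed, idx)
            idx += 1
            scene = make_scene(
                cfg.height,
                cfg.width,
                delta=tuple(ranges.get("delta", (0.2, 0.4))),
                retardance=tuple(ranges.get("retardance", (5.0, 30.0))),
                length_scale=cfg.length_scale,
                seed=seed,
            )
            stack = simulate_acquisition(
                scene_to_mueller(scene),
                AcquisitionConfig(
                    photon_budget=cfg.photon_budget,
                    noise_model=cfg.noise_model,
                    seed=seed,
                    wavelength_nm=cfg.wavelength_nm,
                ),
            )
            name = f"sample_{cond}_{k}.tif"
            truth = {
                "condition": cond,
                "sample": k,
                "roi_delta_mean": float(scene.delta_map[roi.slices].mean()),
                "roi_retardance_mean": float(scene.retardance_map[roi.slices].mean()),
                "seed": seed,
            }
            mio.write_stack(outdir / name, stack, extra={"ground_truth": truth})
            samples.append({"file": name, **truth})
    manifest["files"]["samples"] = samples

    cscene = ContractionScene(
        shape=(cfg.height * 2, cfg.width * 2),
        day0_rect=(4, 4, cfg.width * 2 - 4, cfg.height * 2 - 4),
        day3_ellipse=(cfg.width, cfg.height, cfg.width * 0.45, cfg.height * 0.45),
        noise_sd=1.0 if cfg.noise_model != "none" else 0.0,
        seed=_item_seed(cfg.seed, 900),
    )
    day0, day3, ctruth = simulate_contraction_pair(cscene)
    import tifffile

    tifffile.imwrite(outdir / "contraction_day0.tif", day0.astype(np.float32))
    tifffile.imwrite(outdir / "contraction_day3.tif", day3.astype(np.float32))
    manifest["files"]["contraction"] = {
        "day0": "contraction_day0.tif",
        "day3": "contraction_day3.tif",
        "ground_truth": ctruth,
    }

    pseed = _item_seed(cfg.seed, 901)
    pscene = PshgScene(
        orientation_field=make_scene(
            cfg.height,
            cfg.width,
            retarder_axis=(10.0, 170.0),
            length_scale=cfg.length_scale,
            seed=pseed,
        ).retarder_axis_map,
        anisotropy=0.5,
        noise_model="poisson" if cfg.noise_model != "none" else "none",
        seed=pseed,
    )
    pstack, ptruth = simulate_pshg_stack(pscene)
    mio.write_pshg_stack(
        outdir / "pshg.tif",
        pstack,
        extra={"ground_truth_orientation_mean": float(ptruth["orientation_deg"].mean())},
    )
    manifest["files"]["pshg"] = "pshg.tif"

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("simulated dataset written to %s", outdir)
    return manifest


# ---------------------------------------------------------------------------
# analysis side


def run_full(cfg: PipelineConfig, data_dir, outdir) -> dict:
    """Analyze a simulated (or equivalently structured) dataset end to end."""
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {data_dir}")
    manifest = json.loads(manifest_path.read_text())

    report: dict = {"config_hash": cfg.digest(), "stages": {}}

    # --- calibration
    cal_info = manifest["files"].get("calibration")
    if not cal_info:
        raise FileNotFoundError("manifest lists no calibration stacks")
    b0 = mio.read_stack(data_dir / cal_info["B0"])
    b_stacks, refs = [], []
    from .calibration import ReferenceOptic

    for name in cal_info["references"]:
        stack = mio.read_stack(data_dir / name)
        b_stacks.append(stack)
        r = stack.meta.get("reference")
        refs.append(
            ReferenceOptic(
                kind=r["kind"],
                orientation_deg=r["orientation_deg"],
                retardance_deg=r["retardance_deg"],
                transmittance=r.get("transmittance", 1.0),
            )
        )
    log.info("calibrating (%s mode, %d references)", cfg.calibration_mode, len(refs))
    cal = calibrate_field(b0, b_stacks, refs, mode=cfg.calibration_mode)
    mio.write_calibration(outdir / "calibration.npz", cal)
    report["stages"]["calibration"] = {
        "mode": cfg.calibration_mode,
        "residual": float(np.nanmean(np.asarray(cal.residual))),
    }

    # --- per-sample reconstruction, decomposition, ROI statistics
    rows = []
    for entry in manifest["files"]["samples"]:
        stack = mio.read_stack(data_dir / entry["file"])
        mm = reconstruct(stack, cal)
        dec = decompose_map(mm)
        roi = cfg.resolve_roi(mm.shape)
        d_stats = roi_stats(
            dec.delta, roi, bins=cfg.delta_bins, value_range=(0.0, 1.0), mask=dec.mask
        )
        r_stats = roi_stats(
            dec.retardance,
            roi,
            bins=cfg.retardance_bins,
            value_range=(0.0, 180.0),
            mask=dec.mask,
        )
        stem = Path(entry["file"]).stem
        mio.write_decomposition(outdir / f"{stem}_maps.tif", dec)
        rows.append(
            {
                "condition": entry["condition"],
                "sample": entry["sample"],
                "delta_mu": d_stats.mu,
                "delta_sigma": d_stats.sigma,
                "retardance_mu": r_stats.mu,
                "retardance_sigma": r_stats.sigma,
                "n_valid_pixels": d_stats.n_pixels,
                "clamp_count": dec.clamp_count,
            }
        )
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(outdir / "sample_stats.csv", index=False)
    report["stages"]["samples"] = rows

    # --- group comparison on per-sample means
    by_cond = stats_df.groupby("condition")
    comparisons = {}
    if by_cond.ngroups >= 2 and (by_cond.size() >= 2).all():
        for param in ("delta_mu", "retardance_mu"):
            gc = group_compare(
                {c: g[param].tolist() for c, g in by_cond}, alpha=cfg.alpha
            )
            comparisons[param] = {
                "group_means": gc.group_means,
                "F": gc.F_stat,
                "p": gc.p_anova,
                "tukey": gc.tukey_pairs,
            }
    report["stages"]["group_comparison"] = comparisons

    # --- contraction assay
    contraction = manifest["files"].get("contraction")
    if contraction:
        import tifffile

        day0 = tifffile.imread(data_dir / contraction["day0"]).astype(float)
        day3 = tifffile.imread(data_dir / contraction["day3"]).astype(float)
        metrics = analyze_contraction(day0, day3)
        report["stages"]["contraction"] = {
            "retraction_index": metrics.retraction_index,
            "attenuation_coefficient": metrics.attenuation_coefficient,
            "mode": metrics.mode,
        }

    # --- pSHG orientation statistics
    pshg_file = manifest["files"].get("pshg")
    if pshg_file:
        pstack = mio.read_pshg_stack(data_dir / pshg_file)
        omap = fit_orientation(pstack)
        if omap.valid.any():
            dist = orientation_histogram(omap)
            report["stages"]["pshg"] = {
                "n_valid": int(omap.valid.sum()),
                "entropy_S": entropy(dist),
                "circular_variance_CV": circular_variance(dist),
            }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("analysis report written to %s", outdir / "report.json")
    return report
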