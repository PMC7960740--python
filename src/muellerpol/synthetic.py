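"""Synthetic scenes and forward-modeled acquisitions with known ground truth.

Everything the pipeline consumes can be generated here: smooth per-pixel
fields of depolarization / retardance / diattenuation pushed through the
polarimetric forward model B = A.M.W with photon noise, calibration
acquisitions with reference optics, bright-field images of a contracting
gel, and polarization-resolved SHG stacks with a prescribed fiber
orientation field.  All generators are bit-reproducible under a fixed
seed.

Ground-truth Mueller matrices are composed in the polar-decomposition
forward order M = m11 . M_delta . M_R . M_D, so the downstream
decomposition recovers the generating parameters exactly by construction
(other composition orders exist; this one is deliberate and documented).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import ReferenceOptic
from .mueller import IntensityStack, MuellerMap, _diattenuator_from_vector
from .optics import default_psa_matrix, default_psg_matrix
from .pshg import PSHGStack

__all__ = [
    "GroundTruthScene",
    "AcquisitionConfig",
    "ContractionScene",
    "PshgScene",
    "CalibrationSet",
    "make_scene",
    "scene_to_mueller",
    "simulate_acquisition",
    "simulate_calibration_set",
    "simulate_contraction_pair",
    "simulate_pshg_stack",
]


# ---------------------------------------------------------------------------
# scene containers


@dataclass
class GroundTruthScene:
    """Per-pixel ground-truth polarimetric fields.

    delta_map in [0, 1); retardance_map in degrees [0, 180);
    retarder_axis_map in degrees [0, 180); diattenuation_map in [0, 1);
    m11_map strictly positive (arbitrary intensity units).
    """

    delta_map: np.ndarray
    retardance_map: np.ndarray
    retarder_axis_map: np.ndarray
    diattenuation_map: np.ndarray
    m11_map: np.ndarray
    diatt_axis_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        maps = [
            self.delta_map,
            self.retardance_map,
            self.retarder_axis_map,
            self.diattenuation_map,
            self.m11_map,
        ]
        maps = [np.asarray(m, dtype=float) for m in maps]
        (
            self.delta_map,
            self.retardance_map,
            self.retarder_axis_map,
            self.diattenuation_map,
            self.m11_map,
        ) = maps
        shape = maps[0].shape
        if any(m.shape != shape for m in maps):
            raise ValueError("all scene maps must share the same shape")
        if self.diatt_axis_map is None:
            self.diatt_axis_map = np.zeros(shape)
        else:
            self.diatt_axis_map = np.asarray(self.diatt_axis_map, dtype=float)
            if self.diatt_axis_map.shape != shape:
                raise ValueError("all scene maps must share the same shape")
        if np.any((self.delta_map < 0) | (self.delta_map >= 1)):
            raise ValueError("delta_map must lie in [0, 1)")
        if np.any((self.retardance_map < 0) | (self.retardance_map >= 180)):
            raise ValueError("retardance_map must lie in [0, 180) degrees")
        if np.any((self.diattenuation_map < 0) | (self.diattenuation_map >= 1)):
            raise ValueError("diattenuation_map must lie in [0, 1)")
        if np.any(self.m11_map <= 0):
            raise ValueError("m11_map must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta_map.shape


@dataclass
class AcquisitionConfig:
    """Instrument truth for the forward model B = A.M.W.

    ``photon_budget`` is the expected detector count per frame at m11 = 1
    for a unit forward coefficient; the default 10,000 counts puts the
    synthetic shot-noise floor near a real imager's depolarization /
    retardance noise level.
    """

    W_true: np.ndarray = field(default_factory=default_psg_matrix)
    A_true: np.ndarray = field(default_factory=default_psa_matrix)
    photon_budget: float = 10_000.0
    noise_model: str = "poisson"  # none | poisson | gaussian
    seed: int = 0
    wavelength_nm: float = 550.0

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.A_true = np.asarray(self.A_true, dtype=float)
        for name, m in (("W_true", self.W_true), ("A_true", self.A_true)):
            if m.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4")
            if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
                raise ValueError(f"{name} must be invertible")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class ContractionScene:
    """A bright-field contraction-assay pair: rectangle at day 0, ellipse at day 3."""

    shape: tuple[int, int]  # (H, W)
    day0_rect: tuple[int, int, int, int]  # x0, y0, x1, y1 (half-open)
    day3_ellipse: tuple[float, float, float, float]  # cx, cy, semi_x, semi_y
    sample_intensity: float = 80.0
    day3_sample_intensity: float | None = None  # default: sample_intensity
    background_intensity: float = 200.0
    noise_sd: float = 0.0
    max_grey: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.day0_rect
        if not (x1 > x0 and y1 > y0):
            raise ValueError("day0_rect must have positive extent")
        h, w = self.shape
        if not (0 <= x0 and x1 <= w and 0 <= y0 and y1 <= h):
            raise ValueError("day0_rect must lie inside the image")
        cx, cy, sx, sy = self.day3_ellipse
        if sx <= 0 or sy <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not (x0 <= cx - sx and cx + sx <= x1 and y0 <= cy - sy and cy + sy <= y1):
            raise ValueError("day3 ellipse must lie inside day0_rect")
        if self.day3_sample_intensity is None:
            self.day3_sample_intensity = self.sample_intensity
        for name in ("sample_intensity", "day3_sample_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= self.max_grey:
                raise ValueError(f"{name} must lie in [0, {self.max_grey}]")


@dataclass
class PshgScene:
    """Fiber-orientation ground truth for a polarization-resolved SHG stack."""

    orientation_field: np.ndarray  # degrees in [0, 180)
    anisotropy: np.ndarray | float = 0.5  # 2-theta modulation depth in [0, 1]
    excitation_angles_deg: np.ndarray = field(
        default_factory=lambda: np.arange(18) * 10.0
    )
    baseline: float = 1000.0
    fourth_harmonic: float = 0.0  # optional 4-theta modulation depth
    noise_model: str = "none"  # none | poisson
    seed: int = 0

    def __post_init__(self) -> None:
        self.orientation_field = np.asarray(self.orientation_field, dtype=float)
        self.excitation_angles_deg = np.asarray(self.excitation_angles_deg, dtype=float)
        a = np.asarray(self.anisotropy, dtype=float)
        if np.any((a < 0) | (a > 1)):
            raise ValueError("anisotropy must lie in [0, 1] (negative intensities)")
        self.anisotropy = a
        ang = self.excitation_angles_deg
        if np.any(np.diff(ang) <= 0) or ang[0] < 0 or ang[-1] >= 180:
            raise ValueError("excitation angles must strictly increase within [0, 180)")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass
class CalibrationSet:
    """Simulated calibration acquisitions with their ground truth."""

    B0: IntensityStack
    B_list: list[IntensityStack]
    references: list[ReferenceOptic]
    M_true: list[np.ndarray]
    cfg: AcquisitionConfig


# ---------------------------------------------------------------------------
# smooth random fields


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    lo: float,
    hi: float,
    length_scale: float,
) -> np.ndarray:
    """Seeded white noise blurred to ``length_scale`` px, mapped into (lo, hi).

    The blurred field is standardized and squashed, so the output mean sits
    near the interval midpoint and the full (lo, hi) range is used at any
    length scale; larger length scales give smoother fields, not flatter
    ones.
    """
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=length_scale, mode="reflect")
    sd = f.std()
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    if sd < 1e-12 or half == 0.0:
        return np.full(shape, center)
    z = np.clip((f - f.mean()) / (3.0 * sd), -1.0, 1.0)
    # keep strictly inside open-ended ranges such as [0, 1)
    return center + 0.999 * half * z


def _as_field(
    rng: np.random.Generator,
    value,
    shape: tuple[int, int],
    length_scale: float,
) -> np.ndarray:
    """Scalar -> constant field; (lo, hi) -> smooth random field."""
    if np.isscalar(value):
        return np.full(shape, float(value))
    lo, hi = value
    return _smooth_field(rng, shape, float(lo), float(hi), length_scale)


def make_scene(
    height: int,
    width: int,
    *,
    delta=(0.1, 0.6),
    retardance=(5.0, 60.0),
    retarder_axis=(0.0, 179.0),
    diattenuation=0.0,
    m11=1.0,
    length_scale: float = 20.0,
    seed: int = 0,
) -> GroundTruthScene:
    """Build a ground-truth scene of smooth (or constant) polarimetric fields.

    Each field parameter is either a scalar (constant-field mode) or a
    ``(lo, hi)`` range filled with seeded low-pass-filtered noise of
    correlation length ``length_scale`` pixels, emulating a spatially
    heterogeneous sample.
    """
    if height < 8 or width < 8:
        raise ValueError("scene must be at least 8x8 pixels")
    rng = np.random.default_rng(seed)
    shape = (height, width)
    return GroundTruthScene(
        delta_map=_as_field(rng, delta, shape, length_scale),
        retardance_map=_as_field(rng, retardance, shape, length_scale),
        retarder_axis_map=_as_field(rng, retarder_axis, shape, length_scale),
        diattenuation_map=_as_field(rng, diattenuation, shape, length_scale),
        m11_map=_as_field(rng, m11, shape, length_scale),
    )


# ---------------------------------------------------------------------------
# forward model


def _retarder_batch(ret_deg: np.ndarray, axis_deg: np.ndarray) -> np.ndarray:
    """Canonical linear retarder matrices for fields of phase and azimuth."""
    d = np.deg2rad(ret_deg)
    cd, sd = np.cos(d), np.sin(d)
    c = np.cos(2 * np.deg2rad(axis_deg))
    s = np.sin(2 * np.deg2rad(axis_deg))
    out = np.zeros(np.shape(ret_deg) + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 1, 1] = c * c + s * s * cd
    out[..., 1, 2] = c * s * (1 - cd)
    out[..., 1, 3] = s * sd
    out[..., 2, 1] = c * s * (1 - cd)
    out[..., 2, 2] = s * s + c * c * cd
    out[..., 2, 3] = -c * sd
    out[..., 3, 1] = -s * sd
    out[..., 3, 2] = c * sd
    out[..., 3, 3] = cd
    return out


def scene_to_mueller(scene: GroundTruthScene) -> MuellerMap:
    """Compose per-pixel M = m11 . M_delta . M_R . M_D from the scene fields."""
    k = 1.0 - scene.delta_map
    m_delta = np.zeros(scene.shape + (4, 4))
    m_delta[..., 0, 0] = 1.0
    for i in (1, 2, 3):
        m_delta[..., i, i] = k
    m_r = _retarder_batch(scene.retardance_map, scene.retarder_axis_map)
    two_ax = 2 * np.deg2rad(scene.diatt_axis_map)
    dvec = scene.diattenuation_map[..., None] * np.stack(
        [np.cos(two_ax), np.sin(two_ax), np.zeros(scene.shape)], axis=-1
    )
    m_d = _diattenuator_from_vector(dvec)
    matrices = m_delta @ m_r @ m_d
    return MuellerMap(matrices=matrices, m11=scene.m11_map.copy())


def _apply_noise(
    noiseless: np.ndarray, noise_model: str, rng: np.random.Generator
) -> np.ndarray:
    if noise_model == "none":
        return noiseless
    clipped = np.clip(noiseless, 0.0, None)
    if noise_model == "poisson":
        return rng.poisson(clipped).astype(float)
    if noise_model == "gaussian":
        return clipped + rng.normal(0.0, np.sqrt(clipped))
    raise ValueError(f"unknown noise model {noise_model!r}")


def _forward_frames(
    matrices: np.ndarray, m11: np.ndarray, cfg: AcquisitionConfig
) -> np.ndarray:
    """Noiseless (16, H, W) frames: budget * [A . (m11 M) . W]_{ji} at k = 4i+j."""
    b = cfg.photon_budget * (
        cfg.A_true @ (m11[..., None, None] * matrices) @ cfg.W_true
    )
    neg = b < -1e-9 * max(cfg.photon_budget, 1.0)
    if np.any(neg):
        yx = np.argwhere(neg.any(axis=(-2, -1)))[0]
        j, i = np.argwhere(neg[tuple(yx)])[0]
        raise ValueError(
            f"negative noiseless intensity at pixel (y={yx[0]}, x={yx[1]}), "
            f"PSG state {i}, PSA state {j}: unphysical W/A/M combination"
        )
    h, w = b.shape[:2]
    return np.transpose(b, (3, 2, 0, 1)).reshape(16, h, w)


def simulate_acquisition(
    mueller: MuellerMap, cfg: AcquisitionConfig
) -> IntensityStack:
    """Push a Mueller map through B = A.M.W and apply detector noise."""
    rng = np.random.default_rng(cfg.seed)
    frames = _apply_noise(
        _forward_frames(mueller.matrices, mueller.m11, cfg), cfg.noise_model, rng
    )
    return IntensityStack(
        frames=frames,
        wavelength_nm=cfg.wavelength_nm,
        meta={"photon_budget": cfg.photon_budget, "noise_model": cfg.noise_model,
              "seed": cfg.seed},
    )


def simulate_calibration_set(
    cfg: AcquisitionConfig,
    references: list[ReferenceOptic] | None = None,
    shape: tuple[int, int] = (8, 8),
) -> CalibrationSet:
    """Simulate the neutral-plate stack B0 = A.W and one stack per reference.

    The plate is polarimetrically neutral (M ~ I).  Ground-truth reference
    matrices are returned alongside the stacks.  An empty reference list
    yields only B0.
    """
    if references is None:
        references = []
    rng = np.random.default_rng(cfg.seed)
    h, w = shape
    ident = np.broadcast_to(np.eye(4), (h, w, 4, 4))
    ones = np.ones((h, w))

    def stack_for(M_field: np.ndarray) -> IntensityStack:
        frames = _apply_noise(_forward_frames(M_field, ones, cfg), cfg.noise_model, rng)
        return IntensityStack(frames=frames, wavelength_nm=cfg.wavelength_nm)

    B0 = stack_for(ident)
    m_true = [ref.mueller() for ref in references]
    B_list = [stack_for(np.broadcast_to(M, (h, w, 4, 4))) for M in m_true]
    return CalibrationSet(
        B0=B0, B_list=B_list, references=list(references), M_true=m_true, cfg=cfg
    )


# ---------------------------------------------------------------------------
# contraction assay imagery


def _ellipse_mask(shape, cx, cy, sx, sy) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2 <= 1.0


def simulate_contraction_pair(scene: ContractionScene):
    """Render the day-0 / day-3 bright-field pair with analytic ground truth.

    Returns ``(day0, day3, truth)`` where ``truth`` carries the exact
    area ratio (ellipse over rectangle) and the day-3 sample-to-background
    intensity ratio.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.shape
    x0, y0, x1, y1 = scene.day0_rect
    cx, cy, sx, sy = scene.day3_ellipse

    day0 = np.full((h, w), scene.background_intensity)
    day0[y0:y1, x0:x1] = scene.sample_intensity
    day3 = np.full((h, w), scene.background_intensity)
    day3[_ellipse_mask((h, w), cx, cy, sx, sy)] = scene.day3_sample_intensity

    if scene.noise_sd > 0:
        day0 = day0 + rng.normal(0.0, scene.noise_sd, (h, w))
        day3 = day3 + rng.normal(0.0, scene.noise_sd, (h, w))
        day0 = np.clip(day0, 0.0, scene.max_grey)
        day3 = np.clip(day3, 0.0, scene.max_grey)

    rect_area = float((x1 - x0) * (y1 - y0))
    truth = {
        "day0_area_px": rect_area,
        "ellipse_area_px": float(np.pi * sx * sy),
        "area_ratio": float(np.pi * sx * sy / rect_area),
        "intensity_ratio": float(
            scene.day3_sample_intensity / scene.background_intensity
        ),
    }
    return day0, day3, truth


# ---------------------------------------------------------------------------
# polarization-resolved SHG


def simulate_pshg_stack(scene: PshgScene):
    """Render I(theta) = baseline (1 + a cos 2(theta - phi) + a4 cos 4(theta - phi)).

    Returns ``(stack, truth)`` with the ground-truth orientation field in
    ``truth["orientation_deg"]``.
    """
    rng = np.random.default_rng(scene.seed)
    phi = np.deg2rad(scene.orientation_field)
    theta = np.deg2rad(scene.excitation_angles_deg)[:, None, None]
    a = np.broadcast_to(scene.anisotropy, scene.orientation_field.shape)
    frames = scene.baseline * (
        1.0
        + a * np.cos(2.0 * (theta - phi))
        + scene.fourth_harmonic * np.cos(4.0 * (theta - phi))
    )
    if scene.noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    stack = PSHGStack(
        frames=frames, excitation_angles_deg=scene.excitation_angles_deg.copy()
    )
    truth = {"orientation_deg": scene.orientation_field.copy()}
    return stack, truth
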