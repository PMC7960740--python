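"""Polarization-resolved SHG processing: orientation maps and their statistics.

A pSHG acquisition records the second-harmonic intensity at a set of
linear excitation-polarization angles (18 angles regularly spaced over
[0, 180) in the standard protocol).  Per pixel the modulation

    I(theta) = a0 + a2 cos(2 (theta - phi)) + a4 cos(4 (theta - phi))

is fitted by linear least squares on the trigonometric basis
{1, cos 2theta, sin 2theta, cos 4theta, sin 4theta}; the fiber azimuth
phi comes from the phase of the 2-theta harmonic, folded into [0, 180)
(fiber-axis symmetry).  Pixels with a poor fit (R^2 at or below a 0.5
threshold by default) are masked out.

The orientation distribution p_theta over 180 one-degree bins yields two
summary statistics, both 0 for a single orientation and 1 for no
preferred orientation:

    S  = -(1 / ln 180) sum p_theta ln p_theta      (normalized entropy)
    CV = 1 - | sum p_theta e^{2 i theta} |         (circular variance)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = [
    "PSHGStack",
    "OrientationMap",
    "OrientationDistribution",
    "mean_image",
    "fit_orientation",
    "orientation_histogram",
    "entropy",
    "circular_variance",
    "render_hsv",
]

N_BINS = 180


@dataclass
class PSHGStack:
    """An excitation-angle-resolved SHG image stack, one frame per angle."""

    frames: np.ndarray  # (n_angles, H, W)
    excitation_angles_deg: np.ndarray
    pixel_size_nm: float = 170.0
    binning: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.excitation_angles_deg = np.asarray(self.excitation_angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_angles, H, W)")
        if len(self.excitation_angles_deg) != self.frames.shape[0]:
            raise ValueError("one frame per excitation angle required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class OrientationMap:
    """Per-pixel fiber azimuth with the harmonic-fit quality mask."""

    orientation: np.ndarray  # degrees in [0, 180), NaN where invalid
    r_squared: np.ndarray
    valid: np.ndarray
    r2_threshold: float = 0.5


@dataclass
class OrientationDistribution:
    """Proportions p_theta over 180 one-degree orientation bins."""

    p_theta: np.ndarray
    bin_edges_deg: np.ndarray = field(
        default_factory=lambda: np.arange(N_BINS + 1, dtype=float)
    )

    def __post_init__(self) -> None:
        self.p_theta = np.asarray(self.p_theta, dtype=float)
        if self.p_theta.shape != (N_BINS,):
            raise ValueError(f"p_theta must have {N_BINS} bins")
        if np.any(self.p_theta < 0) or not np.isclose(self.p_theta.sum(), 1.0):
            raise ValueError("p_theta must be nonnegative and sum to 1")

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])


def _block_bin(image: np.ndarray, factor: int) -> np.ndarray:
    h, w = image.shape[-2:]
    h2, w2 = h - h % factor, w - w % factor
    trimmed = image[..., :h2, :w2]
    shape = trimmed.shape[:-2] + (h2 // factor, factor, w2 // factor, factor)
    return trimmed.reshape(shape).mean(axis=(-3, -1))


def mean_image(stack: PSHGStack, binning: int | None = None) -> np.ndarray:
    """Average over all excitation polarizations, optionally block-binned.

    Averaging over the full angle set cancels any dependence on the
    excitation polarization orientation.
    """
    frames = stack.frames
    if binning is None:
        binning = stack.binning
    if binning > 1:
        frames = _block_bin(frames, binning)
    return frames.mean(axis=0)


def fit_orientation(stack: PSHGStack, r2_threshold: float = 0.5) -> OrientationMap:
    """Fit the 2-theta / 4-theta harmonic model per pixel, closed form.

    Requires at least six distinct excitation angles (five basis
    functions).  Constant pixel traces get R^2 = 0 and are masked invalid
    rather than raising.
    """
    angles = np.deg2rad(stack.excitation_angles_deg)
    if len(np.unique(angles)) < 6:
        raise ValueError("at least six distinct excitation angles are required")
    X = np.column_stack(
        [
            np.ones_like(angles),
            np.cos(2 * angles),
            np.sin(2 * angles),
            np.cos(4 * angles),
            np.sin(4 * angles),
        ]
    )
    n, h, w = stack.frames.shape
    y = stack.frames.reshape(n, -1)
    coef = np.linalg.pinv(X) @ y  # (5, H*W)
    resid = y - X @ coef
    ss_res = np.einsum("ij,ij->j", resid, resid)
    ss_tot = np.einsum("ij,ij->j", y - y.mean(axis=0), y - y.mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    r2 = np.clip(r2, 0.0, 1.0).reshape(h, w)

    phi = 0.5 * np.degrees(np.arctan2(coef[2], coef[1])) % 180.0
    phi = phi.reshape(h, w)
    valid = r2 > r2_threshold
    orientation = np.where(valid, phi, np.nan)
    return OrientationMap(
        orientation=orientation, r_squared=r2, valid=valid, r2_threshold=r2_threshold
    )


def orientation_histogram(omap: OrientationMap) -> OrientationDistribution:
    """p_theta over 180 one-degree bins from the valid pixels only."""
    vals = omap.orientation[omap.valid]
    if vals.size == 0:
        raise ValueError("no valid pixels to histogram")
    counts, edges = np.histogram(vals, bins=N_BINS, range=(0.0, 180.0))
    return OrientationDistribution(
        p_theta=counts / counts.sum(), bin_edges_deg=edges
    )


def entropy(dist: OrientationDistribution) -> float:
    """Normalized entropy S = -(1/ln 180) sum p ln p, with 0 ln 0 = 0."""
    p = dist.p_theta[dist.p_theta > 0]
    # + 0.0 normalizes the -0.0 produced by a single-bin distribution
    return float(-(p * np.log(p)).sum() / np.log(N_BINS) + 0.0)


def circular_variance(dist: OrientationDistribution) -> float:
    """CV = 1 - |sum p_theta e^{2 i theta}|, theta at bin centers in radians."""
    theta = np.deg2rad(dist.bin_centers_deg)
    resultant = np.abs(np.sum(dist.p_theta * np.exp(2j * theta)))
    return float(1.0 - resultant)


def render_hsv(omap: OrientationMap) -> np.ndarray:
    """Orientation as hue at full brightness on valid pixels, black elsewhere."""
    h = np.where(omap.valid, omap.orientation, 0.0) / 180.0
    s = np.ones_like(h)
    v = omap.valid.astype(float)
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))
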