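"""Gel-contraction metrics, ROI statistics, and group comparisons.

The contraction assay quantifies how strongly embedded cells remodel a
collagen hydrogel over days of free-floating culture: the *retraction
index* is the gel's projected area at day 3 over its initial area at day
0, and the *attenuation coefficient* compares the mean transmitted
intensity over the contracted gel with the surrounding background.

Polarimetric maps are summarized over a central region of interest (far
from sample edges): mean mu, standard deviation sigma (a spatial
heterogeneity measure), and a histogram.  Per-sample means are compared
across experimental conditions by one-way ANOVA with Tukey's HSD post hoc
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ROI",
    "ContractionMetrics",
    "HistogramStats",
    "GroupComparison",
    "central_roi",
    "segment_gel",
    "retraction_index",
    "attenuation_coefficient",
    "analyze_contraction",
    "roi_stats",
    "group_compare",
]


@dataclass(frozen=True)
class ROI:
    """A rectangular region in 0-based, half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("ROI must have positive extent")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI must have nonnegative origin")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x1 > w or self.y1 > h:
            raise ValueError(f"ROI {self} exceeds image bounds {shape}")


def central_roi(shape: tuple[int, int], fraction: float = 0.5) -> ROI:
    """Centered rectangle covering ``fraction`` of each dimension.

    The default half-extent rectangle keeps the statistics away from
    sample edges.
    """
    h, w = shape
    dy, dx = int(round(h * fraction)), int(round(w * fraction))
    y0, x0 = (h - dy) // 2, (w - dx) // 2
    return ROI(x0=x0, y0=y0, x1=x0 + dx, y1=y0 + dy)


@dataclass
class ContractionMetrics:
    retraction_index: float
    attenuation_coefficient: float
    sample_mask: np.ndarray
    background_roi: ROI | None = None
    mode: str = "ratio"


@dataclass
class HistogramStats:
    """Histogram plus mean/SD of the pixel values inside an ROI."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mu: float
    sigma: float
    n_pixels: int


@dataclass
class GroupComparison:
    group_means: dict
    F_stat: float
    p_anova: float
    tukey_pairs: list  # (group_a, group_b, mean difference, adjusted p, reject)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_anova < self.alpha


# ---------------------------------------------------------------------------
# contraction assay


def segment_gel(
    day3_image: np.ndarray,
    polarity: str = "auto",
    closing_size: int = 3,
) -> np.ndarray:
    """Binary gel mask: Otsu threshold, 3x3 closing, largest component.

    ``polarity`` selects which side of the threshold is gel: ``"dark"``
    (transmitted light, gel darker than background -- also the ``"auto"``
    behavior), or ``"bright"``.
    """
    img = np.asarray(day3_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if np.ptp(img) == 0:
        raise ValueError("uniform image: no foreground to segment")
    t = threshold_otsu(img)
    if polarity in ("auto", "dark"):
        fg = img < t
    elif polarity == "bright":
        fg = img > t
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    fg = morphology.closing(fg, morphology.footprint_rectangle((closing_size, closing_size)))
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("empty foreground after morphology")
    largest = 1 + np.argmax(np.bincount(labels.ravel())[1:])
    return labels == largest


def retraction_index(day0_area: float, sample_mask: np.ndarray) -> float:
    """Contracted area over initial area: mask pixel count / day0 area."""
    if day0_area <= 0:
        raise ValueError("day0_area must be positive")
    area = int(np.count_nonzero(sample_mask))
    if area == 0:
        raise ValueError("sample mask is empty")
    return area / float(day0_area)


def attenuation_coefficient(
    day3_image: np.ndarray,
    sample_mask: np.ndarray,
    background_roi: ROI,
    mode: str = "ratio",
) -> float:
    """Mean transmitted intensity over the gel relative to the background.

    ``ratio`` is the literal definition mean(sample)/mean(background);
    ``inverse_ratio`` and ``neg_log`` are provided for users who want the
    value to grow with optical density.
    """
    img = np.asarray(day3_image, dtype=float)
    background_roi.validate_within(img.shape)
    bg_region = np.zeros(img.shape, dtype=bool)
    bg_region[background_roi.slices] = True
    if (bg_region & sample_mask).any():
        raise ValueError("background ROI overlaps the sample mask")
    sample_mean = img[sample_mask].mean()
    bg_mean = img[bg_region].mean()
    if bg_mean == 0:
        raise ValueError("background mean intensity is zero")
    ratio = sample_mean / bg_mean
    if mode == "ratio":
        return float(ratio)
    if mode == "inverse_ratio":
        return float(1.0 / ratio)
    if mode == "neg_log":
        return float(-np.log(ratio))
    raise ValueError(f"unknown mode {mode!r}")


def _auto_background_roi(shape: tuple[int, int], mask: np.ndarray) -> ROI:
    """A corner rectangle (10% of each dimension) clear of the sample."""
    h, w = shape
    dy, dx = max(h // 10, 2), max(w // 10, 2)
    for y0, x0 in ((0, 0), (0, w - dx), (h - dy, 0), (h - dy, w - dx)):
        roi = ROI(x0=x0, y0=y0, x1=x0 + dx, y1=y0 + dy)
        region = np.zeros(shape, dtype=bool)
        region[roi.slices] = True
        if not (region & mask).any():
            return roi
    raise ValueError("no sample-free corner found for the background ROI")


def analyze_contraction(
    day0_image: np.ndarray,
    day3_image: np.ndarray,
    background_roi: ROI | None = None,
    mode: str = "ratio",
    polarity: str = "auto",
    day0_mask: np.ndarray | None = None,
    day3_mask: np.ndarray | None = None,
) -> ContractionMetrics:
    """Full contraction-assay readout from a day-0 / day-3 image pair.

    Masks are segmented automatically unless provided (manual masks mirror
    the traditional FIJI workflow).
    """
    if day0_mask is None:
        day0_mask = segment_gel(day0_image, polarity=polarity)
    if day3_mask is None:
        day3_mask = segment_gel(day3_image, polarity=polarity)
    if background_roi is None:
        background_roi = _auto_background_roi(day3_mask.shape, day3_mask)
    ri = retraction_index(np.count_nonzero(day0_mask), day3_mask)
    att = attenuation_coefficient(day3_image, day3_mask, background_roi, mode=mode)
    return ContractionMetrics(
        retraction_index=ri,
        attenuation_coefficient=att,
        sample_mask=day3_mask,
        background_roi=background_roi,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# ROI statistics


def roi_stats(
    scalar_map: np.ndarray,
    roi: ROI,
    bins: int = 100,
    value_range: tuple[float, float] | None = None,
    mask: np.ndarray | None = None,
) -> HistogramStats:
    """Histogram, mean and SD of a scalar map inside an ROI.

    Masked or NaN pixels are excluded; sigma is the population SD, the
    spatial-heterogeneity measure.  Values outside ``value_range`` are
    clipped into the outer bins so the counts conserve the pixel count.
    """
    m = np.asarray(scalar_map, dtype=float)
    roi.validate_within(m.shape)
    vals = m[roi.slices]
    keep = np.isfinite(vals)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)[roi.slices]
    vals = vals[keep]
    if vals.size == 0:
        raise ValueError("ROI is fully masked")
    if value_range is None:
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            hi = lo + 1.0
        value_range = (lo, hi)
    clipped = np.clip(vals, value_range[0], value_range[1])
    counts, edges = np.histogram(clipped, bins=bins, range=value_range)
    return HistogramStats(
        bin_edges=edges,
        counts=counts,
        mu=float(vals.mean()),
        sigma=float(vals.std()),
        n_pixels=int(vals.size),
    )


# ---------------------------------------------------------------------------
# group statistics


def group_compare(samples: dict[str, list[float]], alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across conditions followed by Tukey's HSD post hoc test.

    ``samples`` maps condition name -> per-sample means (the per-sample
    mean, not pooled pixels, is the statistical unit).
    """
    if len(samples) < 2:
        raise ValueError("at least two groups are required")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    if any(g.size < 2 for g in groups.values()):
        raise ValueError("each group needs at least two samples")
    arrays = list(groups.values())
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if within_ss == 0:
        raise ValueError("zero within-group variance in all groups: F undefined")

    F, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(g) for k, g in groups.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    # statsmodels orders comparisons as combinations of the sorted groups
    combos = list(combinations(tk.groupsunique, 2))
    pairs = [
        (str(a), str(b), float(diff), float(padj), bool(rej))
        for (a, b), diff, padj, rej in zip(combos, tk.meandiffs, tk.pvalues, tk.reject)
    ]
    return GroupComparison(
        group_means={k: float(g.mean()) for k, g in groups.items()},
        F_stat=float(F),
        p_anova=float(p),
        tukey_pairs=pairs,
        alpha=alpha,
    )
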