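"""Specimen width tracking from grayscale video frames.

Each frame is binarized (Otsu threshold, small specks removed, interior
holes filled), the largest connected component is taken as the specimen, its
boundary pixels are split into four edge groups (left, right, top, bottom)
by the quadrant of their outward direction from the component centroid, and
the per-row span between the lateral edges gives a width profile whose
minimum -- the neck on a waisted specimen -- is reported in mm.  Extension
is the change of the top-to-bottom extent relative to the first frame.

A synthetic renderer produces silhouette frames of an incompressibly
stretched rectangular specimen (length x lambda, width x lambda^-1/2) with
Gaussian pixel noise, carrying its ground-truth width in metadata, so the
tracker can be validated end to end.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .errors import SegmentationError
from .specimens import SpecimenGeometry

__all__ = [
    "FrameImage",
    "EdgeGroups",
    "WidthSeries",
    "binarize",
    "extract_edges",
    "track_width",
    "render_frame",
]


@dataclasses.dataclass
class FrameImage:
    """One grayscale frame with its physical pixel scale."""

    pixels: np.ndarray  # 2-D float intensities
    pixel_scale: float  # mm per pixel
    timestamp: float = 0.0
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("frame must be a non-empty 2-D array")
        if not self.pixel_scale > 0:
            raise ValueError("pixel scale must be positive")


@dataclasses.dataclass
class EdgeGroups:
    """Boundary pixels of the specimen split into the four edges.

    Each group is an (n, 2) integer array of (row, col) pixel coordinates.
    The groups are disjoint and together cover every boundary pixel.
    """

    left: np.ndarray
    right: np.ndarray
    top: np.ndarray
    bottom: np.ndarray

    def all_points(self) -> np.ndarray:
        return np.vstack([self.left, self.right, self.top, self.bottom])


@dataclasses.dataclass
class WidthSeries:
    """Per-frame minimum width and axial extension."""

    timestamps: np.ndarray  # s
    min_width: np.ndarray  # mm
    extension: np.ndarray  # mm, relative to the first frame


def binarize(
    frame: FrameImage,
    polarity: str = "bright",
    min_area: int = 64,
) -> np.ndarray:
    """Otsu-threshold the frame into a specimen mask.

    ``polarity`` says whether the specimen is brighter ("bright", the default
    for a lit specimen on a dark curtain) or darker ("dark") than the
    background; speckles below ``min_area`` pixels are removed and interior
    holes are filled.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    px = frame.pixels
    if np.ptp(px) < 1e-6:
        raise SegmentationError("uniform frame: no foreground/background contrast")
    thr = filters.threshold_otsu(px)
    mask = px > thr if polarity == "bright" else px < thr
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise SegmentationError("no specimen-sized foreground object found")
    return mask


def extract_edges(mask: np.ndarray) -> EdgeGroups:
    """Split the boundary of the largest component into four edge groups.

    A boundary pixel belongs to the left/right group if its centroid-relative
    offset, normalized by the component's bounding-box half extents, points
    mostly horizontally (ties go to the lateral groups), else top/bottom.
    For convex silhouettes the four groups exactly partition the boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise SegmentationError("mask has no foreground component")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    comp = labels == largest
    if comp.sum() < 4:
        raise SegmentationError("foreground component degenerate (< 4 pixels)")

    boundary = comp & ~ndimage.binary_erosion(comp, border_value=0)
    rows, cols = np.nonzero(boundary)
    r0, c0 = np.nonzero(comp)[0].mean(), np.nonzero(comp)[1].mean()
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    half_h = max((rmax - rmin) / 2.0, 0.5)
    half_w = max((cmax - cmin) / 2.0, 0.5)

    x = (cols - c0) / half_w
    y = (rows - r0) / half_h
    lateral = np.abs(x) >= np.abs(y)
    pts = np.column_stack([rows, cols])
    return EdgeGroups(
        left=pts[lateral & (x < 0)],
        right=pts[lateral & (x >= 0)],
        top=pts[~lateral & (y < 0)],
        bottom=pts[~lateral & (y >= 0)],
    )


def _frame_width_extent(frame: FrameImage, polarity: str, min_area: int):
    mask = binarize(frame, polarity=polarity, min_area=min_area)
    edges = extract_edges(mask)
    if edges.left.size == 0 or edges.right.size == 0:
        raise SegmentationError("missing lateral edges")
    # per-row span between lateral edges
    widths = {}
    for r, c in edges.left:
        widths.setdefault(r, [np.inf, -np.inf])
        widths[r][0] = min(widths[r][0], c)
    for r, c in edges.right:
        widths.setdefault(r, [np.inf, -np.inf])
        widths[r][1] = max(widths[r][1], c)
    spans = [
        hi - lo + 1 for lo, hi in widths.values() if np.isfinite(lo) and np.isfinite(hi)
    ]
    if not spans:
        raise SegmentationError("no row spanned by both lateral edges")
    all_rows = np.nonzero(mask.any(axis=1))[0]
    extent_px = all_rows.max() - all_rows.min() + 1
    return min(spans) * frame.pixel_scale, extent_px * frame.pixel_scale


def track_width(
    frames: Sequence[FrameImage],
    polarity: str = "bright",
    min_area: int = 64,
) -> WidthSeries:
    """Minimum width (mm) and axial extension per frame."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    widths, extents, times = [], [], []
    for i, frame in enumerate(frames):
        try:
            w, e = _frame_width_extent(frame, polarity, min_area)
        except SegmentationError as err:
            raise SegmentationError(f"frame {i}: {err}") from err
        widths.append(w)
        extents.append(e)
        times.append(frame.timestamp)
    extents = np.asarray(extents)
    return WidthSeries(
        timestamps=np.asarray(times),
        min_width=np.asarray(widths),
        extension=extents - extents[0],
    )


def render_frame(
    geometry: SpecimenGeometry,
    stretch: float = 1.0,
    pixel_scale: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    timestamp: float = 0.0,
    waist_fraction: float = 0.0,
) -> FrameImage:
    """Render a silhouette frame of the incompressibly stretched specimen.

    The gauge region is drawn as a bright rectangle (length x stretch,
    width x stretch^-1/2) on a dark background with additive Gaussian pixel
    noise.  ``waist_fraction`` > 0 narrows the middle rows to emulate
    necking.  Ground truth (width in px and mm) is stored in metadata.
    """
    if not stretch > 0:
        raise ValueError("stretch must be positive")
    lam = float(stretch)
    length_mm = geometry.gauge_length * lam
    width_mm = geometry.width / np.sqrt(lam)
    length_px = max(int(round(length_mm / pixel_scale)), 2)
    width_px = max(int(round(width_mm / pixel_scale)), 2)

    margin = max(int(0.25 * max(length_px, width_px)), 8)
    H = length_px + 2 * margin
    W = width_px + 2 * margin
    img = np.full((H, W), 0.15)
    r0, c0 = margin, margin
    img[r0 : r0 + length_px, c0 : c0 + width_px] = 0.85

    min_width_px = width_px
    if waist_fraction > 0:
        neck_px = max(int(round(width_px * (1.0 - waist_fraction))), 2)
        trim = (width_px - neck_px) // 2
        neck_px = width_px - 2 * trim
        rows = slice(r0 + length_px // 3, r0 + 2 * length_px // 3)
        img[rows, c0 : c0 + trim] = 0.15
        img[rows, c0 + width_px - trim : c0 + width_px] = 0.15
        min_width_px = neck_px

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return FrameImage(
        pixels=img,
        pixel_scale=pixel_scale,
        timestamp=timestamp,
        metadata={
            "true_width_px": min_width_px,
            "true_width_mm": min_width_px * pixel_scale,
            "true_length_px": length_px,
            "stretch": lam,
        },
    )
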