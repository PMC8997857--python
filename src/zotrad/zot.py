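"""Adaptive zone-of-transition (ZOT) detection from image gradients.

The tumour/parenchyma interface is treated as a transition band rather than
a curve.  Detection is a two-stage procedure:

1. **Border refinement** — the manual tumour ROI is coarsely dilated, and
   every manual-border pixel is relocated along the local gradient direction
   to the position of maximum gradient magnitude (the true edge); the
   relocated points are joined into a closed contour and filled.

2. **ZOT reconstruction** — at every refined-border pixel the gradient
   magnitude is profiled along the gradient direction and at ±45° to it.
   Such profiles are bell-shaped: maximal at the edge, falling off on both
   sides.  The transition extent on each side is the first strict local
   minimum (or the first sample at/below a noise floor) walking outward from
   the peak; profiles whose peak is below the floor, or that never come down
   on one side, are deemed undetectable.  The union of all detected
   min-to-min segments, closed morphologically at the scale of the median
   detected half-width, is the ZOT.  It crosses the refined border by
   construction and is anisotropic: wide where the image transition is
   gradual, thin where the edge is sharp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, map_coordinates
from skimage.draw import polygon
from skimage.morphology import closing as _closing, dilation as _dilation, disk
from skimage.segmentation import find_boundaries

from .io import PhaseImage, RoiMask

logger = logging.getLogger(__name__)

#: the three gradient-line offsets, degrees relative to the local gradient
LINE_OFFSETS_DEG = (0.0, 45.0, -45.0)


class ZOTUndetectableError(RuntimeError):
    """Raised when fewer than half of the border pixels yield a usable line."""


@dataclass
class ZotConfig:
    smoothing_sigma: float = 1.0     # px, Gaussian smoothing before gradients
    dilation_radius: int = 10        # px, coarse dilation of the manual ROI
    half_length: int = 15            # px, gradient-line half-length
    noise_floor_frac: float = 0.10   # fraction of the 95th pct border gradient
    min_detectable_fraction: float = 0.5


@dataclass
class GradientField:
    """Gradient magnitude and direction (radians, direction of max increase)."""

    magnitude: np.ndarray
    direction: np.ndarray


@dataclass
class GradientLine:
    """Gradient-magnitude profile through a border pixel."""

    border_pixel: tuple[int, int]
    angle_offset: float                 # degrees relative to local gradient
    samples: np.ndarray                 # ordered profile, unit-px steps
    center_idx: int                     # index of the border pixel
    step: tuple[float, float]           # (drow, dcol) unit step of the line
    truncated: bool = False             # line exited the image bounds
    left_min_idx: int | None = None
    right_min_idx: int | None = None

    @property
    def detectable(self) -> bool:
        return self.left_min_idx is not None and self.right_min_idx is not None


@dataclass
class ZOTRegion:
    """Anisotropic band of pixels crossing the refined tumour border."""

    support: np.ndarray
    inner_overlap: int
    outer_overlap: int
    source_slice: int = 0
    detect_fraction: float = 1.0
    half_widths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not self.support.any():
            raise ValueError("ZOT support is empty")
        if self.inner_overlap <= 0 or self.outer_overlap <= 0:
            raise ValueError("ZOT must cross the tumour border "
                             "(inner and outer overlap must be positive)")

    @property
    def area(self) -> int:
        return int(self.support.sum())


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def select_largest_slice(mask_3d: np.ndarray) -> int:
    """Index of the slice (last axis) with the largest in-slice mask area.

    Ties break toward the lowest index.  2-D input returns 0.
    """
    mask_3d = np.asarray(mask_3d) > 0
    if not mask_3d.any():
        raise ValueError("mask is empty")
    if mask_3d.ndim == 2:
        return 0
    areas = mask_3d.sum(axis=(0, 1))
    return int(np.argmax(areas))


def compute_gradient_field(image, smoothing_sigma: float = 1.0) -> GradientField:
    """Gradient magnitude/direction from Gaussian-smoothed central differences."""
    arr = image.voxels if isinstance(image, PhaseImage) else np.asarray(image, float)
    if arr.ndim != 2:
        raise ValueError("gradient field is computed on 2-D slices")
    if smoothing_sigma > 0:
        arr = gaussian_filter(arr, smoothing_sigma)
    gy, gx = np.gradient(arr)
    magnitude = np.hypot(gy, gx)
    direction = np.arctan2(gy, gx)
    return GradientField(magnitude, direction)


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    """(n, 2) array of inner-border pixel coordinates."""
    border = find_boundaries(mask, mode="inner")
    return np.argwhere(border)


def _sample_lines(magnitude: np.ndarray, starts: np.ndarray,
                  angles: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Bilinear profiles of ``magnitude`` along rays: (n_lines, len(t))."""
    drow = np.sin(angles)[:, None] * t[None, :]
    dcol = np.cos(angles)[:, None] * t[None, :]
    rows = starts[:, 0:1] + drow
    cols = starts[:, 1:2] + dcol
    vals = map_coordinates(magnitude, [rows.ravel(), cols.ravel()],
                           order=1, mode="nearest")
    return vals.reshape(len(starts), len(t)), rows, cols


# ---------------------------------------------------------------------------
# stage 1: border refinement
# ---------------------------------------------------------------------------

def refine_tumour_roi(image, manual_mask, dilation_radius: int = 10,
                      smoothing_sigma: float = 1.0) -> RoiMask:
    """Relocate each manual-border pixel to the local gradient maximum.

    Border pixels march along ± the local gradient direction inside the
    coarsely dilated manual ROI; the relocated points (sorted by angle about
    the mask centroid) are joined into a closed contour and filled.  The
    refined mask is always a subset of the dilated manual mask.  Degenerate
    inputs (no edges, empty or non-closed result) fall back to the manual
    mask with a logged warning.
    """
    if dilation_radius < 1:
        raise ValueError("dilation_radius must be >= 1")
    arr = image.voxels if isinstance(image, PhaseImage) else np.asarray(image, float)
    manual = np.asarray(
        manual_mask.support if isinstance(manual_mask, RoiMask) else manual_mask
    ) > 0
    if not manual.any():
        raise ValueError("manual mask is empty")

    field_ = compute_gradient_field(arr, smoothing_sigma)
    dilated = _dilation(manual, disk(dilation_radius))
    if field_.magnitude.max() <= 1e-12:
        logger.warning("refine_tumour_roi: image has no edges; "
                       "falling back to the manual mask")
        return RoiMask(manual.copy(), kind="refined")

    pts = _border_pixels(manual)
    angles = field_.direction[pts[:, 0], pts[:, 1]]
    t = np.arange(-dilation_radius, dilation_radius + 0.5, 0.5)
    vals, rows, cols = _sample_lines(field_.magnitude, pts.astype(float), angles, t)

    # restrict the search to the dilated band and to in-bounds samples
    band = map_coordinates(dilated.astype(float), [rows.ravel(), cols.ravel()],
                           order=0, mode="constant").reshape(vals.shape)
    inb = ((rows >= 0) & (rows <= arr.shape[0] - 1)
           & (cols >= 0) & (cols <= arr.shape[1] - 1))
    vals = np.where((band > 0.5) & inb, vals, -np.inf)
    best = np.argmax(vals, axis=1)
    no_edge = ~np.isfinite(vals[np.arange(len(pts)), best])
    center_idx = np.searchsorted(t, 0.0)
    best[no_edge] = center_idx

    new_r = pts[:, 0] + t[best] * np.sin(angles)
    new_c = pts[:, 1] + t[best] * np.cos(angles)

    cy, cx = np.argwhere(manual).mean(axis=0)
    order = np.argsort(np.arctan2(new_r - cy, new_c - cx))
    rr, cc = polygon(new_r[order], new_c[order], shape=arr.shape)
    refined = np.zeros_like(manual)
    refined[rr, cc] = True
    refined &= dilated
    if refined.sum() < 4:
        logger.warning("refine_tumour_roi: refinement degenerated; "
                       "falling back to the manual mask")
        return RoiMask(manual.copy(), kind="refined")
    return RoiMask(refined, kind="refined")


# ---------------------------------------------------------------------------
# stage 2: gradient-line analysis
# ---------------------------------------------------------------------------

def trace_gradient_lines(field: GradientField, border_pixel,
                         half_length: int = 15) -> list[GradientLine]:
    """Profiles at 0° and ±45° to the local gradient through one border pixel.

    Profiles are sampled by bilinear interpolation at unit-pixel steps and
    truncated (and flagged) where the line exits the image bounds.
    """
    if half_length < 2:
        raise ValueError("half_length must be >= 2 px")
    r0, c0 = border_pixel
    base = field.direction[int(round(r0)), int(round(c0))]
    H, W = field.magnitude.shape
    lines = []
    for off in LINE_OFFSETS_DEG:
        ang = base + np.deg2rad(off)
        step = (float(np.sin(ang)), float(np.cos(ang)))
        t = np.arange(-half_length, half_length + 1, dtype=float)
        rows = r0 + t * step[0]
        cols = c0 + t * step[1]
        inb = (rows >= 0) & (rows <= H - 1) & (cols >= 0) & (cols <= W - 1)
        # keep the contiguous in-bounds run containing the center
        center = half_length
        lo = center
        while lo - 1 >= 0 and inb[lo - 1]:
            lo -= 1
        hi = center
        while hi + 1 < len(t) and inb[hi + 1]:
            hi += 1
        truncated = lo > 0 or hi < len(t) - 1
        samples = map_coordinates(field.magnitude,
                                  [rows[lo:hi + 1], cols[lo:hi + 1]],
                                  order=1, mode="nearest")
        lines.append(GradientLine(
            border_pixel=(int(round(r0)), int(round(c0))),
            angle_offset=off, samples=samples, center_idx=center - lo,
            step=step, truncated=truncated))
    return lines


def find_transition_extent(line: GradientLine, noise_floor: float):
    """Locate the two transition-end minima of a bell-shaped gradient profile.

    Walking outward from the central peak, the extent on each side ends at
    the first strict interior local minimum, or at the first sample at or
    below ``noise_floor`` (the tail of a smooth edge profile decays without
    a strict minimum, so the floor marks where the transition has died out).
    The line is *reliably detectable* only if the central peak reaches the
    floor and both ends are found before the profile runs out.

    Returns ``(left_min_idx, right_min_idx)`` or ``None`` (undetectable);
    the indices are also stored on the line.
    """
    s = np.asarray(line.samples, dtype=float)
    n = len(s)
    if n < 5:
        return None

    # climb from the center to the local maximum (the edge peak)
    i = int(line.center_idx)
    moved = True
    while moved:
        moved = False
        if i + 1 < n and s[i + 1] > s[i]:
            i += 1
            moved = True
        elif i - 1 >= 0 and s[i - 1] > s[i]:
            i -= 1
            moved = True
    if i == 0 or i == n - 1 or s[i] < noise_floor or s[i] <= 0:
        return None

    def walk(start: int, stop: int, step: int):
        j = start
        while j != stop + step:
            if s[j] <= noise_floor:
                return j
            interior = 0 < j < n - 1
            if interior and s[j] < s[j - 1] and s[j] < s[j + 1]:
                return j
            j += step
        return None

    left = walk(i - 1, 0, -1)
    right = walk(i + 1, n - 1, +1)
    if left is None or right is None:
        return None
    line.left_min_idx, line.right_min_idx = int(left), int(right)
    return int(left), int(right)


def reconstruct_zot(lines: list[GradientLine], refined_mask: np.ndarray,
                    image_shape: tuple[int, int],
                    min_detectable_fraction: float = 0.5,
                    source_slice: int = 0) -> ZOTRegion:
    """Union of detected min-to-min segments, morphologically closed.

    ``lines`` must already carry transition extents (see
    :func:`find_transition_extent`).  Raises :class:`ZOTUndetectableError`
    when fewer than ``min_detectable_fraction`` of the border pixels have at
    least one detectable line.
    """
    refined_mask = np.asarray(refined_mask) > 0
    per_pixel: dict[tuple[int, int], bool] = {}
    for ln in lines:
        per_pixel.setdefault(ln.border_pixel, False)
        if ln.detectable:
            per_pixel[ln.border_pixel] = True
    if not per_pixel:
        raise ZOTUndetectableError("no gradient lines supplied")
    frac = sum(per_pixel.values()) / len(per_pixel)
    if frac < min_detectable_fraction:
        raise ZOTUndetectableError(
            f"ZOT undetectable: only {frac:.0%} of border pixels have a "
            f"detectable gradient transition (need "
            f">= {min_detectable_fraction:.0%})")

    support = np.zeros(image_shape, dtype=bool)
    half_widths = []
    for ln in lines:
        if not ln.detectable:
            continue
        r0, c0 = ln.border_pixel
        # paint the interior of the min-to-min segment: the minima mark where
        # the transition has died out and are not part of the zone itself
        lo = min(ln.left_min_idx + 1, ln.center_idx)
        hi = max(ln.right_min_idx - 1, ln.center_idx)
        tt = np.arange(lo, hi + 0.25, 0.5) - ln.center_idx
        rows = np.clip(np.round(r0 + tt * ln.step[0]).astype(int), 0, image_shape[0] - 1)
        cols = np.clip(np.round(c0 + tt * ln.step[1]).astype(int), 0, image_shape[1] - 1)
        support[rows, cols] = True
        half_widths.append((ln.right_min_idx - ln.left_min_idx) / 2.0)
    half_widths = np.asarray(half_widths, dtype=float)

    close_r = int(np.clip(round(float(np.median(half_widths))), 1, 10))
    # closing bridges tangential gaps left by undetectable pixels but must
    # not let the band reach farther from the border than the detected
    # transitions themselves
    border = find_boundaries(refined_mask, mode="inner")
    reach = None
    if border.any() and support.any():
        dist_border = distance_transform_edt(~border)
        reach = float(dist_border[support].max())
    support = _closing(support, disk(close_r))
    if reach is not None:
        support &= dist_border <= reach + 1.0

    inner = int(np.sum(support & refined_mask))
    outer = int(np.sum(support & ~refined_mask))
    tries = 0
    while (inner == 0 or outer == 0) and tries < 3:
        support = _dilation(support, disk(1))
        inner = int(np.sum(support & refined_mask))
        outer = int(np.sum(support & ~refined_mask))
        tries += 1
    return ZOTRegion(support, inner, outer, source_slice=source_slice,
                     detect_fraction=frac, half_widths=half_widths)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def detect_zot(image, manual_mask, config: ZotConfig | None = None):
    """Full two-stage ZOT detection on one slice of one phase.

    For a 3-D manual mask the slice with the largest tumour area is used.

    Returns
    -------
    (refined, zot, report)
        Refined tumour :class:`RoiMask`, the :class:`ZOTRegion`, and a dict
        of diagnostics (detectability fraction, thickness stats, fallbacks).
    """
    config = config or ZotConfig()
    arr = image.voxels if isinstance(image, PhaseImage) else np.asarray(image, float)
    manual = np.asarray(
        manual_mask.support if isinstance(manual_mask, RoiMask) else manual_mask
    ) > 0

    sl = 0
    if arr.ndim == 3:
        sl = select_largest_slice(manual)
        arr = arr[:, :, sl]
        manual = manual[:, :, sl]

    refined = refine_tumour_roi(arr, RoiMask(manual, kind="manual"),
                                dilation_radius=config.dilation_radius,
                                smoothing_sigma=config.smoothing_sigma)
    field_ = compute_gradient_field(arr, config.smoothing_sigma)

    pts = _border_pixels(refined.support)
    border_mags = field_.magnitude[pts[:, 0], pts[:, 1]]
    noise_floor = config.noise_floor_frac * float(np.percentile(border_mags, 95))
    if noise_floor <= 1e-12:
        raise ZOTUndetectableError(
            "ZOT undetectable: no gradient signal at the tumour border")

    lines: list[GradientLine] = []
    for p in pts:
        for ln in trace_gradient_lines(field_, tuple(p), config.half_length):
            find_transition_extent(ln, noise_floor)
            lines.append(ln)
    zot = reconstruct_zot(lines, refined.support, arr.shape,
                          config.min_detectable_fraction, source_slice=sl)
    widths = zot.half_widths * 2.0
    report = {
        "source_slice": sl,
        "noise_floor": noise_floor,
        "n_border_pixels": int(len(pts)),
        "detect_fraction": zot.detect_fraction,
        "zot_area": zot.area,
        "thickness_mean": float(widths.mean()) if widths.size else float("nan"),
        "thickness_median": float(np.median(widths)) if widths.size else float("nan"),
    }
    return refined, zot, report
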