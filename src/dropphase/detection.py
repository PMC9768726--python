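"""Droplet detection and quality-control filtering.

Trapped microdroplets appear as bright, high-contrast discs on a dark
background, so detection is segmentation-based and fully deterministic:
Otsu threshold on the detection channel, hole filling, connected-component
labelling, then a least-squares circle fit to each component's contour.
Circularity (4πA/P²), pairwise overlap and edge proximity drive the
keep/reject flags; droplets that are non-circular, overlapping, touching
another droplet or the image border are excluded from quantitative
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .io import ImageSet

FLAG_NON_CIRCULAR = "non_circular"
FLAG_OVERLAPPING = "overlapping"
FLAG_TOUCHING_EDGE = "touching_edge"
FLAG_LOW_CONTRAST = "low_contrast"


@dataclass
class DetectedDroplet:
    """A fitted circle with QC metrics; ``kept`` iff no flags are set."""

    droplet_id: int
    row: float
    col: float
    radius: float
    circularity: float
    flags: set = field(default_factory=set)
    mean_intensity: float = 0.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.circularity > 1.0:
            raise ValueError("circularity must be <= 1")

    @property
    def kept(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class DetectionParams:
    """Detection and QC thresholds.

    ``min_separation`` is the minimum allowed centre distance as a multiple
    of the radius sum; pairs closer than that are flagged overlapping.
    ``edge_margin`` (px) is the guard band from the image border.
    """

    radius_range: tuple[float, float] = (20.0, 80.0)
    min_circularity: float = 0.85
    min_separation: float = 1.05
    edge_margin: float = 2.0
    detection_channel: str = "sum"
    min_contrast: float = 1.2  # mean-in-circle / background ratio
    threshold_method: str = "robust"  # "robust" (median + k·MAD) or "otsu"
    noise_k: float = 6.0
    smooth_sigma: float = 1.0

    def __post_init__(self):
        if not self.radius_range[0] < self.radius_range[1]:
            raise ValueError("radius_range must satisfy min < max")
        if not 0 < self.min_circularity <= 1:
            raise ValueError("min_circularity must be in (0, 1]")
        if self.threshold_method not in ("robust", "otsu"):
            raise ValueError("threshold_method must be 'robust' or 'otsu'")


def _fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit to (row, col) points.

    Exact for points on a circle; for partial arcs (edge-truncated
    droplets) it extrapolates the underlying circle from the visible arc.
    """
    r = points[:, 0]
    c = points[:, 1]
    A = np.column_stack([2 * r, 2 * c, np.ones_like(r)])
    b = r**2 + c**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cr, cc, k = sol
    radius = math.sqrt(max(k + cr**2 + cc**2, 0.0))
    return float(cr), float(cc), float(radius)


def detect_droplets(images: ImageSet, params: DetectionParams) -> list[DetectedDroplet]:
    """Locate droplets as circles in the detection channel.

    Returns every circle candidate whose fitted radius lies in
    ``radius_range``, with circularity computed as 4πA/P² (Crofton
    perimeter, clamped at 1) and edge/contrast flags already set.  An empty
    or constant image yields an empty list.  Deterministic for fixed input.
    """
    img = np.asarray(images.channel(params.detection_channel), dtype=np.float64)
    if img.size == 0 or np.ptp(img) <= 0:
        return []
    smooth = (
        ndimage.gaussian_filter(img, params.smooth_sigma)
        if params.smooth_sigma > 0
        else img
    )
    if params.threshold_method == "otsu":
        thresh = threshold_otsu(smooth)
    else:
        # robust background floor: droplet brightness spans a wide range
        # along the composition ramp, so a bimodal (Otsu) split can land
        # between dim and bright droplets; the background median plus a
        # noise multiple keeps every droplet above threshold
        med = float(np.median(smooth))
        mad = float(np.median(np.abs(smooth - med)))
        thresh = med + params.noise_k * 1.4826 * mad
    mask = smooth > thresh
    if not mask.any() or mask.all():
        return []
    mask = ndimage.binary_fill_holes(mask)
    min_area = math.pi * params.radius_range[0] ** 2 * 0.25
    labels, _ = ndimage.label(mask)
    background_med = float(np.median(img[~mask])) if (~mask).any() else 0.0

    droplets: list[DetectedDroplet] = []
    next_id = 0
    for region in measure.regionprops(labels, intensity_image=img):
        if region.area < min_area:
            continue
        # all per-component work happens on a padded bounding-box crop
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(r0 - 2, 0), max(c0 - 2, 0)
        r1, c1 = min(r1 + 2, img.shape[0]), min(c1 + 2, img.shape[1])
        box = (slice(r0, r1), slice(c0, c1))
        comp_mask = _refine_component(
            labels[box] == region.label, smooth[box], background_med
        )
        row, col, radius, on_border = _fit_component_circle(
            comp_mask, (r0, c0), img.shape
        )
        if not params.radius_range[0] <= radius <= params.radius_range[1]:
            continue
        area = int(comp_mask.sum())
        perimeter = measure.perimeter_crofton(comp_mask, directions=4)
        circ = 1.0 if perimeter == 0 else min(
            4.0 * math.pi * area / perimeter**2, 1.0
        )
        flags = set()
        if _near_edge(row, col, radius, img.shape, params.edge_margin) or on_border:
            flags.add(FLAG_TOUCHING_EDGE)
        mean_in = float(region.intensity_mean)
        if background_med > 0 and mean_in < params.min_contrast * background_med:
            flags.add(FLAG_LOW_CONTRAST)
        droplets.append(
            DetectedDroplet(
                droplet_id=next_id,
                row=row,
                col=col,
                radius=radius,
                circularity=circ,
                flags=flags,
                mean_intensity=mean_in,
            )
        )
        next_id += 1
    return droplets


def _refine_component(comp_mask, smooth, background):
    """Re-threshold one component (bounding-box crop) at half maximum.

    The global threshold sits just above the background floor, so the mask
    boundary of a bright droplet lands where its smoothed edge tail crosses
    that floor — a brightness-dependent over-estimate of the radius.
    Re-thresholding at the midpoint between the component's interior median
    and the background puts the boundary at the 50% edge crossing, which for
    a symmetric edge profile is the true droplet rim.
    """
    interior = float(np.median(smooth[comp_mask]))
    if interior <= background:
        return comp_mask
    level = 0.5 * (interior + background)
    refined = comp_mask & (smooth > level)
    if not refined.any():
        return comp_mask
    lab, n = ndimage.label(refined)
    if n > 1:
        keep = np.argmax(ndimage.sum_labels(refined, lab, np.arange(1, n + 1))) + 1
        refined = lab == keep
    return ndimage.binary_fill_holes(refined)


def _fit_component_circle(comp_mask, offset, shape):
    """Circle fit on the component contour, ignoring image-border runs.

    ``comp_mask`` is a bounding-box crop whose top-left corner sits at
    ``offset`` in the full image of ``shape``.
    """
    padded = np.pad(comp_mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    pts = np.vstack(contours) - 1.0  # undo padding offset
    pts[:, 0] += offset[0]
    pts[:, 1] += offset[1]
    on_border = bool(
        (offset[0] == 0 and comp_mask[0, :].any())
        or (offset[0] + comp_mask.shape[0] >= shape[0] and comp_mask[-1, :].any())
        or (offset[1] == 0 and comp_mask[:, 0].any())
        or (offset[1] + comp_mask.shape[1] >= shape[1] and comp_mask[:, -1].any())
    )
    if on_border:
        interior = (
            (pts[:, 0] > 0.6)
            & (pts[:, 0] < shape[0] - 1.6)
            & (pts[:, 1] > 0.6)
            & (pts[:, 1] < shape[1] - 1.6)
        )
        if interior.sum() >= 6:
            pts = pts[interior]
    row, col, radius = _fit_circle(pts)
    return row, col, radius, on_border


def _near_edge(row, col, radius, shape, margin) -> bool:
    return (
        row - radius < margin
        or col - radius < margin
        or row + radius > shape[0] - margin
        or col + radius > shape[1] - margin
    )


def qc_filter(
    droplets: list[DetectedDroplet],
    params: DetectionParams,
    image_shape: tuple[int, int] | None = None,
) -> list[DetectedDroplet]:
    """Recompute QC flags: non-circular, overlapping, touching edge.

    Flags are recomputed from the stored metrics, so the operation is
    idempotent.  ``image_shape`` re-evaluates the edge criterion; when it is
    omitted, existing ``touching_edge`` flags are preserved.  The
    ``low_contrast`` flag set at detection time is always preserved.
    Returns new droplet objects; inputs are not mutated.
    """
    out = [
        replace(
            d,
            flags={
                f
                for f in d.flags
                if f in (FLAG_LOW_CONTRAST,)
                or (f == FLAG_TOUCHING_EDGE and image_shape is None)
            },
        )
        for d in droplets
    ]
    for d in out:
        if d.circularity < params.min_circularity:
            d.flags.add(FLAG_NON_CIRCULAR)
        if image_shape is not None and _near_edge(
            d.row, d.col, d.radius, image_shape, params.edge_margin
        ):
            d.flags.add(FLAG_TOUCHING_EDGE)
    for i in range(len(out)):
        for j in range(i + 1, len(out)):
            a, b = out[i], out[j]
            dist = math.hypot(a.row - b.row, a.col - b.col)
            if dist < params.min_separation * (a.radius + b.radius):
                a.flags.add(FLAG_OVERLAPPING)
                b.flags.add(FLAG_OVERLAPPING)
    return out


def droplet_volume(
    radius: float,
    pixel_size: float,
    model: str = "sphere",
    well_depth: float = 50.0,
) -> float:
    """Droplet volume in nL from the fitted radius.

    ``model="sphere"`` uses V = (π/6)·d³ with d = 2·radius·pixel_size
    (µm³ → nL with 1 nL = 10⁶ µm³).  ``model="cylinder"`` treats the
    droplet as a disc squashed into a trap well of depth ``well_depth`` µm
    (V = π·r²·h), which makes intensity-per-volume independent of droplet
    radius for focal-slice imaging.
    """
    if radius <= 0 or pixel_size <= 0:
        raise ValueError("radius and pixel_size must be positive")
    r_um = radius * pixel_size
    if model == "sphere":
        vol_um3 = (math.pi / 6.0) * (2.0 * r_um) ** 3
    elif model == "cylinder":
        if well_depth <= 0:
            raise ValueError("well_depth must be positive")
        vol_um3 = math.pi * r_um**2 * well_depth
    else:
        raise ValueError(f"unknown volume model {model!r}")
    return vol_um3 / 1e6
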