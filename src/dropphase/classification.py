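"""Phase-separation classification of individual droplets.

A droplet is called phase-separated when its protein-channel pixel
distribution contains at least ``min_connected_px`` connected pixels above
an algorithm-defined intensity threshold — the presence of bright
condensate puncta.  The default threshold is robust (median + k·scaled MAD
of the droplet's own pixels), which makes the call invariant to
multiplicative intensity rescaling and insensitive to the condensates
themselves inflating the spread estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detection import DetectedDroplet
from .io import ImageSet
from .simulation import HOMOGENEOUS, SEPARATED

MAD_SCALE = 1.4826  # Gaussian-consistent scaling of the MAD


class UnclassifiableDroplet(ValueError):
    """Raised when a droplet has too few usable pixels to classify."""


@dataclass(frozen=True)
class ClassifierParams:
    """Connected-pixel rule parameters.

    ``erosion_px`` shrinks the analysis mask from the fitted circle to
    suppress bright rim artefacts; ``connectivity`` selects 4- or
    8-connected components; ``k`` is the robust multiplier of the
    median_mad / mean_sd rules; ``fixed_threshold`` is used only by the
    ``fixed`` rule.
    """

    min_connected_px: int = 3
    threshold_rule: str = "median_mad"
    k: float = 6.0
    connectivity: int = 8
    erosion_px: float = 2.0
    fixed_threshold: float = 0.0
    min_pixels: int = 25

    def __post_init__(self):
        if self.min_connected_px < 1:
            raise ValueError("min_connected_px must be >= 1")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_rule not in ("median_mad", "mean_sd", "fixed"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")


@dataclass(frozen=True)
class PhaseCall:
    droplet_id: int
    label: str
    n_condensate_px: int
    threshold_used: float
    largest_component_px: int


def condensate_threshold(pixels: np.ndarray, params: ClassifierParams) -> float:
    """Intensity threshold above which pixels count as condensate.

    median_mad: median + k · 1.4826 · MAD (deterministic, scale-equivariant);
    mean_sd: mean + k · sd; fixed: the configured constant.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size < params.min_pixels:
        raise UnclassifiableDroplet(
            f"{pixels.size} pixels < required {params.min_pixels}"
        )
    if params.threshold_rule == "median_mad":
        med = float(np.median(pixels))
        mad = float(np.median(np.abs(pixels - med)))
        return med + params.k * MAD_SCALE * mad
    if params.threshold_rule == "mean_sd":
        return float(pixels.mean() + params.k * pixels.std())
    return float(params.fixed_threshold)


def classify_droplet(
    images: ImageSet,
    droplet: DetectedDroplet,
    params: ClassifierParams,
    channel: str,
) -> PhaseCall:
    """Classify one droplet from the given (protein) channel.

    The fitted circle is eroded by ``erosion_px``, pixels strictly above the
    condensate threshold are labelled into connected components, and the
    droplet is separated iff the largest component has at least
    ``min_connected_px`` pixels.  Deterministic.
    """
    img = images.channel(channel)
    rows, cols = img.shape
    radius = droplet.radius - params.erosion_px
    if radius <= 0:
        raise UnclassifiableDroplet("erosion removed the whole droplet")
    r0 = max(int(droplet.row - radius) - 1, 0)
    r1 = min(int(droplet.row + radius) + 2, rows)
    c0 = max(int(droplet.col - radius) - 1, 0)
    c1 = min(int(droplet.col + radius) + 2, cols)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - droplet.row) ** 2 + (cc - droplet.col) ** 2 <= radius**2
    crop = np.asarray(img[r0:r1, c0:c1], dtype=float)
    pixels = crop[mask]
    threshold = condensate_threshold(pixels, params)

    binary = (crop > threshold) & mask
    structure = ndimage.generate_binary_structure(2, 2 if params.connectivity == 8 else 1)
    labels, n_comp = ndimage.label(binary, structure=structure)
    if n_comp == 0:
        largest = 0
    else:
        largest = int(np.max(ndimage.sum_labels(binary, labels, np.arange(1, n_comp + 1))))
    n_px = int(binary.sum())
    label = SEPARATED if largest >= params.min_connected_px else HOMOGENEOUS
    return PhaseCall(droplet.droplet_id, label, n_px, float(threshold), largest)


def classify_droplets(
    images: ImageSet,
    droplets: Sequence[DetectedDroplet],
    params: ClassifierParams,
    channel: str,
) -> tuple[list[PhaseCall], int]:
    """Classify all droplets; returns (calls, n_unclassifiable)."""
    calls = []
    skipped = 0
    for d in droplets:
        try:
            calls.append(classify_droplet(images, d, params, channel))
        except UnclassifiableDroplet:
            skipped += 1
    return calls, skipped


def classification_error(calls: Sequence[PhaseCall], truth: dict) -> float:
    """(false positives + false negatives) / number of classified droplets.

    ``truth`` maps droplet_id -> ground-truth label; only droplets present
    in both are scored.
    """
    scored = [c for c in calls if c.droplet_id in truth]
    if not scored:
        raise ValueError("no droplets shared between calls and truth")
    wrong = sum(1 for c in scored if c.label != truth[c.droplet_id])
    return wrong / len(scored)
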