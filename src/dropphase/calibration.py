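"""Fluorescence barcode calibration and spectral unmixing.

Raw per-droplet channel intensities are converted to component
concentrations in three steps: (1) total in-circle intensity per channel,
background-subtracted and normalised by droplet volume; (2) linear spectral
unmixing with the channel×fluorophore crosstalk matrix estimated from
single-fluorophore calibration series; (3) an affine intensity→concentration
map per fluorophore fitted to the same calibration series.

Because both sample and calibration droplets are reduced to
intensity-per-volume, droplets of different sizes are directly comparable
and the conversion is invariant to any global gain applied to both.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .detection import DetectedDroplet, DetectionParams, detect_droplets, droplet_volume, qc_filter
from .io import ImageSet
from .simulation import CalibrationSeries

logger = logging.getLogger(__name__)

FLAG_CLIPPED_NEGATIVE = "clipped_negative"


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class AffineFit:
    """Least-squares affine map intensity-per-volume = gain·conc + offset."""

    gain: float
    offset: float
    residual_sd: float = 0.0


@dataclass
class CalibrationModel:
    """Crosstalk matrix plus per-fluorophore concentration maps.

    ``crosstalk[c][f]`` is the channel-``c`` response per unit signal of
    fluorophore ``f``, column-normalised so the diagonal is 1.
    ``component_map`` maps fluorophore -> (component name, stock units).
    """

    channels: tuple[str, ...]
    fluorophores: tuple[str, ...]
    crosstalk: np.ndarray
    affine_maps: dict  # fluorophore -> AffineFit
    component_map: dict  # fluorophore -> (component, units)

    def __post_init__(self):
        K = np.asarray(self.crosstalk, dtype=float)
        if K.shape != (len(self.channels), len(self.fluorophores)):
            raise CalibrationError("crosstalk shape must be channels x fluorophores")
        if abs(np.linalg.det(K)) < 1e-12:
            raise CalibrationError("crosstalk matrix is singular")
        if not np.all(np.diag(K) == K.max(axis=1)):
            raise CalibrationError("crosstalk diagonal must dominate each row")
        if any(m.gain <= 0 for m in self.affine_maps.values()):
            raise CalibrationError("calibration gains must be positive")
        self.crosstalk = K

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": list(self.channels),
            "fluorophores": list(self.fluorophores),
            "crosstalk": self.crosstalk.tolist(),
            "affine_maps": {
                f: {"gain": m.gain, "offset": m.offset, "residual_sd": m.residual_sd}
                for f, m in self.affine_maps.items()
            },
            "component_map": {f: list(v) for f, v in self.component_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        p = json.loads(Path(path).read_text())
        return cls(
            channels=tuple(p["channels"]),
            fluorophores=tuple(p["fluorophores"]),
            crosstalk=np.asarray(p["crosstalk"], dtype=float),
            affine_maps={
                f: AffineFit(m["gain"], m["offset"], m.get("residual_sd", 0.0))
                for f, m in p["affine_maps"].items()
            },
            component_map={f: tuple(v) for f, v in p["component_map"].items()},
        )


@dataclass
class DropletIntensity:
    """Per-droplet background-subtracted intensities and volume."""

    droplet_id: int
    total: dict  # channel -> background-subtracted total intensity
    volume_nl: float
    per_volume: dict = field(default_factory=dict)  # channel -> total / volume

    def __post_init__(self):
        if not self.per_volume:
            self.per_volume = {c: t / self.volume_nl for c, t in self.total.items()}


@dataclass
class DropletRecord:
    """A droplet after concentration conversion (phase label added later)."""

    droplet_id: int
    concentrations: dict  # component -> concentration in stock units
    unmixed: dict  # fluorophore -> intensity per volume
    flags: set = field(default_factory=set)
    phase: str | None = None


def measure_intensities(
    images: ImageSet,
    droplets: Sequence[DetectedDroplet],
    volume_model: str = "cylinder",
    well_depth: float = 50.0,
    background_droplets: Sequence[DetectedDroplet] | None = None,
) -> list[DropletIntensity]:
    """Total in-circle intensity per channel, normalised per unit volume.

    The per-channel background is the median of pixels outside *all*
    detected circles (pass every detection, kept or not, via
    ``background_droplets``; defaults to ``droplets``) and is subtracted
    pixelwise from each droplet's total.
    """
    rows, cols = images.shape
    bg_src = droplets if background_droplets is None else background_droplets
    outside = np.ones((rows, cols), dtype=bool)
    for d in bg_src:
        rad = d.radius + 2.0
        r0, r1 = max(int(d.row - rad) - 1, 0), min(int(d.row + rad) + 2, rows)
        c0, c1 = max(int(d.col - rad) - 1, 0), min(int(d.col + rad) + 2, cols)
        rr, cc = np.ogrid[r0:r1, c0:c1]
        inside = (rr - d.row) ** 2 + (cc - d.col) ** 2 <= rad**2
        outside[r0:r1, c0:c1] &= ~inside

    backgrounds = {
        ch: float(np.median(images.channel(ch)[outside])) if outside.any() else 0.0
        for ch in images.channels
    }

    out = []
    for d in droplets:
        if (
            d.row - d.radius < 0
            or d.col - d.radius < 0
            or d.row + d.radius > rows
            or d.col + d.radius > cols
        ):
            raise ValueError(
                f"droplet {d.droplet_id} extends outside the image; "
                "edge droplets must be flagged upstream"
            )
        r0, r1 = int(d.row - d.radius) - 1, int(d.row + d.radius) + 2
        c0, c1 = int(d.col - d.radius) - 1, int(d.col + d.radius) + 2
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, rows), min(c1, cols)
        br, bc = np.ogrid[r0:r1, c0:c1]
        mask = (br - d.row) ** 2 + (bc - d.col) ** 2 <= d.radius**2
        area = int(mask.sum())
        volume = droplet_volume(
            d.radius, images.pixel_size, model=volume_model, well_depth=well_depth
        )
        totals = {}
        for ch in images.channels:
            crop = images.channel(ch)[r0:r1, c0:c1]
            totals[ch] = float(crop[mask].sum() - backgrounds[ch] * area)
        out.append(DropletIntensity(d.droplet_id, totals, volume))
    return out


def _series_responses(
    series: CalibrationSeries,
    det_params: DetectionParams,
    volume_model: str,
    well_depth: float,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """(concentration, mean per-channel intensity-per-volume) per frame."""
    concs, responses = [], []
    channels = None
    for conc, images in zip(series.concentrations, series.images):
        channels = images.channels
        detections = qc_filter(
            detect_droplets(images, det_params), det_params, images.shape
        )
        kept = [d for d in detections if d.kept]
        if not kept:
            continue  # e.g. zero-concentration frame: nothing to detect
        meas = measure_intensities(
            images, kept, volume_model, well_depth, background_droplets=detections
        )
        mean_ipv = [
            float(np.mean([m.per_volume[ch] for m in meas])) for ch in channels
        ]
        concs.append(conc)
        responses.append(mean_ipv)
    if len(concs) < 2:
        raise CalibrationError(
            f"series for {series.fluorophore}: fewer than 2 usable concentrations"
        )
    return np.asarray(concs), np.asarray(responses), channels


def estimate_crosstalk(
    calibration_sets: Sequence[CalibrationSeries],
    det_params: DetectionParams | None = None,
    volume_model: str = "cylinder",
    well_depth: float = 50.0,
) -> np.ndarray:
    """Channel×fluorophore crosstalk matrix from single-fluorophore series.

    Column ``f`` holds the per-channel response slopes of fluorophore ``f``'s
    dilution series, normalised so the fluorophore's own channel is 1.
    Negative off-diagonals are clipped to 0 (warning if below -0.01).
    """
    det_params = det_params or DetectionParams()
    fluorophores = [s.fluorophore for s in calibration_sets]
    channels = None
    cols = []
    for series in calibration_sets:
        concs, resp, channels = _series_responses(
            series, det_params, volume_model, well_depth
        )
        slopes = np.polyfit(concs, resp, 1)[0]  # per-channel slope
        cols.append(slopes)
    K = np.column_stack(cols)
    # channel order must match fluorophore order for the diagonal convention
    if K.shape[0] != K.shape[1]:
        raise CalibrationError("need one channel per fluorophore")
    for f in range(K.shape[1]):
        own = K[f, f]
        if own <= 0:
            raise CalibrationError(
                f"fluorophore {fluorophores[f]} has non-positive own-channel slope"
            )
        K[:, f] /= own
    negative = K < 0
    if (K < -0.01).any():
        logger.warning("negative crosstalk entries below -0.01 clipped to 0")
        warnings.warn("negative crosstalk entries clipped to 0", stacklevel=2)
    K[negative] = 0.0
    if abs(np.linalg.det(K)) < 1e-12:
        raise CalibrationError("fitted crosstalk matrix is singular")
    return K


def unmix(observed, K: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert the crosstalk: fluorophore = K⁻¹ · observed.

    Accepts a single channel vector or an (n, channels) matrix.  Negative
    unmixed values are floored at 0; the second return value reports whether
    any flooring occurred.
    """
    K = np.asarray(K, dtype=float)
    if abs(np.linalg.det(K)) < 1e-12:
        raise CalibrationError("crosstalk matrix is singular")
    obs = np.asarray(observed, dtype=float)
    result = np.linalg.solve(K, obs.T).T
    clipped = bool((result < 0).any())
    return np.clip(result, 0.0, None), clipped


def fit_intensity_to_concentration(
    concentrations: Sequence[float],
    intensities: Sequence[float],
    through_origin: bool = False,
) -> AffineFit:
    """Ordinary least-squares affine fit of intensity-per-volume on
    concentration; stores the residual standard deviation."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(np.unique(c)) < 2:
        raise CalibrationError("need at least 2 distinct concentrations")
    if through_origin:
        gain = float(np.dot(c, y) / np.dot(c, c))
        offset = 0.0
    else:
        gain, offset = (float(v) for v in np.polyfit(c, y, 1))
    resid = y - (gain * c + offset)
    dof = max(len(c) - (1 if through_origin else 2), 1)
    return AffineFit(gain, offset, float(np.sqrt(np.sum(resid**2) / dof)))


def build_calibration_model(
    calibration_sets: Sequence[CalibrationSeries],
    component_map: dict,
    det_params: DetectionParams | None = None,
    volume_model: str = "cylinder",
    well_depth: float = 50.0,
    through_origin: bool = False,
) -> CalibrationModel:
    """Full calibration: crosstalk matrix + affine map per fluorophore.

    ``component_map``: fluorophore -> (component name, units).  The affine
    maps are fitted on the *unmixed* series responses so they compose
    correctly with :func:`unmix` at conversion time.
    """
    det_params = det_params or DetectionParams()
    K = estimate_crosstalk(calibration_sets, det_params, volume_model, well_depth)
    affine_maps = {}
    channels = None
    for f_idx, series in enumerate(calibration_sets):
        concs, resp, channels = _series_responses(
            series, det_params, volume_model, well_depth
        )
        unmixed, _ = unmix(resp, K)
        affine_maps[series.fluorophore] = fit_intensity_to_concentration(
            concs, unmixed[:, f_idx], through_origin=through_origin
        )
    return CalibrationModel(
        channels=tuple(channels),
        fluorophores=tuple(s.fluorophore for s in calibration_sets),
        crosstalk=K,
        affine_maps=affine_maps,
        component_map=dict(component_map),
    )


def to_concentrations(
    record: DropletIntensity, model: CalibrationModel
) -> DropletRecord:
    """Convert one droplet's intensities to component concentrations.

    conc_f = (unmixed_f − offset_f) / gain_f; negatives are floored at 0 and
    flagged rather than discarded so droplet counts are preserved for the
    phase diagram.
    """
    missing = [c for c in model.channels if c not in record.total]
    if missing:
        raise CalibrationError(f"droplet record missing channels {missing}")
    observed = np.array([record.per_volume[c] for c in model.channels])
    unmixed, clipped = unmix(observed, model.crosstalk)
    flags = {FLAG_CLIPPED_NEGATIVE} if clipped else set()
    concentrations = {}
    unmixed_map = {}
    for i, f in enumerate(model.fluorophores):
        if f not in model.component_map:
            raise CalibrationError(f"no component mapped for fluorophore {f}")
        component = model.component_map[f][0]
        fit = model.affine_maps[f]
        conc = (unmixed[i] - fit.offset) / fit.gain
        if conc < 0:
            conc = 0.0
            flags.add(FLAG_CLIPPED_NEGATIVE)
        concentrations[component] = float(conc)
        unmixed_map[f] = float(unmixed[i])
    return DropletRecord(record.droplet_id, concentrations, unmixed_map, flags)
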