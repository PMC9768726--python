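"""Ground-truthed synthetic droplet experiments.

This module emulates a combinatorial droplet-microfluidics experiment in
which aqueous inlets (protein, crowder/trigger, buffer, optional modulator)
are mixed at programmed volume-fraction ratios, encapsulated as water-in-oil
microdroplets, trapped and imaged.  Each droplet's component concentrations
are encoded by barcode fluorophores; droplets whose composition falls on the
phase-separated side of a parametric boundary contain bright condensate
puncta in the protein channel.

Everything needed to test the downstream pipeline is generated here with a
known manifest: compositions from a :class:`FlowProgramme`, phase labels
from a :class:`BoundaryModel` (with optional label noise), and rendered
multichannel images with additive Gaussian noise and linear channel
crosstalk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ImageSet

SEPARATED = "separated"
HOMOGENEOUS = "homogeneous"

_FRACTION_TOL = 1e-9


class ConfigurationError(ValueError):
    """Raised for invalid programme / scene specifications."""


# ---------------------------------------------------------------------------
# Boundary models


@dataclass(frozen=True)
class BoundaryModel:
    """Parametric phase boundary in concentration space.

    kinds
    -----
    ``linear``
        separated iff ``dot(params[:-1], c) + params[-1] > 0``.
    ``reentrant_band``
        separated iff the designated coordinate lies strictly between two
        affine functions of the remaining coordinates:
        ``lo(c_other) < c[axis] < hi(c_other)`` with
        ``params = [lo_intercept, *lo_slopes, hi_intercept, *hi_slopes]``.
    ``threshold_3d``
        separated iff a planar drive term on the first two coordinates
        exceeds a suppression term proportional to the third:
        ``params = (w0, w1, b, w_suppress)`` and separated iff
        ``w0*c0 + w1*c1 + b > w_suppress*c2`` (``w_suppress > 0`` makes the
        third component monotonically suppress phase separation).

    ``flip_rate`` is the probability that the noiseless label is inverted,
    modelling classification/label noise.
    """

    kind: str
    params: tuple[float, ...]
    flip_rate: float = 0.0
    axis: int = 0
    ndim: int = 2

    def __post_init__(self):
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ConfigurationError("flip_rate must be in [0, 1]")
        if self.kind not in ("linear", "reentrant_band", "threshold_3d"):
            raise ConfigurationError(f"unknown boundary kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind == "linear" and len(self.params) != self.ndim + 1:
            raise ConfigurationError("linear boundary needs ndim weights + intercept")
        if self.kind == "reentrant_band" and len(self.params) != 2 * self.ndim:
            raise ConfigurationError(
                "reentrant_band needs (intercept + slopes) for lower and upper bound"
            )
        if self.kind == "threshold_3d":
            if self.ndim != 3 or len(self.params) != 4:
                raise ConfigurationError("threshold_3d needs ndim=3 and 4 params")

    @classmethod
    def linear(cls, weights: Sequence[float], intercept: float, flip_rate: float = 0.0):
        w = tuple(float(x) for x in weights)
        return cls("linear", w + (float(intercept),), flip_rate, ndim=len(w))

    @classmethod
    def reentrant_band(
        cls,
        axis: int,
        lower: Sequence[float],
        upper: Sequence[float],
        flip_rate: float = 0.0,
        ndim: int = 2,
    ):
        """``lower``/``upper`` = (intercept, *slopes over the other coords)."""
        return cls(
            "reentrant_band",
            tuple(lower) + tuple(upper),
            flip_rate,
            axis=axis,
            ndim=ndim,
        )

    @classmethod
    def threshold_3d(
        cls, drive: Sequence[float], intercept: float, suppression: float,
        flip_rate: float = 0.0,
    ):
        return cls(
            "threshold_3d",
            (float(drive[0]), float(drive[1]), float(intercept), float(suppression)),
            flip_rate,
            ndim=3,
        )

    def evaluate(self, composition: Sequence[float]) -> str:
        """Noiseless phase label of one composition."""
        c = np.asarray(composition, dtype=float)
        if c.shape != (self.ndim,):
            raise ValueError(
                f"composition has {c.shape[0] if c.ndim == 1 else c.shape} dims, "
                f"model expects {self.ndim}"
            )
        if self.kind == "linear":
            sep = float(np.dot(self.params[:-1], c) + self.params[-1]) > 0.0
        elif self.kind == "reentrant_band":
            half = len(self.params) // 2
            lo_p, hi_p = self.params[:half], self.params[half:]
            others = np.delete(c, self.axis)
            lo = lo_p[0] + float(np.dot(lo_p[1:], others))
            hi = hi_p[0] + float(np.dot(hi_p[1:], others))
            sep = lo < c[self.axis] < hi
        else:  # threshold_3d
            w0, w1, b, ws = self.params
            sep = (w0 * c[0] + w1 * c[1] + b) > ws * c[2]
        return SEPARATED if sep else HOMOGENEOUS


def ground_truth_label(
    composition: Sequence[float], model: BoundaryModel, rng: np.random.Generator
) -> str:
    """Boundary evaluation, inverted with probability ``model.flip_rate``."""
    label = model.evaluate(composition)
    if model.flip_rate > 0 and rng.random() < model.flip_rate:
        label = HOMOGENEOUS if label == SEPARATED else SEPARATED
    return label


# ---------------------------------------------------------------------------
# Flow programme


@dataclass(frozen=True)
class FlowProgramme:
    """Programmed inlet volume fractions and stock concentrations.

    Each inlet carries one (possibly unbarcoded, zero-stock) component at a
    stated stock concentration; a droplet formed at ramp step ``j`` receives
    component concentration ``fraction_j · stock`` for every inlet.  The
    total aqueous flow is constant, so fractions in every ramp tuple sum
    to 1.
    """

    inlet_names: tuple[str, ...]
    stocks: tuple[float, ...]
    ramp: tuple[tuple[float, ...], ...]
    constant_inlets: frozenset[int] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "inlet_names", tuple(self.inlet_names))
        object.__setattr__(self, "stocks", tuple(float(s) for s in self.stocks))
        object.__setattr__(
            self, "ramp", tuple(tuple(float(f) for f in row) for row in self.ramp)
        )
        object.__setattr__(self, "constant_inlets", frozenset(self.constant_inlets))
        if len(self.ramp) == 0:
            raise ConfigurationError("flow programme ramp is empty")
        k = len(self.inlet_names)
        if len(self.stocks) != k:
            raise ConfigurationError("one stock concentration per inlet required")
        for row in self.ramp:
            if len(row) != k:
                raise ConfigurationError("ramp tuple length != number of inlets")
            if any(f < 0 for f in row):
                raise ConfigurationError("volume fractions must be >= 0")
            if abs(sum(row) - 1.0) > _FRACTION_TOL:
                raise ConfigurationError("volume fractions must sum to 1")
        for i in self.constant_inlets:
            vals = {row[i] for row in self.ramp}
            if len(vals) > 1:
                raise ConfigurationError(
                    f"constant inlet {self.inlet_names[i]} varies along the ramp"
                )

    @property
    def n_inlets(self) -> int:
        return len(self.inlet_names)

    def index(self, name: str) -> int:
        return self.inlet_names.index(name)


def sample_compositions(
    programme: FlowProgramme, n_droplets: int, seed: int | None = None
) -> np.ndarray:
    """Per-droplet component concentrations along the flow programme.

    Droplets are assigned ramp points cyclically (droplet ``j`` gets ramp
    step ``j mod len(ramp)``) so the full ramp is traversed at least once
    whenever ``n_droplets >= len(ramp)``.  The assignment is deterministic;
    ``seed`` is accepted for interface symmetry with the stochastic steps
    but does not influence the result.

    Returns an ``(n_droplets, n_inlets)`` array of concentrations in the
    stock units of each inlet.
    """
    if n_droplets < 1:
        raise ConfigurationError("n_droplets must be >= 1")
    ramp = np.asarray(programme.ramp, dtype=float)
    stocks = np.asarray(programme.stocks, dtype=float)
    idx = np.arange(n_droplets) % len(ramp)
    return ramp[idx] * stocks[None, :]


def linear_ramp(
    start: Sequence[float], stop: Sequence[float], n_steps: int
) -> tuple[tuple[float, ...], ...]:
    """Straight-line ramp between two volume-fraction tuples (inclusive)."""
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    t = np.linspace(0.0, 1.0, n_steps)[:, None]
    rows = (1 - t) * start[None, :] + t * stop[None, :]
    return tuple(tuple(row) for row in rows)


def grid_ramp(
    fractions_a: Sequence[float],
    fractions_b: Sequence[float],
    constant: Sequence[float] = (),
) -> tuple[tuple[float, ...], ...]:
    """Cartesian grid over two varied inlets; remaining flow goes to buffer.

    ``constant`` holds fixed fractions for any constant inlets (appended
    after the buffer column).  Inlet order of the produced tuples:
    ``(a, b, buffer, *constant)``.
    """
    rows = []
    c_sum = float(sum(constant))
    for fa in fractions_a:
        for fb in fractions_b:
            buffer = 1.0 - fa - fb - c_sum
            if buffer < -_FRACTION_TOL:
                raise ConfigurationError("grid fractions exceed total flow")
            rows.append((float(fa), float(fb), max(buffer, 0.0)) + tuple(constant))
    return tuple(rows)


# ---------------------------------------------------------------------------
# Optics and scenes


@dataclass(frozen=True)
class PunctaSpec:
    """Condensate puncta drawn inside separated droplets.

    1–5 discs of radius 2–4 px at >=2x the droplet's own barcode signal,
    placed uniformly inside the circle away from the rim so that at least
    one punctum always presents >=3 connected pixels to the classifier.
    """

    count_range: tuple[int, int] = (1, 5)
    radius_range: tuple[float, float] = (2.0, 4.0)
    contrast: float = 2.0

    def __post_init__(self):
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ConfigurationError("invalid puncta count range")
        if self.radius_range[0] < 1.0:
            raise ConfigurationError("puncta radius must be >= 1 px")
        if self.contrast <= 1.0:
            raise ConfigurationError("puncta contrast must exceed 1")


@dataclass(frozen=True)
class OpticsSpec:
    """Per-channel imaging model: intensity = gain·concentration + background.

    ``gains`` map fluorophore name -> counts per concentration unit,
    ``background`` is the camera offset in counts (fluorophore space),
    ``noise_sd`` the additive per-pixel Gaussian noise sd in counts.
    """

    gains: dict
    background: float = 100.0
    noise_sd: float = 0.0
    pixel_size: float = 1.0
    puncta: PunctaSpec = field(default_factory=PunctaSpec)

    def __post_init__(self):
        if any(g <= 0 for g in self.gains.values()):
            raise ConfigurationError("gains must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel size must be positive")


@dataclass(frozen=True)
class DropletSpec:
    """One droplet placed in a scene (ground truth)."""

    row: float
    col: float
    radius: float
    composition: dict  # component name -> concentration
    label: str

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("droplet radius must be positive")
        if self.label not in (SEPARATED, HOMOGENEOUS):
            raise ConfigurationError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one rendered field of view."""

    image_shape: tuple[int, int]
    droplets: tuple[DropletSpec, ...]
    optics: OpticsSpec
    channels: tuple[str, ...]
    fluorophores: tuple[str, ...]
    crosstalk: tuple[tuple[float, ...], ...]  # channel x fluorophore
    fluorophore_of: dict  # component name -> fluorophore
    condensate_component: str
    seed: int = 0
    allow_edge: bool = False

    def __post_init__(self):
        object.__setattr__(self, "droplets", tuple(self.droplets))
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "fluorophores", tuple(self.fluorophores))
        K = np.asarray(self.crosstalk, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ConfigurationError("crosstalk matrix must be square")
        if K.shape[0] != len(self.channels) or K.shape[0] != len(self.fluorophores):
            raise ConfigurationError("crosstalk shape must match channels/fluorophores")
        if abs(np.linalg.det(K)) < 1e-12:
            raise ConfigurationError("crosstalk matrix is singular")
        offdiag = np.abs(K).sum(axis=1) - np.abs(np.diag(K))
        if np.any(np.abs(np.diag(K)) <= offdiag):
            raise ConfigurationError(
                "crosstalk matrix must be diagonally dominant (minimal crosstalk)"
            )
        object.__setattr__(self, "crosstalk", tuple(tuple(row) for row in K))

    @property
    def crosstalk_matrix(self) -> np.ndarray:
        return np.asarray(self.crosstalk, dtype=float)


def _disc_mask(shape, row, col, radius):
    """Boolean disc plus its bounding-box slices (clipped to the image)."""
    r0 = max(int(math.floor(row - radius)) - 1, 0)
    r1 = min(int(math.ceil(row + radius)) + 2, shape[0])
    c0 = max(int(math.floor(col - radius)) - 1, 0)
    c1 = min(int(math.ceil(col + radius)) + 2, shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
    return mask, (slice(r0, r1), slice(c0, c1))


def render_scene(spec: SceneSpec) -> tuple[ImageSet, pd.DataFrame]:
    """Render a scene to a multichannel image plus its ground-truth manifest.

    Forward model, per fluorophore ``f``: inside each droplet the pre-noise
    fluorophore-space intensity is ``gain_f · conc_f + background``; within
    condensate puncta of separated droplets the signal term of the
    condensate fluorophore is multiplied by the puncta contrast.  Observed
    channels are the crosstalk matrix applied pixelwise to the fluorophore
    stack, plus additive Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    n_f = len(spec.fluorophores)
    fluo = np.zeros((n_f, *shape), dtype=np.float64)
    comp_to_f = {c: spec.fluorophores.index(f) for c, f in spec.fluorophore_of.items()}
    cond_f = comp_to_f[spec.condensate_component]

    rows = []
    for i, d in enumerate(spec.droplets):
        if not spec.allow_edge:
            if (
                d.row - d.radius < 0
                or d.col - d.radius < 0
                or d.row + d.radius > shape[0]
                or d.col + d.radius > shape[1]
            ):
                raise ConfigurationError(
                    f"droplet {i} extends beyond the image; "
                    "enable allow_edge to render edge droplets"
                )
        mask, box = _disc_mask(shape, d.row, d.col, d.radius)
        signal = {}
        for comp, conc in d.composition.items():
            fi = comp_to_f.get(comp)
            if fi is None:
                continue  # unbarcoded component (e.g. buffer)
            fname = spec.fluorophores[fi]
            s = spec.optics.gains[fname] * conc
            fluo[fi][box][mask] += s
            signal[fi] = s
        if d.label == SEPARATED and signal.get(cond_f, 0.0) > 0.0:
            _render_puncta(fluo[cond_f], d, signal[cond_f], spec.optics.puncta, rng)
        rec = {
            "droplet_id": i,
            "row_px": d.row,
            "col_px": d.col,
            "radius_px": d.radius,
            "true_label": d.label,
        }
        rec.update({f"conc_{k}": v for k, v in d.composition.items()})
        rows.append(rec)

    fluo += spec.optics.background
    K = spec.crosstalk_matrix
    observed = np.tensordot(K, fluo, axes=(1, 0))
    if spec.optics.noise_sd > 0:
        observed = observed + rng.normal(0.0, spec.optics.noise_sd, observed.shape)
    observed = np.clip(observed, 0.0, None)

    images = ImageSet(
        data=observed.astype(np.float32),
        channels=spec.channels,
        pixel_size=spec.optics.pixel_size,
    )
    manifest = pd.DataFrame(rows)
    return images, manifest


def _render_puncta(plane, droplet, signal, puncta: PunctaSpec, rng):
    """Add condensate puncta: signal multiplied by contrast inside discs."""
    n = int(rng.integers(puncta.count_range[0], puncta.count_range[1] + 1))
    extra = signal * (puncta.contrast - 1.0)
    # keep puncta clear of the rim so a 2 px mask erosion cannot clip the
    # guaranteed >=3 connected pixels
    rim_margin = puncta.radius_range[1] + 4.0
    max_off = max(droplet.radius - rim_margin, 0.0)
    for j in range(n):
        # first punctum at the largest radius in range: always >=3 connected px
        pr = (
            puncta.radius_range[1]
            if j == 0
            else rng.uniform(*puncta.radius_range)
        )
        theta = rng.uniform(0.0, 2.0 * math.pi)
        rho = max_off * math.sqrt(rng.uniform())
        prow = droplet.row + rho * math.sin(theta)
        pcol = droplet.col + rho * math.cos(theta)
        mask, box = _disc_mask(plane.shape, prow, pcol, pr)
        plane[box][mask] += extra


def random_layout(
    n: int,
    shape: tuple[int, int],
    radius_range: tuple[float, float],
    rng: np.random.Generator,
    min_gap: float = 4.0,
    edge_margin: float = 4.0,
    max_attempts: int = 2000,
    overlap_fraction: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping circle placements.

    Returns up to ``n`` tuples ``(row, col, radius)``; fewer if the field
    cannot accommodate all of them.  ``overlap_fraction`` > 0 deliberately
    places that fraction of droplets overlapping an existing one (QC test
    material).
    """
    placed: list[tuple[float, float, float]] = []
    for i in range(n):
        radius = rng.uniform(*radius_range)
        lo_r, hi_r = radius + edge_margin, shape[0] - radius - edge_margin
        lo_c, hi_c = radius + edge_margin, shape[1] - radius - edge_margin
        if hi_r <= lo_r or hi_c <= lo_c:
            break
        want_overlap = placed and rng.random() < overlap_fraction
        for _ in range(max_attempts):
            row = rng.uniform(lo_r, hi_r)
            col = rng.uniform(lo_c, hi_c)
            d2 = [
                (row - p[0]) ** 2 + (col - p[1]) ** 2 - (radius + p[2] + min_gap) ** 2
                for p in placed
            ]
            ok = all(x > 0 for x in d2)
            if want_overlap:
                # touching but distinct centres
                j = int(rng.integers(len(placed)))
                p = placed[j]
                theta = rng.uniform(0, 2 * math.pi)
                dist = 0.85 * (radius + p[2])
                row = p[0] + dist * math.sin(theta)
                col = p[1] + dist * math.cos(theta)
                if lo_r < row < hi_r and lo_c < col < hi_c:
                    placed.append((row, col, radius))
                    break
            elif ok:
                placed.append((row, col, radius))
                break
        # droplet silently skipped if no placement found
    return placed


def simulate_fields(
    programme: FlowProgramme,
    boundary: BoundaryModel,
    optics: OpticsSpec,
    channels: Sequence[str],
    fluorophores: Sequence[str],
    crosstalk,
    fluorophore_of: dict,
    condensate_component: str,
    boundary_components: Sequence[str],
    n_droplets: int,
    field_shape: tuple[int, int] = (1024, 1024),
    droplets_per_field: int = 35,
    radius_range: tuple[float, float] = (40.0, 55.0),
    seed: int = 0,
    overlap_fraction: float = 0.0,
) -> tuple[list[tuple[ImageSet, pd.DataFrame]], pd.DataFrame]:
    """Render a whole experiment as a series of fields of view.

    Compositions follow the flow programme cyclically; labels come from the
    boundary model evaluated on ``boundary_components`` (in that order) with
    label noise ``boundary.flip_rate``.  Returns the per-field
    ``(ImageSet, manifest)`` pairs and the combined manifest with global
    droplet ids and field indices.
    """
    rng = np.random.default_rng(seed)
    comps = sample_compositions(programme, n_droplets)
    b_idx = [programme.index(name) for name in boundary_components]
    labels = [
        ground_truth_label(comps[j, b_idx], boundary, rng) for j in range(n_droplets)
    ]

    fields = []
    manifests = []
    placed_total = 0
    fid = 0
    while placed_total < n_droplets:
        want = min(droplets_per_field, n_droplets - placed_total)
        layout = random_layout(want, field_shape, radius_range, rng)
        if not layout:
            raise ConfigurationError("field too small for requested droplets")
        droplets = []
        for k, (row, col, radius) in enumerate(layout):
            j = placed_total + k
            composition = {
                name: float(comps[j, programme.index(name)])
                for name in programme.inlet_names
            }
            droplets.append(
                DropletSpec(row, col, radius, composition, labels[j])
            )
        spec = SceneSpec(
            image_shape=field_shape,
            droplets=tuple(droplets),
            optics=optics,
            channels=tuple(channels),
            fluorophores=tuple(fluorophores),
            crosstalk=crosstalk,
            fluorophore_of=fluorophore_of,
            condensate_component=condensate_component,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        images, manifest = render_scene(spec)
        manifest["field"] = fid
        manifest["droplet_id"] = manifest["droplet_id"] + placed_total
        fields.append((images, manifest))
        manifests.append(manifest)
        placed_total += len(layout)
        fid += 1
    combined = pd.concat(manifests, ignore_index=True)
    return fields, combined


@dataclass(frozen=True)
class CalibrationSeries:
    """Single-fluorophore droplet images at known concentrations."""

    fluorophore: str
    concentrations: tuple[float, ...]
    images: tuple[ImageSet, ...]


def make_calibration_series(
    fluorophore: str,
    concentrations: Sequence[float],
    optics: OpticsSpec,
    channels: Sequence[str],
    fluorophores: Sequence[str],
    crosstalk,
    n_droplets: int = 8,
    image_shape: tuple[int, int] = (512, 512),
    radius_range: tuple[float, float] = (40.0, 55.0),
    seed: int = 0,
) -> CalibrationSeries:
    """Render the calibration dilution series for one barcode fluorophore.

    Each frame contains droplets of a single component carrying
    ``fluorophore`` at one known concentration, imaged with the same optics
    as the experiment.
    """
    concs = tuple(float(c) for c in concentrations)
    if len(set(concs)) < 2:
        raise ConfigurationError("need at least 2 distinct calibration concentrations")
    rng = np.random.default_rng(seed)
    images = []
    for conc in concs:
        layout = random_layout(n_droplets, image_shape, radius_range, rng)
        droplets = tuple(
            DropletSpec(row, col, radius, {"cal": conc}, HOMOGENEOUS)
            for row, col, radius in layout
        )
        spec = SceneSpec(
            image_shape=image_shape,
            droplets=droplets,
            optics=optics,
            channels=tuple(channels),
            fluorophores=tuple(fluorophores),
            crosstalk=crosstalk,
            fluorophore_of={"cal": fluorophore},
            condensate_component="cal",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, _ = render_scene(spec)
        images.append(img)
    return CalibrationSeries(fluorophore, concs, tuple(images))
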