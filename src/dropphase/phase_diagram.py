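"""Phase-diagram assembly, SVM probability surfaces and stability analysis.

Per-droplet (concentration, phase-label) points are combined into a scatter
phase diagram; a support-vector machine with an RBF kernel, trained on the
standardised points, provides a calibrated probability of phase separation
over a dense grid of chemical space.  The phase boundary is the p = 0.5
isocontour.  Differential maps quantify a modulator's shift of the
boundary; bootstrap refits quantify how stable the diagram is at a given
sample size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import interpn
from skimage import measure
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .calibration import DropletRecord
from .simulation import SEPARATED

logger = logging.getLogger(__name__)

MIN_RECOMMENDED_N = 1500


class PhaseDiagramError(ValueError):
    pass


@dataclass(frozen=True)
class SVMParams:
    """SVM hyperparameters: RBF kernel, C=1, bandwidth by median heuristic
    on the standardised features unless ``gamma`` is given explicitly."""

    C: float = 1.0
    gamma: float | None = None
    seed: int = 0


@dataclass
class Grid:
    """Probability (or difference) values over a rectilinear grid."""

    dims: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise PhaseDiagramError("grid values shape must match axes")

    def to_table(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {d: m.ravel() for d, m in zip(self.dims, mesh)}
        data["probability"] = self.values.ravel()
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StabilityReport:
    """Bootstrap stability of the thresholded probability map."""

    n_boot: int
    disagreement: float  # mean pairwise fraction of grid cells flipping at p=0.5
    probability_mad: float  # mean pairwise |Δp| over the grid

    def __post_init__(self):
        if not 0.0 <= self.disagreement <= 1.0:
            raise PhaseDiagramError("disagreement must be in [0, 1]")
        if not 0.0 <= self.probability_mad <= 1.0:
            raise PhaseDiagramError("probability_mad must be in [0, 1]")


def build_phase_diagram(
    records: Sequence[DropletRecord], dims: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (points, labels) scatter from classified droplet records.

    Unclassified records are dropped; raises if either class is absent
    ("phase boundary not bracketed"); warns below the recommended sample
    size of 1500 droplets.
    """
    dims = list(dims)
    classified = [r for r in records if r.phase is not None]
    points = np.empty((len(classified), len(dims)), dtype=float)
    labels = np.empty(len(classified), dtype=int)
    for i, rec in enumerate(classified):
        for j, dim in enumerate(dims):
            if dim not in rec.concentrations:
                raise PhaseDiagramError(
                    f"record {rec.droplet_id} lacks concentration for {dim!r}"
                )
            points[i, j] = rec.concentrations[dim]
        labels[i] = 1 if rec.phase == SEPARATED else 0
    if len(classified) == 0 or labels.min() == labels.max():
        raise PhaseDiagramError("phase boundary not bracketed: need both classes")
    if len(classified) < MIN_RECOMMENDED_N:
        warnings.warn(
            f"only {len(classified)} droplets; >={MIN_RECOMMENDED_N} recommended "
            "for a <3% bootstrap-stable diagram",
            stacklevel=2,
        )
    n_sep = int(labels.sum())
    logger.info(
        "phase diagram: %d droplets (%d separated / %d homogeneous)",
        len(classified), n_sep, len(classified) - n_sep,
    )
    return points, labels


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    sub = X if len(X) <= 500 else X[rng.choice(len(X), 500, replace=False)]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = float(np.median(d2[np.triu_indices(len(sub), k=1)]))
    return 1.0 / med if med > 0 else 1.0


def fit_svm(
    points: np.ndarray,
    labels: np.ndarray,
    params: SVMParams | None = None,
) -> Pipeline:
    """Fit the probability-calibrated RBF SVM on standardised features.

    Features are z-scored per dimension; probabilities come from sigmoid
    (Platt) calibration on internal cross-validation folds.  A fixed seed
    makes the fit reproducible.
    """
    params = params or SVMParams()
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[1] not in (2, 3):
        raise PhaseDiagramError("points must be n x d with d in {2, 3}")
    if len(np.unique(labels)) < 2:
        raise PhaseDiagramError("phase boundary not bracketed: need both classes")
    if np.any(points.std(axis=0) == 0):
        raise PhaseDiagramError("zero-variance dimension; cannot standardise")
    rng = np.random.default_rng(params.seed)
    Xz = (points - points.mean(axis=0)) / points.std(axis=0)
    gamma = params.gamma if params.gamma is not None else _median_heuristic_gamma(Xz, rng)
    svc = SVC(kernel="rbf", C=params.C, gamma=gamma, random_state=params.seed)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False),
            ),
        ]
    )
    model.fit(points, labels)
    return model


def percentile_bounds(
    points: np.ndarray, lo: float = 1.0, hi: float = 99.0
) -> list[tuple[float, float]]:
    """Default grid bounds: the [lo, hi] percentile box of the data."""
    points = np.asarray(points, dtype=float)
    return [
        (float(np.percentile(points[:, j], lo)), float(np.percentile(points[:, j], hi)))
        for j in range(points.shape[1])
    ]


def probability_grid(
    model: Pipeline,
    bounds: Sequence[tuple[float, float]],
    resolution: int | Sequence[int] = 200,
    dims: Sequence[str] | None = None,
) -> Grid:
    """Calibrated probability of phase separation over a dense grid."""
    d = len(bounds)
    if np.isscalar(resolution):
        resolution = [int(resolution)] * d
    if any(r < 2 for r in resolution):
        raise PhaseDiagramError("grid resolution must be >= 2 per dimension")
    axes = tuple(
        np.linspace(lo, hi, r) for (lo, hi), r in zip(bounds, resolution)
    )
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    sep_col = list(model.classes_).index(1)
    probs = model.predict_proba(pts)[:, sep_col].reshape([len(a) for a in axes])
    dims = tuple(dims) if dims is not None else tuple(f"dim{j}" for j in range(d))
    return Grid(dims=dims, axes=axes, values=probs)


def boundary_curve(grid: Grid) -> np.ndarray:
    """The p = 0.5 isocontour of the probability grid, in data units.

    2-D grids use marching squares, 3-D grids marching cubes.  Returns an
    (n, d) array of contour points; empty (with a warning) when the grid
    never crosses 0.5.
    """
    v = grid.values
    if not (v.min() < 0.5 < v.max()):
        warnings.warn("probability grid does not cross 0.5; empty boundary", stacklevel=2)
        return np.empty((0, v.ndim))
    if v.ndim == 2:
        contours = measure.find_contours(v, 0.5)
        idx = np.vstack(contours) if contours else np.empty((0, 2))
    elif v.ndim == 3:
        verts, *_ = measure.marching_cubes(v, level=0.5)
        idx = verts
    else:
        raise PhaseDiagramError("boundary extraction supports 2-D and 3-D grids")
    pts = np.empty_like(idx)
    for j, axis in enumerate(grid.axes):
        pts[:, j] = np.interp(idx[:, j], np.arange(len(axis)), axis)
    return pts


def differential_map(grid_a: Grid, grid_b: Grid) -> Grid:
    """Elementwise probability shift P_B − P_A on grid A's axes.

    If B's axes differ, B is linearly resampled onto A's axes where the
    ranges overlap; disjoint axis ranges are an error.
    """
    same = len(grid_a.axes) == len(grid_b.axes) and all(
        len(a) == len(b) and np.allclose(a, b)
        for a, b in zip(grid_a.axes, grid_b.axes)
    )
    if same:
        vb = grid_b.values
    else:
        for a, b in zip(grid_a.axes, grid_b.axes):
            if a.max() < b.min() or b.max() < a.min():
                raise PhaseDiagramError("grid axis ranges are disjoint")
        mesh = np.meshgrid(*grid_a.axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vb = interpn(
            grid_b.axes, grid_b.values, pts, bounds_error=False, fill_value=None
        ).reshape(grid_a.values.shape)
    return Grid(dims=grid_a.dims, axes=grid_a.axes, values=vb - grid_a.values)


def slice_3d(grid: Grid, axis: str, value: float, interpolate: bool = False) -> Grid:
    """Extract a 2-D slice of a 3-D grid at a concentration value.

    Nearest-plane extraction by default; linear interpolation between the
    two adjacent planes when ``interpolate`` is set.
    """
    if grid.values.ndim != 3:
        raise PhaseDiagramError("slice_3d requires a 3-D grid")
    try:
        ax = grid.dims.index(axis)
    except ValueError:
        raise PhaseDiagramError(f"unknown axis {axis!r}") from None
    coords = grid.axes[ax]
    if not coords.min() <= value <= coords.max():
        raise PhaseDiagramError(f"slice value {value} outside axis range")
    if interpolate:
        j = int(np.searchsorted(coords, value))
        j = min(max(j, 1), len(coords) - 1)
        t = (value - coords[j - 1]) / (coords[j] - coords[j - 1])
        lo = np.take(grid.values, j - 1, axis=ax)
        hi = np.take(grid.values, j, axis=ax)
        plane = (1 - t) * lo + t * hi
    else:
        j = int(np.argmin(np.abs(coords - value)))
        plane = np.take(grid.values, j, axis=ax)
    keep = [i for i in range(3) if i != ax]
    return Grid(
        dims=tuple(grid.dims[i] for i in keep),
        axes=tuple(grid.axes[i] for i in keep),
        values=plane,
    )


def bootstrap_stability(
    points: np.ndarray,
    labels: np.ndarray,
    n_boot: int,
    bounds: Sequence[tuple[float, float]] | None = None,
    resolution: int | Sequence[int] = 200,
    seed: int = 0,
    svm_params: SVMParams | None = None,
) -> StabilityReport:
    """Stability of the diagram under bootstrap resampling.

    The SVM is refit on ``n_boot`` with-replacement resamples of the points;
    ``disagreement`` is the mean over resample pairs of the fraction of grid
    cells whose thresholded (p >= 0.5) classification differs, and
    ``probability_mad`` the mean pairwise absolute probability difference.
    A resample missing one class is redrawn (at most 10 attempts).
    """
    if n_boot < 2:
        raise PhaseDiagramError("n_boot must be >= 2")
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if bounds is None:
        bounds = percentile_bounds(points)
    svm_params = svm_params or SVMParams(seed=seed)

    prob_maps = []
    n = len(points)
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) > 1:
                break
        else:
            raise PhaseDiagramError("bootstrap resample never contained both classes")
        model = fit_svm(points[idx], labels[idx], svm_params)
        grid = probability_grid(model, bounds, resolution)
        prob_maps.append(grid.values)

    maps = np.stack(prob_maps)
    calls = maps >= 0.5
    dis, mad, pairs = 0.0, 0.0, 0
    for i in range(n_boot):
        for j in range(i + 1, n_boot):
            dis += float(np.mean(calls[i] != calls[j]))
            mad += float(np.mean(np.abs(maps[i] - maps[j])))
            pairs += 1
    return StabilityReport(n_boot, dis / pairs, mad / pairs)
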