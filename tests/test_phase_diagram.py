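"""SVM phase diagrams: fitting, grids, contours, slices, stability."""

import numpy as np
import pytest

from dropphase import (
    BoundaryModel,
    Grid,
    SVMParams,
    boundary_curve,
    bootstrap_stability,
    build_phase_diagram,
    differential_map,
    fit_svm,
    ground_truth_label,
    percentile_bounds,
    probability_grid,
    slice_3d,
)
from dropphase.calibration import DropletRecord
from dropphase.phase_diagram import PhaseDiagramError
from dropphase.simulation import SEPARATED

SVM = SVMParams(seed=0)


def linear_dataset(n, flip_rate=0.0, seed=0, weights=(1.0, 0.8), intercept=-5.2):
    """Uniform 2-D compositions labelled by a linear boundary."""
    rng = np.random.default_rng(seed)
    points = rng.uniform(0.8, 4.5, size=(n, 2))
    model = BoundaryModel.linear(weights, intercept, flip_rate=flip_rate)
    labels = np.array(
        [1 if ground_truth_label(p, model, rng) == SEPARATED else 0 for p in points]
    )
    return points, labels


def two_clusters(n=200, delta=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal((0.0, 0.0), 1.0, size=(n, 2))
    b = rng.normal((delta, delta), 1.0, size=(n, 2))
    return np.vstack([a, b]), np.r_[np.zeros(n, int), np.ones(n, int)]


class TestBuild:
    def _records(self, n_sep=5, n_hom=5, dims=("protein", "crowder")):
        recs = []
        for i in range(n_sep + n_hom):
            recs.append(
                DropletRecord(
                    i,
                    {d: float(i + j) for j, d in enumerate(dims)},
                    {},
                    phase=SEPARATED if i < n_sep else "homogeneous",
                )
            )
        return recs

    def test_matrix_shape_and_labels(self):
        with pytest.warns(UserWarning, match="1500"):
            points, labels = build_phase_diagram(
                self._records(), ("protein", "crowder")
            )
        assert points.shape == (10, 2)
        assert labels.sum() == 5

    def test_missing_dimension_rejected(self):
        with pytest.raises(PhaseDiagramError):
            build_phase_diagram(self._records(), ("protein", "salt"))

    def test_single_class_rejected(self):
        with pytest.raises(PhaseDiagramError, match="not bracketed"):
            build_phase_diagram(self._records(n_hom=0), ("protein", "crowder"))

    def test_unclassified_records_dropped(self):
        recs = self._records()
        recs.append(DropletRecord(99, {"protein": 1.0, "crowder": 1.0}, {}, phase=None))
        with pytest.warns(UserWarning):
            points, _ = build_phase_diagram(recs, ("protein", "crowder"))
        assert len(points) == 10


class TestFitSvm:
    def test_separable_clusters_high_accuracy(self):
        points, labels = two_clusters()
        model = fit_svm(points, labels, SVM)
        assert (model.predict(points) == labels).mean() >= 0.99

    def test_single_class_rejected(self):
        points, _ = two_clusters()
        with pytest.raises(PhaseDiagramError):
            fit_svm(points, np.zeros(len(points), int), SVM)

    def test_zero_variance_dimension_rejected(self):
        points, labels = two_clusters()
        points[:, 1] = 3.0
        with pytest.raises(PhaseDiagramError):
            fit_svm(points, labels, SVM)

    def test_permutation_null_near_chance(self):
        # label-shuffled balanced data carries no signal: CV accuracy ~ 0.5
        from sklearn.model_selection import cross_val_score

        # intercept chosen so the two classes are balanced on the sampling box
        points, labels = linear_dataset(400, seed=3, intercept=-4.77)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        model = fit_svm(points, shuffled, SVM)
        acc = cross_val_score(model, points, shuffled, cv=5).mean()
        assert abs(acc - 0.5) <= 0.07
        # and the probability map it produces is near-uniform
        grid = probability_grid(model, percentile_bounds(points), 40)
        assert np.mean(np.abs(grid.values - 0.5)) < 0.15

    def test_reproducible_given_seed(self):
        points, labels = linear_dataset(300, flip_rate=0.05, seed=1)
        g1 = probability_grid(fit_svm(points, labels, SVM), [(1, 4), (1, 4)], 20)
        g2 = probability_grid(fit_svm(points, labels, SVM), [(1, 4), (1, 4)], 20)
        assert np.array_equal(g1.values, g2.values)


class TestGrid:
    def test_probabilities_bounded_and_confident_at_centroids(self):
        points, labels = two_clusters()
        model = fit_svm(points, labels, SVM)
        grid = probability_grid(model, [(-3, 13), (-3, 13)], 60)
        assert (grid.values >= 0).all() and (grid.values <= 1).all()
        # nearest grid nodes to the two cluster centres
        i0 = np.argmin(np.abs(grid.axes[0] - 0.0))
        i1 = np.argmin(np.abs(grid.axes[0] - 10.0))
        assert grid.values[i0, i0] < 0.1
        assert grid.values[i1, i1] > 0.9

    def test_resolution_floor(self):
        points, labels = two_clusters()
        model = fit_svm(points, labels, SVM)
        with pytest.raises(PhaseDiagramError):
            probability_grid(model, [(0, 1), (0, 1)], 1)

    def test_3d_grid_shape_contract(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (300, 3))
        labels = (pts.sum(axis=1) > 1.5).astype(int)
        model = fit_svm(pts, labels, SVM)
        grid = probability_grid(model, [(0, 1)] * 3, 12, dims=("a", "b", "c"))
        assert grid.values.shape == (12, 12, 12)
        assert len(grid.axes) == 3


class TestBoundary:
    def test_linear_boundary_recovered(self):
        # contour-to-line distance < 5% of the axis range
        points, labels = linear_dataset(2000, flip_rate=0.02, seed=5)
        model = fit_svm(points, labels, SVM)
        grid = probability_grid(model, percentile_bounds(points), 100)
        contour = boundary_curve(grid)
        assert len(contour) > 0
        w = np.array([1.0, 0.8])
        dist = np.abs(contour @ w - 5.2) / np.linalg.norm(w)
        assert dist.mean() < 0.05 * (4.5 - 0.8)

    def test_no_crossing_gives_empty_contour(self):
        grid = Grid(("a", "b"), (np.linspace(0, 1, 5),) * 2, np.full((5, 5), 0.9))
        with pytest.warns(UserWarning):
            contour = boundary_curve(grid)
        assert contour.shape == (0, 2)

    def test_contour_points_inside_grid_bounds(self):
        points, labels = linear_dataset(500, seed=2)
        model = fit_svm(points, labels, SVM)
        grid = probability_grid(model, [(0.8, 4.5), (0.8, 4.5)], 50)
        contour = boundary_curve(grid)
        assert (contour >= 0.8 - 1e-9).all() and (contour <= 4.5 + 1e-9).all()

    def test_boundary_error_shrinks_with_sample_size(self):
        # paired seeds: mean contour distance at n=2000 below that at n=200
        w = np.array([1.0, 0.8])

        def mean_dist(n, seed):
            points, labels = linear_dataset(n, flip_rate=0.02, seed=seed)
            model = fit_svm(points, labels, SVM)
            grid = probability_grid(model, [(0.8, 4.5), (0.8, 4.5)], 80)
            contour = boundary_curve(grid)
            return np.abs(contour @ w - 5.2).mean() / np.linalg.norm(w)

        small = np.mean([mean_dist(200, s) for s in range(3)])
        large = np.mean([mean_dist(2000, s) for s in range(3)])
        assert large < small

    def test_reentrant_band_recovered_with_two_crossings(self):
        rng = np.random.default_rng(8)
        points = rng.uniform(0.0, 10.0, size=(3000, 2))
        band = BoundaryModel.reentrant_band(
            axis=1, lower=(2.0, 0.0), upper=(7.0, 0.0), ndim=2
        )
        labels = np.array(
            [1 if band.evaluate(p) == SEPARATED else 0 for p in points]
        )
        model = fit_svm(points, labels, SVM)
        grid = probability_grid(model, [(0, 10), (0, 10)], 100)
        # scan the RNA-like axis at fixed protein-like value: two 0.5 crossings
        profile = grid.values[50, :]
        crossings = np.sum(np.diff(profile >= 0.5).astype(int) != 0)
        assert crossings == 2


class TestDifferential:
    def _grid(self, values):
        axes = tuple(np.linspace(0, 1, s) for s in values.shape)
        return Grid(("a", "b"), axes, values)

    def test_identical_grids_zero(self):
        g = self._grid(np.random.default_rng(0).uniform(0, 1, (10, 10)))
        assert np.allclose(differential_map(g, g).values, 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = self._grid(rng.uniform(0, 1, (10, 10)))
        b = self._grid(rng.uniform(0, 1, (10, 10)))
        assert np.allclose(
            differential_map(a, b).values, -differential_map(b, a).values
        )

    def test_bounded_in_minus_one_one(self):
        a = self._grid(np.zeros((5, 5)))
        b = self._grid(np.ones((5, 5)))
        d = differential_map(a, b)
        assert (d.values >= -1).all() and (d.values <= 1).all()

    def test_modulator_shift_positive_between_boundaries(self):
        # a modulator moving the boundary to lower concentrations makes the
        # difference positive in the band between the two boundaries
        points_a, labels_a = linear_dataset(1500, seed=1, intercept=-5.2)
        points_b, labels_b = linear_dataset(1500, seed=2, intercept=-3.6)
        bounds = [(0.8, 4.5), (0.8, 4.5)]
        grid_a = probability_grid(fit_svm(points_a, labels_a, SVM), bounds, 60)
        grid_b = probability_grid(fit_svm(points_b, labels_b, SVM), bounds, 60)
        diff = differential_map(grid_a, grid_b)
        xx, yy = np.meshgrid(grid_a.axes[0], grid_a.axes[1], indexing="ij")
        lin = xx + 0.8 * yy
        between = (lin > 3.6 + 0.4) & (lin < 5.2 - 0.4)
        assert diff.values[between].mean() > 0.5

    def test_disjoint_axes_rejected(self):
        a = Grid(("x", "y"), (np.linspace(0, 1, 5),) * 2, np.zeros((5, 5)))
        b = Grid(("x", "y"), (np.linspace(5, 6, 5),) * 2, np.zeros((5, 5)))
        with pytest.raises(PhaseDiagramError):
            differential_map(a, b)

    def test_resampling_onto_other_axes(self):
        axes_a = (np.linspace(0, 1, 11),) * 2
        axes_b = (np.linspace(0, 1, 21),) * 2
        f = lambda x, y: 0.5 * x + 0.25 * y
        a = Grid(("x", "y"), axes_a, f(*np.meshgrid(*axes_a, indexing="ij")))
        b = Grid(("x", "y"), axes_b, f(*np.meshgrid(*axes_b, indexing="ij")))
        d = differential_map(a, b)
        assert np.allclose(d.values, 0.0, atol=1e-12)


class TestSlice:
    def _grid3(self):
        axes = (np.linspace(0, 1, 6), np.linspace(0, 2, 7), np.linspace(0, 3, 8))
        rng = np.random.default_rng(0)
        return Grid(("a", "b", "c"), axes, rng.uniform(0, 1, (6, 7, 8)))

    def test_exact_plane_returned(self):
        g = self._grid3()
        s = slice_3d(g, "c", g.axes[2][4])
        assert np.array_equal(s.values, g.values[:, :, 4])
        assert s.dims == ("a", "b")

    def test_values_stay_probabilities(self):
        s = slice_3d(self._grid3(), "b", 1.0)
        assert (s.values >= 0).all() and (s.values <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(PhaseDiagramError):
            slice_3d(self._grid3(), "a", 9.0)

    def test_separated_area_monotone_along_suppressor_axis(self):
        # third component suppresses separation: slice area shrinks with it
        rng = np.random.default_rng(4)
        pts = rng.uniform(0.0, 5.0, size=(4000, 3))
        model3 = BoundaryModel.threshold_3d((1.0, 0.8), -4.0, suppression=1.2)
        labels = np.array(
            [1 if model3.evaluate(p) == SEPARATED else 0 for p in pts]
        )
        svm = fit_svm(pts, labels, SVM)
        grid = probability_grid(svm, [(0, 5)] * 3, 24, dims=("p", "c", "hd"))
        areas = [
            (slice_3d(grid, "hd", v).values >= 0.5).mean() for v in (0.5, 2.0, 4.0)
        ]
        assert areas[0] > areas[1] > areas[2]


class TestBootstrapStability:
    def test_duplicate_resamples_agree(self):
        points, labels = linear_dataset(300, seed=0)
        # deterministic check of the disagreement metric itself
        from dropphase.phase_diagram import StabilityReport

        r = StabilityReport(2, 0.0, 0.0)
        assert r.disagreement == 0.0
        model = fit_svm(points, labels, SVM)
        grid = probability_grid(model, percentile_bounds(points), 40)
        calls = grid.values >= 0.5
        assert np.mean(calls != calls) == 0.0

    def test_requires_two_resamples(self):
        points, labels = linear_dataset(100, seed=0)
        with pytest.raises(PhaseDiagramError):
            bootstrap_stability(points, labels, n_boot=1)

    def test_disagreement_shrinks_with_sample_size(self):
        small = bootstrap_stability(
            *linear_dataset(100, flip_rate=0.02, seed=10),
            n_boot=6, resolution=60, seed=0,
        )
        large = bootstrap_stability(
            *linear_dataset(1200, flip_rate=0.02, seed=10),
            n_boot=6, resolution=60, seed=0,
        )
        assert large.disagreement < small.disagreement

    def test_report_bounds_validated(self):
        from dropphase.phase_diagram import StabilityReport

        with pytest.raises(PhaseDiagramError):
            StabilityReport(2, 1.5, 0.0)
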