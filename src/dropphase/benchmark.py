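"""Default synthetic benchmark: the study conditions used for validation.

The defaults here define a single, fixed synthetic experiment emulating a
two-component protein/crowder scan: 10 µM protein stock barcoded in a green
channel, 10 %w/v crowder stock barcoded in a far-red channel, a 12x12
volume-fraction grid traversed cyclically, a linear phase boundary
c_protein + 0.8·c_crowder > 5.2, droplets of 40–55 px radius in
1024x1024 px fields, 8% / 5% channel crosstalk, puncta contrast 2x and
pixel noise such that the dimmest truly separated droplet has a barcode
signal-to-noise ratio of 20 (signal 480 counts / noise sd 24).

Two headline quantities are computed at full scale:

* end-to-end phase-classification error against the generator manifest
  (>=2000 rendered droplets per seed), and
* bootstrap stability of the SVM phase diagram at n = 1500 points with 2%
  label noise (mean thresholded-grid disagreement over 20 refits).
"""

from __future__ import annotations

import numpy as np

from .calibration import build_calibration_model
from .classification import ClassifierParams, classification_error, PhaseCall
from .detection import DetectionParams
from .phase_diagram import SVMParams, bootstrap_stability, percentile_bounds
from .pipeline import match_to_manifest, process_experiment
from .simulation import (
    BoundaryModel,
    FlowProgramme,
    OpticsSpec,
    PunctaSpec,
    grid_ramp,
    ground_truth_label,
    make_calibration_series,
    sample_compositions,
)

CHANNELS = ("ch_green", "ch_farred")
FLUOROPHORES = ("EGFP", "Alexa647")
COMPONENTS = ("protein", "crowder")
FLUOROPHORE_OF = {"protein": "EGFP", "crowder": "Alexa647"}
COMPONENT_MAP = {"EGFP": ("protein", "uM"), "Alexa647": ("crowder", "pct_w_v")}
STOCKS = {"protein": 10.0, "crowder": 10.0}
CROSSTALK = ((1.0, 0.08), (0.05, 1.0))
CALIBRATION_CONCS = (1.0, 2.5, 5.0, 7.5, 10.0)

FIELD_SHAPE = (1024, 1024)
RADIUS_RANGE = (40.0, 55.0)
DROPLETS_PER_FIELD = 35


def default_programme(n_steps: int = 12) -> FlowProgramme:
    """12x12 volume-fraction grid over protein and crowder inlets."""
    fracs = np.linspace(0.08, 0.45, n_steps)
    return FlowProgramme(
        inlet_names=("protein", "crowder", "buffer"),
        stocks=(STOCKS["protein"], STOCKS["crowder"], 0.0),
        ramp=grid_ramp(fracs, fracs),
    )


def default_boundary(flip_rate: float = 0.0) -> BoundaryModel:
    """Linear boundary: separated iff c_protein + 0.8·c_crowder > 5.2."""
    return BoundaryModel.linear((1.0, 0.8), -5.2, flip_rate=flip_rate)


def default_optics(noise_sd: float = 24.0) -> OpticsSpec:
    """Gain 300 counts per concentration unit, background 100 counts.

    noise_sd 24 puts the dimmest truly separated droplet (1.6 µM protein,
    480 counts of signal) at SNR 20.
    """
    return OpticsSpec(
        gains={"EGFP": 300.0, "Alexa647": 300.0},
        background=100.0,
        noise_sd=noise_sd,
        pixel_size=1.0,
        puncta=PunctaSpec(count_range=(1, 5), radius_range=(2.0, 4.0), contrast=2.0),
    )


def default_detection_params() -> DetectionParams:
    return DetectionParams(radius_range=(20.0, 80.0), detection_channel="sum")


def default_classifier_params() -> ClassifierParams:
    return ClassifierParams()


def default_calibration_model(seed: int = 0, noise_sd: float = 24.0):
    """Calibration model fitted to rendered single-fluorophore series."""
    optics = default_optics(noise_sd)
    series = [
        make_calibration_series(
            f, CALIBRATION_CONCS, optics, CHANNELS, FLUOROPHORES, CROSSTALK,
            seed=seed + 101 + i,
        )
        for i, f in enumerate(FLUOROPHORES)
    ]
    return build_calibration_model(series, COMPONENT_MAP, default_detection_params())


def render_benchmark(seed: int, n_droplets: int = 2000, flip_rate: float = 0.0):
    """Render the default experiment; returns (fields, manifest)."""
    from .simulation import simulate_fields

    fields, manifest = simulate_fields(
        programme=default_programme(),
        boundary=default_boundary(flip_rate),
        optics=default_optics(),
        channels=CHANNELS,
        fluorophores=FLUOROPHORES,
        crosstalk=CROSSTALK,
        fluorophore_of=FLUOROPHORE_OF,
        condensate_component="protein",
        boundary_components=COMPONENTS,
        n_droplets=n_droplets,
        field_shape=FIELD_SHAPE,
        droplets_per_field=DROPLETS_PER_FIELD,
        radius_range=RADIUS_RANGE,
        seed=seed,
    )
    return fields, manifest


def classification_benchmark(seed: int, n_droplets: int = 2000) -> dict:
    """End-to-end classification error on the default synthetic experiment.

    Renders >= ``n_droplets`` droplets (flip_rate 0), runs detection, QC,
    calibration, unmixing and the connected-pixel classifier with defaults,
    matches kept droplets to the manifest by position and returns
    (FP + FN) / N over classified droplets.
    """
    fields, manifest = render_benchmark(seed, n_droplets)
    model = default_calibration_model(seed=seed)
    records, table = process_experiment(
        [img for img, _ in fields],
        model,
        default_detection_params(),
        default_classifier_params(),
        condensate_channel="ch_green",
    )
    matched = match_to_manifest(table, manifest)
    scored = matched[matched["kept"] & matched["phase"].notna() & matched["true_label"].notna()]
    calls = [
        PhaseCall(int(r.droplet_id), r.phase, 0, 0.0, 0)
        for r in scored.itertuples()
    ]
    truth = {int(r.droplet_id): r.true_label for r in scored.itertuples()}
    error = classification_error(calls, truth)
    return {
        "error": error,
        "n_classified": len(scored),
        "n_rendered": len(manifest),
        "records": records,
        "table": matched,
    }


def stability_benchmark(
    seed: int,
    n_points: int = 1500,
    flip_rate: float = 0.02,
    n_boot: int = 20,
    resolution: int = 200,
) -> dict:
    """Bootstrap SVM-map stability at the recommended sample size.

    Draws ``n_points`` (concentration, label) pairs from the default linear
    boundary generator with 2% label noise, fits the SVM, and reports the
    mean pairwise thresholded-grid disagreement over ``n_boot`` bootstrap
    refits on a ``resolution``² grid spanning the data's percentile box.
    """
    programme = default_programme()
    boundary = default_boundary(flip_rate)
    rng = np.random.default_rng(seed)
    comps = sample_compositions(programme, n_points)
    idx = [programme.index(c) for c in COMPONENTS]
    points = comps[:, idx]
    labels = np.array(
        [
            1 if ground_truth_label(points[j], boundary, rng) == "separated" else 0
            for j in range(n_points)
        ]
    )
    report = bootstrap_stability(
        points,
        labels,
        n_boot=n_boot,
        bounds=percentile_bounds(points),
        resolution=resolution,
        seed=seed,
        svm_params=SVMParams(seed=seed),
    )
    return {
        "disagreement": report.disagreement,
        "probability_mad": report.probability_mad,
        "n": n_points,
        "n_boot": n_boot,
    }
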