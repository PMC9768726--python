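"""End-to-end processing: images -> droplet records -> phase-diagram table."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .calibration import (
    CalibrationModel,
    DropletRecord,
    measure_intensities,
    to_concentrations,
)
from .classification import ClassifierParams, classify_droplets
from .detection import DetectionParams, detect_droplets, qc_filter
from .io import ImageSet

logger = logging.getLogger(__name__)


def process_field(
    images: ImageSet,
    model: CalibrationModel,
    det_params: DetectionParams,
    clf_params: ClassifierParams,
    condensate_channel: str,
    volume_model: str = "cylinder",
    well_depth: float = 50.0,
) -> tuple[list[DropletRecord], list, pd.DataFrame]:
    """Detect, QC-filter, measure, convert and classify one field of view.

    Returns the concentration-annotated records of kept droplets, the full
    detection list, and a per-droplet table mirroring the droplets CSV.
    """
    detections = qc_filter(detect_droplets(images, det_params), det_params, images.shape)
    kept = [d for d in detections if d.kept]
    records: list[DropletRecord] = []
    if kept:
        intensities = measure_intensities(
            images, kept, volume_model, well_depth, background_droplets=detections
        )
        calls, n_skipped = classify_droplets(images, kept, clf_params, condensate_channel)
        call_by_id = {c.droplet_id: c for c in calls}
        if n_skipped:
            logger.info("%d droplets unclassifiable, excluded", n_skipped)
        for meas in intensities:
            rec = to_concentrations(meas, model)
            call = call_by_id.get(meas.droplet_id)
            if call is not None:
                rec.phase = call.label
            records.append(rec)
    rows = []
    kept_by_id = {d.droplet_id: d for d in kept}
    call_lookup = {r.droplet_id: r for r in records}
    for d in detections:
        row = {
            "droplet_id": d.droplet_id,
            "row_px": d.row,
            "col_px": d.col,
            "radius_px": d.radius,
            "circularity": d.circularity,
            "flags": ";".join(sorted(d.flags)),
            "kept": d.kept,
        }
        rec = call_lookup.get(d.droplet_id) if d.droplet_id in kept_by_id else None
        if rec is not None:
            for comp, conc in rec.concentrations.items():
                row[f"conc_{comp}"] = conc
            row["phase"] = rec.phase
        rows.append(row)
    return records, detections, pd.DataFrame(rows)


def process_experiment(
    fields: Sequence[ImageSet],
    model: CalibrationModel,
    det_params: DetectionParams | None = None,
    clf_params: ClassifierParams | None = None,
    condensate_channel: str | None = None,
    volume_model: str = "cylinder",
    well_depth: float = 50.0,
) -> tuple[list[DropletRecord], pd.DataFrame]:
    """Run the full per-field pipeline over an experiment.

    Droplet ids are made globally unique across fields.  Returns all kept
    records plus the combined droplets table (one row per detection, with a
    ``field`` column).
    """
    det_params = det_params or DetectionParams()
    clf_params = clf_params or ClassifierParams()
    if condensate_channel is None:
        condensate_channel = fields[0].channels[0]
    all_records: list[DropletRecord] = []
    tables = []
    offset = 0
    for fid, images in enumerate(fields):
        records, detections, table = process_field(
            images, model, det_params, clf_params, condensate_channel,
            volume_model, well_depth,
        )
        for r in records:
            r.droplet_id += offset
        table = table.copy()
        table["droplet_id"] += offset
        table["field"] = fid
        tables.append(table)
        all_records.extend(records)
        offset += len(detections)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["droplet_id", "field"])
    )
    n_kept = int(table["kept"].sum()) if len(table) else 0
    logger.info(
        "experiment: %d detected, %d kept, %d classified",
        len(table), n_kept, sum(r.phase is not None for r in all_records),
    )
    return all_records, table


def match_to_manifest(
    table: pd.DataFrame, manifest: pd.DataFrame, max_dist_px: float = 10.0
) -> pd.DataFrame:
    """Match detections to ground-truth manifest droplets by centre position.

    Both tables must carry ``field``, ``row_px``, ``col_px``.  Returns the
    detection table with ``true_label`` and manifest concentrations joined;
    unmatched detections get NaN truth.
    """
    out = table.copy()
    truth_cols = [c for c in manifest.columns if c.startswith("conc_")]
    out["true_label"] = pd.NA
    for c in truth_cols:
        out[f"true_{c}"] = np.nan
    for fid, sub in out.groupby("field"):
        msub = manifest[manifest["field"] == fid]
        if msub.empty or sub.empty:
            continue
        tree = cKDTree(msub[["row_px", "col_px"]].to_numpy())
        dist, idx = tree.query(sub[["row_px", "col_px"]].to_numpy())
        ok = dist <= max_dist_px
        rows = sub.index[ok]
        src = msub.iloc[idx[ok]]
        out.loc[rows, "true_label"] = src["true_label"].to_numpy()
        for c in truth_cols:
            out.loc[rows, f"true_{c}"] = src[c].to_numpy()
    return out
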