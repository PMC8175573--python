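"""End-to-end glue: simulate -> detect -> calibrate -> classify -> score.

These helpers run the whole imaging pipeline in memory.  They are what
the CLI, the acceptance script, and the end-to-end tests drive; each
stage is the corresponding module's public API, so the pipeline measures
exactly what a user running the CLI stage by stage would get.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import image_quant, io, screen_stats, state_classify, synth_screen
from .config import IntensityModel, RenderParams
from .synth_screen import CompoundEntry, PlateLayout, WellTruth

__all__ = [
    "quantify_fields",
    "simulated_enucleation_estimate",
    "run_plate_screen",
]


def _child_seeds(seed: int, n: int) -> List[int]:
    """Derive n independent 31-bit substream seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def quantify_fields(
    images: Iterable[synth_screen.FieldImage],
    min_area: int = 20,
    min_separation: int = 5,
) -> pd.DataFrame:
    """Detect objects in every field and concatenate the object tables."""
    frames = [
        image_quant.detect_objects(img, min_area=min_area, min_separation=min_separation)
        for img in images
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=image_quant.OBJECT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulated_enucleation_estimate(
    template: WellTruth,
    n_wells: int = 5,
    n_fields: int = 10,
    seed: int = 0,
    control_template: Optional[WellTruth] = None,
    n_control_wells: int = 3,
    intensity_model: Optional[IntensityModel] = None,
    render_params: Optional[RenderParams] = None,
    min_area: int = 20,
    min_separation: int = 5,
    denominator_mode: str = "methods",
) -> Dict[str, object]:
    """Recover the enucleation frequency of wells drawn from ``template``.

    Renders ``n_wells`` replicate wells plus ``n_control_wells`` DMSO
    wells (used only for threshold calibration), runs detection and
    truth-table classification, and returns per-well estimated and true
    enucleation frequencies (as fractions) together with their means.
    """
    if control_template is None:
        control_template = synth_screen.dmso_well_template(template.total_cells)
    seeds = _child_seeds(seed, n_wells + n_control_wells)

    control_objects = []
    for i in range(n_control_wells):
        truth = WellTruth(
            f"C{i + 1}",
            control_template.total_cells,
            dict(control_template.state_fractions),
            control_template.rupture_fraction,
        )
        images, _ = synth_screen.render_field_images(
            truth,
            n_fields=n_fields,
            intensity_model=intensity_model,
            render_params=render_params,
            seed=seeds[i],
            plate_id="EST",
        )
        control_objects.append(
            quantify_fields(images, min_area=min_area, min_separation=min_separation)
        )
    control_objects = pd.concat(control_objects, ignore_index=True)
    thresholds = image_quant.calibrate_thresholds(control_objects, plate_id="EST")

    est, truth_freq = [], []
    for i in range(n_wells):
        truth = WellTruth(
            f"W{i + 1}",
            template.total_cells,
            dict(template.state_fractions),
            template.rupture_fraction,
        )
        images, gt = synth_screen.render_field_images(
            truth,
            n_fields=n_fields,
            intensity_model=intensity_model,
            render_params=render_params,
            seed=seeds[n_control_wells + i],
            plate_id="EST",
        )
        objects = quantify_fields(images, min_area=min_area, min_separation=min_separation)
        calls = state_classify.classify_objects(objects, thresholds)
        counts = state_classify.count_well(calls, plate_id="EST", well=truth.well_address)
        est.append(state_classify.enucleation_frequency(counts, denominator_mode))
        gt_states = gt["state"].value_counts()
        v, e = int(gt_states.get("viable_nucleated", 0)), int(gt_states.get("enucleated", 0))
        truth_freq.append(e / (v + e) if (v + e) else float("nan"))
    return {
        "estimated": est,
        "true": truth_freq,
        "mean_estimated": float(np.nanmean(est)),
        "mean_true": float(np.nanmean(truth_freq)),
        "thresholds": thresholds,
    }


def run_plate_screen(
    layout: PlateLayout,
    library: Sequence[CompoundEntry],
    baseline: WellTruth,
    n_fields: int = 10,
    seed: int = 0,
    intensity_model: Optional[IntensityModel] = None,
    render_params: Optional[RenderParams] = None,
    min_area: int = 20,
    min_separation: int = 5,
    denominator_mode: str = "methods",
    enuc_threshold: float = screen_stats.ENUC_FOLD_THRESHOLD,
    cellnum_threshold: float = screen_stats.CELLNUM_FOLD_THRESHOLD,
) -> Dict[str, object]:
    """Simulate one plate end to end and produce its ranked hit report.

    Every non-empty well of ``layout`` is populated from ``baseline`` (with
    each test compound's true folds applied), rendered, detected, and
    classified against thresholds calibrated from the plate's own DMSO
    wells; per-well scores are normalized to the in-plate DMSO means and
    the dual hit criterion applied per compound x concentration.
    """
    by_id = {c.compound_id: c for c in library}
    wells = [w for w in layout.wells if w.role != "empty"]
    seeds = _child_seeds(seed, len(wells))

    truths: Dict[str, WellTruth] = {}
    object_tables = []
    for w, s in zip(wells, seeds):
        compound = by_id.get(w.compound_id) if w.role == "test" else None
        truth = synth_screen.sample_well_population(w, compound, baseline, seed=s)
        truths[w.well] = truth
        images, _ = synth_screen.render_field_images(
            truth,
            n_fields=n_fields,
            intensity_model=intensity_model,
            render_params=render_params,
            seed=s + 1,
            plate_id=layout.plate_id,
        )
        object_tables.append(
            quantify_fields(images, min_area=min_area, min_separation=min_separation)
        )
    objects = pd.concat(object_tables, ignore_index=True)

    platemap = io.platemap_frame([layout])
    control_wells = {w.well for w in layout.control_wells}
    thresholds = image_quant.calibrate_thresholds(
        objects[objects["well"].isin(control_wells)], plate_id=layout.plate_id
    )
    calls = state_classify.classify_objects(objects, thresholds)
    counts = state_classify.count_wells(calls)
    scores = screen_stats.well_scores(counts, platemap, denominator_mode)
    folds = screen_stats.fold_changes(scores)
    treatments = screen_stats.aggregate_treatments(folds)
    hits = screen_stats.call_hits(
        treatments, enuc_threshold=enuc_threshold, cellnum_threshold=cellnum_threshold
    )
    report = screen_stats.rank_report(hits)
    return {
        "truths": truths,
        "objects": objects,
        "thresholds": thresholds,
        "counts": counts,
        "scores": scores,
        "folds": folds,
        "treatments": treatments,
        "hits": hits,
        "report": report,
    }
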