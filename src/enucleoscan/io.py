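"""File-format helpers: plate maps, TIFF fields, ground truth, tables.

Formats
-------
* Plate map CSV: ``plate_id, well, role{test|dmso|empty}, compound_id,
  name, concentration_uM, dmso_volume_class``.
* Field images: one 16-bit grayscale TIFF per plate/well/field/channel,
  named ``{plate}_{well}_f{field:02d}_{channel}.tif``.
* Ground truth: one JSON per screen (per-well composition) plus a
  per-object CSV for oracle testing.
* Objects / counts / flow events: plain CSV; thresholds: JSON per plate.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .config import CHANNELS
from .image_quant import ChannelThresholds
from .synth_screen import FieldImage, PlateLayout, WellAssignment, WellTruth

TIFF_NAME_RE = re.compile(
    r"^(?P<plate>.+)_(?P<well>[A-Z]+\d+|[A-Za-z0-9]+)_f(?P<field>\d+)_(?P<channel>[^_]+)\.tif$"
)


def platemap_frame(layouts: Iterable[PlateLayout]) -> pd.DataFrame:
    rows = []
    for layout in layouts:
        for w in layout.wells:
            rows.append(
                {
                    "plate_id": layout.plate_id,
                    "well": w.well,
                    "role": w.role,
                    "compound_id": w.compound_id,
                    "name": w.name,
                    "concentration_uM": w.concentration_uM,
                    "dmso_volume_class": w.dmso_volume_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id",
            "well",
            "role",
            "compound_id",
            "name",
            "concentration_uM",
            "dmso_volume_class",
        ],
    )


def write_platemap(layouts: Iterable[PlateLayout], path) -> None:
    platemap_frame(layouts).to_csv(path, index=False)


def read_platemap(path) -> pd.DataFrame:
    return pd.read_csv(path)


def field_tiff_name(img: FieldImage, channel: str) -> str:
    return f"{img.plate_id}_{img.well_address}_f{img.field_index:02d}_{channel}.tif"


def write_field_tiffs(images: Iterable[FieldImage], outdir) -> List[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for img in images:
        for ch in CHANNELS:
            path = outdir / field_tiff_name(img, ch)
            tifffile.imwrite(path, img.channels[ch])
            written.append(path)
    return written


def read_field_images(directory) -> List[FieldImage]:
    """Load all field TIFFs in a directory, grouping channels per field."""
    directory = Path(directory)
    grouped: Dict[Tuple[str, str, int], Dict[str, np.ndarray]] = {}
    for path in sorted(directory.glob("*.tif")):
        m = TIFF_NAME_RE.match(path.name)
        if not m:
            continue
        key = (m["plate"], m["well"], int(m["field"]))
        grouped.setdefault(key, {})[m["channel"]] = tifffile.imread(path)
    images = []
    for (plate, well, field), channels in sorted(grouped.items()):
        missing = set(CHANNELS) - set(channels)
        if missing:
            raise ValueError(f"{plate}/{well}/f{field}: missing channels {sorted(missing)}")
        images.append(FieldImage(plate, well, field, channels))
    return images


def write_well_truths(truths: Mapping[str, Mapping[str, WellTruth]], path) -> None:
    """Ground-truth JSON: {plate_id: {well: WellTruth fields}}."""
    payload = {
        plate: {
            well: {
                "well_address": t.well_address,
                "total_cells": t.total_cells,
                "state_fractions": dict(t.state_fractions),
                "rupture_fraction": t.rupture_fraction,
            }
            for well, t in wells.items()
        }
        for plate, wells in truths.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_well_truths(path) -> Dict[str, Dict[str, WellTruth]]:
    payload = json.loads(Path(path).read_text())
    return {
        plate: {
            well: WellTruth(
                rec["well_address"],
                rec["total_cells"],
                rec["state_fractions"],
                rec.get("rupture_fraction", 0.0),
            )
            for well, rec in wells.items()
        }
        for plate, wells in payload.items()
    }


def write_thresholds(thresholds: ChannelThresholds, path) -> None:
    payload = {
        "plate_id": thresholds.plate_id,
        "method": thresholds.method,
        "cutoffs": dict(thresholds.cutoffs),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_thresholds(path) -> ChannelThresholds:
    payload = json.loads(Path(path).read_text())
    return ChannelThresholds(
        cutoffs=payload["cutoffs"],
        plate_id=payload.get("plate_id"),
        method=payload.get("method", "otsu"),
    )
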