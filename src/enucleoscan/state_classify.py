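"""Three-signal truth-table classification and per-well state counting.

Every object is called positive or negative for KuO, SYTO 16 and SYTOX
Red against plate-calibrated cutoffs; the triple maps to exactly one of
four states or debris:

====  =======  =========  ================
KuO   SYTO16   SYTOXRed   state
====  =======  =========  ================
 +       +        −       viable_nucleated
 +       −        −       enucleated
 +       +        +       dead_cell
 −       +        +       free_nucleus
====  =======  =========  ================

All other triples are debris.  The triple (KuO−, SYTO16+, SYTOXRed−) — a
membrane-intact nucleus-like object without reporter signal — is not part
of the assay's expected patterns; it defaults to debris but can be
reassigned to ``free_nucleus`` via ``kuo_negative_nucleus_as``.

The enucleation frequency supports two denominators:

* ``methods`` (default): enucleated / (viable nucleated + enucleated),
  i.e. KuO+ SYTOX Red− cells;
* ``kuo_total``: enucleated / all KuO+ events (adds KuO+ dead cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .config import CHANNELS, DEBRIS, STATES
from .image_quant import ChannelThresholds

__all__ = [
    "StateCounts",
    "classify_object",
    "classify_objects",
    "count_well",
    "count_wells",
    "enucleation_frequency",
    "COUNT_COLUMNS",
]

_TRUTH_TABLE = {
    (True, True, False): "viable_nucleated",
    (True, False, False): "enucleated",
    (True, True, True): "dead_cell",
    (False, True, True): "free_nucleus",
}

COUNT_COLUMNS = [
    "plate_id",
    "well",
    *STATES,
    DEBRIS,
    "dead_kuo_pos",
    "n_objects_total",
]


def classify_object(
    kuo: bool,
    syto16: bool,
    sytox_red: bool,
    kuo_negative_nucleus_as: str = DEBRIS,
) -> str:
    """Map one (KuO, SYTO16, SYTOXRed) positivity triple to a state.

    Total function: every one of the 8 triples maps to exactly one of the
    four states or debris.
    """
    if kuo_negative_nucleus_as not in (DEBRIS, "free_nucleus"):
        raise ValueError("kuo_negative_nucleus_as must be 'debris' or 'free_nucleus'")
    triple = (bool(kuo), bool(syto16), bool(sytox_red))
    if triple == (False, True, False):
        return kuo_negative_nucleus_as
    return _TRUTH_TABLE.get(triple, DEBRIS)


def classify_objects(
    objects: pd.DataFrame,
    thresholds: ChannelThresholds,
    kuo_negative_nucleus_as: str = DEBRIS,
) -> pd.DataFrame:
    """Call positivity against cutoffs and classify every object.

    Returns a copy of the object table with ``pos_<channel>`` boolean
    columns and a ``state`` column appended.
    """
    df = objects.copy()
    for ch in CHANNELS:
        df[f"pos_{ch}"] = df[f"mean_{ch}"].to_numpy() > thresholds.cutoffs[ch]
    df["state"] = [
        classify_object(k, s, x, kuo_negative_nucleus_as)
        for k, s, x in zip(df["pos_KuO"], df["pos_SYTO16"], df["pos_SYTOXRed"])
    ]
    return df


@dataclass(frozen=True)
class StateCounts:
    """Per-well object counts by state; the unit the screen statistics use.

    ``dead_kuo_pos`` is the KuO-positive share of dead cells — the part of
    the dead population that counts toward "KuO+ cell number".
    """

    plate_id: Optional[str]
    well: Optional[str]
    viable_nucleated: int
    enucleated: int
    dead_cell: int
    free_nucleus: int
    debris: int
    dead_kuo_pos: int
    n_objects_total: int

    def __post_init__(self) -> None:
        parts = (
            self.viable_nucleated
            + self.enucleated
            + self.dead_cell
            + self.free_nucleus
            + self.debris
        )
        if parts != self.n_objects_total:
            raise ValueError(
                f"state counts sum to {parts}, not n_objects_total={self.n_objects_total}"
            )
        if self.dead_kuo_pos > self.dead_cell:
            raise ValueError("dead_kuo_pos cannot exceed dead_cell")
        if min(
            self.viable_nucleated,
            self.enucleated,
            self.dead_cell,
            self.free_nucleus,
            self.debris,
        ) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def kuo_cell_count(self) -> int:
        """KuO+ cells: viable nucleated + enucleated + KuO+ dead."""
        return self.viable_nucleated + self.enucleated + self.dead_kuo_pos


def count_well(
    calls: pd.DataFrame,
    exclude_border: bool = True,
    plate_id: Optional[str] = None,
    well: Optional[str] = None,
) -> StateCounts:
    """Aggregate classified objects of one well into state counts.

    An empty object table yields all-zero counts.  Objects flagged
    ``touches_border`` are excluded by default (partial objects bias the
    intensity means; fields sample the well, so exclusion is unbiased).
    """
    df = calls
    if len(df):
        wells = set(df["well"].dropna().unique()) if "well" in df else set()
        if len(wells) > 1:
            raise ValueError(f"count_well expects a single well, got {sorted(wells)}")
        if well is None and wells:
            well = next(iter(wells))
        if plate_id is None and "plate_id" in df and df["plate_id"].notna().any():
            plate_id = df["plate_id"].dropna().iloc[0]
        if exclude_border and "touches_border" in df:
            df = df[~df["touches_border"].astype(bool)]
    counts = {s: 0 for s in (*STATES, DEBRIS)}
    dead_kuo_pos = 0
    if len(df):
        vc = df["state"].value_counts()
        for s in counts:
            counts[s] = int(vc.get(s, 0))
        dead = df[df["state"] == "dead_cell"]
        if "pos_KuO" in dead:
            dead_kuo_pos = int(dead["pos_KuO"].sum())
        else:
            dead_kuo_pos = len(dead)
    return StateCounts(
        plate_id=plate_id,
        well=well,
        viable_nucleated=counts["viable_nucleated"],
        enucleated=counts["enucleated"],
        dead_cell=counts["dead_cell"],
        free_nucleus=counts["free_nucleus"],
        debris=counts[DEBRIS],
        dead_kuo_pos=dead_kuo_pos,
        n_objects_total=int(len(df)),
    )


def count_wells(calls: pd.DataFrame, exclude_border: bool = True) -> pd.DataFrame:
    """Per-well state counts for a multi-well object table."""
    rows = []
    for (plate_id, well), grp in calls.groupby(["plate_id", "well"], dropna=False):
        sc = count_well(grp, exclude_border=exclude_border, plate_id=plate_id, well=well)
        rows.append(
            {
                "plate_id": sc.plate_id,
                "well": sc.well,
                **{s: getattr(sc, s) for s in STATES},
                DEBRIS: sc.debris,
                "dead_kuo_pos": sc.dead_kuo_pos,
                "n_objects_total": sc.n_objects_total,
            }
        )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def enucleation_frequency(
    counts: Union[StateCounts, Mapping[str, int]],
    denominator_mode: str = "methods",
) -> float:
    """Enucleation frequency of one well, in [0, 1].

    ``methods`` divides enucleated events by intact KuO+ cells (viable
    nucleated + enucleated); ``kuo_total`` divides by all KuO+ events,
    additionally counting KuO+ dead cells.  A zero denominator flags the
    well by returning NaN (such wells are dropped from fold computation).
    """
    if isinstance(counts, StateCounts):
        viable = counts.viable_nucleated
        enuc = counts.enucleated
        dead_kuo = counts.dead_kuo_pos
    else:
        viable = int(counts["viable_nucleated"])
        enuc = int(counts["enucleated"])
        dead_kuo = int(counts.get("dead_kuo_pos", counts.get("dead_cell", 0)))
    if denominator_mode == "methods":
        denom = viable + enuc
    elif denominator_mode == "kuo_total":
        denom = viable + enuc + dead_kuo
    else:
        raise ValueError("denominator_mode must be 'methods' or 'kuo_total'")
    if denom <= 0:
        return math.nan
    return enuc / denom
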