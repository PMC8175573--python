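"""Plate-normalized fold changes, hit calling, and the ranked hit report.

Every test well is scored relative to the mean of the DMSO control wells
on the *same plate* (matching DMSO volume class when at least two such
controls exist, pooled controls otherwise):

    enuc_fold    = well enucleation frequency / mean(control frequencies)
    cellnum_fold = well KuO+ cell count       / mean(control counts)

A compound x concentration is a hit when its enucleation fold exceeds 9.0
(strict) and its cell-number fold is at least 0.25 (inclusive) — a strong
enucleation response that is not explained by cytotoxic cell loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import DMSO_VOLUME_CLASS

__all__ = [
    "ENUC_FOLD_THRESHOLD",
    "CELLNUM_FOLD_THRESHOLD",
    "HitRecord",
    "well_scores",
    "fold_changes",
    "aggregate_treatments",
    "call_hits",
    "rank_report",
    "round_half_up",
]

ENUC_FOLD_THRESHOLD = 9.0
CELLNUM_FOLD_THRESHOLD = 0.25

SCORE_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "compound_id",
    "name",
    "concentration_uM",
    "dmso_volume_class",
    "enuc_freq",
    "kuo_cell_count",
]


@dataclass(frozen=True)
class HitRecord:
    """One compound x concentration row of the hit table."""

    name: str
    concentration_uM: float
    enuc_fold: float
    cellnum_fold: float
    is_hit: bool

    def __post_init__(self) -> None:
        if self.enuc_fold < 0 or self.cellnum_fold < 0:
            raise ValueError("folds must be non-negative")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 10.005 -> 10.01, unlike banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def well_scores(
    counts: pd.DataFrame,
    platemap: pd.DataFrame,
    denominator_mode: str = "methods",
) -> pd.DataFrame:
    """Join per-well counts with the plate map and compute per-well scores.

    Adds ``enuc_freq`` (chosen denominator mode) and ``kuo_cell_count``
    (viable nucleated + enucleated + KuO+ dead — the "KuO+ cells" axis of
    the screen scatter).
    """
    from .state_classify import enucleation_frequency

    df = counts.merge(
        platemap[
            ["plate_id", "well", "role", "compound_id", "name", "concentration_uM", "dmso_volume_class"]
        ],
        on=["plate_id", "well"],
        how="left",
        validate="one_to_one",
    )
    df["enuc_freq"] = [
        enucleation_frequency(row, denominator_mode) for _, row in df.iterrows()
    ]
    df["kuo_cell_count"] = (
        df["viable_nucleated"] + df["enucleated"] + df["dead_kuo_pos"]
    )
    return df[SCORE_COLUMNS + [c for c in df.columns if c not in SCORE_COLUMNS]]


def _control_means(controls: pd.DataFrame) -> Tuple[float, float]:
    return float(controls["enuc_freq"].mean()), float(controls["kuo_cell_count"].mean())


def fold_changes(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-well fold changes relative to same-plate DMSO control means.

    Control wells receive folds relative to the mean of their own volume
    class, so the average DMSO fold is 1 per plate by construction.  Test
    wells use controls of the volume class matching their concentration
    when that class has >= 2 valid controls, pooled controls otherwise.
    Wells with an undefined enucleation frequency are dropped with a
    warning; a plate whose control mean is zero is flagged unscorable
    (all folds NaN).
    """
    out = []
    for plate_id, plate in scores.groupby("plate_id", dropna=False):
        plate = plate.copy()
        flagged = plate["enuc_freq"].isna()
        if flagged.any():
            warnings.warn(
                f"plate {plate_id}: dropping {int(flagged.sum())} unscorable "
                "well(s) with zero denominator",
                stacklevel=2,
            )
            plate = plate[~flagged]
        controls = plate[plate["role"] == "dmso"]
        if len(controls) < 2:
            raise ValueError(
                f"plate {plate_id}: need >= 2 valid DMSO control wells, got {len(controls)}"
            )
        pooled = _control_means(controls)
        by_class = {}
        for vc, grp in controls.groupby("dmso_volume_class", dropna=False):
            if len(grp) >= 2:
                by_class[vc] = _control_means(grp)

        def _ref(row) -> Tuple[float, float]:
            if row["role"] == "dmso":
                vc = row["dmso_volume_class"]
            else:
                vc = DMSO_VOLUME_CLASS.get(row["concentration_uM"], row["dmso_volume_class"])
            return by_class.get(vc, pooled)

        refs = plate.apply(_ref, axis=1, result_type="expand")
        refs.columns = ["ref_enuc", "ref_count"]
        plate = pd.concat([plate, refs], axis=1)
        bad = (plate["ref_enuc"] <= 0) | (plate["ref_count"] <= 0)
        if bad.any():
            warnings.warn(
                f"plate {plate_id}: zero control mean — plate unscorable",
                stacklevel=2,
            )
            plate["enuc_fold"] = np.nan
            plate["cellnum_fold"] = np.nan
        else:
            plate["enuc_fold"] = plate["enuc_freq"] / plate["ref_enuc"]
            plate["cellnum_fold"] = plate["kuo_cell_count"] / plate["ref_count"]
        out.append(plate.drop(columns=["ref_enuc", "ref_count"]))
    return pd.concat(out, ignore_index=True) if out else scores.iloc[0:0]


def aggregate_treatments(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean folds per compound x concentration across replicate wells."""
    tests = folds[(folds["role"] == "test") & folds["enuc_fold"].notna()]
    agg = (
        tests.groupby(["name", "concentration_uM"], dropna=False)
        .agg(
            enuc_fold=("enuc_fold", "mean"),
            cellnum_fold=("cellnum_fold", "mean"),
            n_wells=("well", "count"),
        )
        .reset_index()
    )
    return agg


def call_hits(
    folds: Union[pd.DataFrame, Iterable[Tuple[str, float, float, float]]],
    enuc_threshold: float = ENUC_FOLD_THRESHOLD,
    cellnum_threshold: float = CELLNUM_FOLD_THRESHOLD,
) -> List[HitRecord]:
    """Apply the dual hit criterion to per-treatment fold changes.

    ``is_hit`` requires enucleation fold strictly greater than
    ``enuc_threshold`` ("more than 9.0-fold") and cell-number fold at
    least ``cellnum_threshold`` ("not <0.25-fold").
    """
    if isinstance(folds, pd.DataFrame):
        rows = [
            (r["name"], float(r["concentration_uM"]), float(r["enuc_fold"]), float(r["cellnum_fold"]))
            for _, r in folds.iterrows()
        ]
    else:
        rows = [(n, float(c), float(ef), float(cf)) for n, c, ef, cf in folds]
    records = []
    for name, conc, ef, cf in rows:
        if not (np.isfinite(ef) and np.isfinite(cf)):
            raise ValueError(f"{name} @ {conc} uM: folds must be finite")
        is_hit = (ef > enuc_threshold) and (cf >= cellnum_threshold)
        records.append(HitRecord(name, conc, ef, cf, is_hit))
    return records


def rank_report(hits: Sequence[HitRecord]) -> pd.DataFrame:
    """Ranked hit table: descending enucleation fold, ties broken by
    descending cell-number fold then name; folds rendered to 2 decimals
    (half-up)."""
    rows = [
        {
            "name": h.name,
            "concentration_uM": h.concentration_uM,
            "enucleation_fold": round_half_up(h.enuc_fold, 2),
            "cellnum_fold": round_half_up(h.cellnum_fold, 2),
            "is_hit": h.is_hit,
        }
        for h in hits
    ]
    df = pd.DataFrame(
        rows,
        columns=["name", "concentration_uM", "enucleation_fold", "cellnum_fold", "is_hit"],
    )
    if len(df):
        df = df.sort_values(
            by=["enucleation_fold", "cellnum_fold", "name"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df
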