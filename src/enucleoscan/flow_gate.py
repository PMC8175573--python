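"""Flow-cytometry-style gating of simulated events.

The validation assay stains cells with SYTO 16 (cell-permeant) and 7AAD
(cell-impermeant) and reads forward scatter (FSC) as a size surrogate:
whole cells are FSC-high, enucleated reticulocytes and free nuclei
FSC-low.  After removing sub-cellular debris below an FSC percentile
floor, events are split into FSC-low/FSC-high groups and each group is
quadrant-gated on SYTO 16 x 7AAD.  The flow enucleation efficiency is
the percentage of SYTO 16− 7AAD− events among all gated (FSC-high +
FSC-low) events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from .config import FlowSignalModel
from .image_quant import intensity_threshold

__all__ = [
    "GateResult",
    "split_fsc",
    "gate_enucleation",
    "calibrate_flow_thresholds",
]


@dataclass(frozen=True)
class GateResult:
    """Quadrant counts within the FSC-low and FSC-high groups."""

    n_events: int
    quadrants: Mapping[Tuple[str, str, str], int]
    enucleation_pct: float

    def __post_init__(self) -> None:
        if sum(self.quadrants.values()) != self.n_events:
            raise ValueError("quadrant counts must sum to the gated event count")
        if not (np.isnan(self.enucleation_pct) or 0.0 <= self.enucleation_pct <= 100.0):
            raise ValueError("enucleation_pct must lie in [0, 100]")


def split_fsc(
    events: pd.DataFrame,
    debris_floor: float = 2.0,
    split: str = "kmeans2",
    fixed_cutoff: Optional[float] = None,
    seed: int = 0,
    min_log_separation: float = 0.1,
    min_events: int = 100,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition events into (FSC-low, FSC-high) groups.

    Events below the ``debris_floor`` FSC percentile are discarded.  The
    remaining events are split by 2-means on log10(FSC) (seeded at the
    extremes, deterministic); if the two cluster centers are closer than
    ``min_log_separation`` decades the split is degenerate and a fixed
    cutoff is used instead, with a warning.
    """
    fsc = events["fsc"].to_numpy(dtype=float)
    floor_val = np.percentile(fsc, debris_floor) if len(fsc) else 0.0
    kept = events[fsc >= floor_val]
    if len(kept) < min_events:
        raise ValueError(
            f"need >= {min_events} events after debris removal, got {len(kept)}"
        )
    logf = np.log10(kept["fsc"].to_numpy(dtype=float))
    if fixed_cutoff is None:
        fixed_cutoff = FlowSignalModel().fixed_fsc_cutoff
    if split == "fixed":
        low_mask = kept["fsc"].to_numpy() <= fixed_cutoff
    elif split == "kmeans2":
        init = np.array([[logf.min()], [logf.max()]])
        with warnings.catch_warnings():
            # degenerate (empty-cluster) splits are handled by the fixed-
            # cutoff fallback below
            warnings.filterwarnings("ignore", message="One of the clusters is empty")
            centroids, labels = kmeans2(logf[:, None], init, minit="matrix", seed=seed)
        centers = centroids.ravel()
        if abs(centers[1] - centers[0]) < min_log_separation:
            warnings.warn(
                "FSC distribution not separable into two groups; "
                f"falling back to fixed cutoff {fixed_cutoff}",
                stacklevel=2,
            )
            low_mask = kept["fsc"].to_numpy() <= fixed_cutoff
        else:
            low_label = int(np.argmin(centers))
            low_mask = labels == low_label
    else:
        raise ValueError("split must be 'kmeans2' or 'fixed'")
    return kept[low_mask], kept[~low_mask]


def gate_enucleation(
    events: pd.DataFrame,
    syto16_cutoff: float,
    aad7_cutoff: float,
    debris_floor: float = 2.0,
    split: str = "kmeans2",
    fixed_cutoff: Optional[float] = None,
    seed: int = 0,
) -> GateResult:
    """Quadrant-gate events and compute the flow enucleation efficiency.

    ``enucleation_pct`` = 100 x (SYTO 16− 7AAD− events) / (all gated
    events, FSC-high + FSC-low).  A zero denominator yields NaN.
    """
    low, high = split_fsc(
        events, debris_floor=debris_floor, split=split, fixed_cutoff=fixed_cutoff, seed=seed
    )
    quadrants = {}
    double_negative = 0
    n_gated = 0
    for fsc_class, grp in (("fsc_low", low), ("fsc_high", high)):
        s16 = grp["syto16"].to_numpy(dtype=float) > syto16_cutoff
        aad = grp["aad7"].to_numpy(dtype=float) > aad7_cutoff
        for s16_sign, s16_mask in (("SYTO16+", s16), ("SYTO16-", ~s16)):
            for aad_sign, aad_mask in (("7AAD+", aad), ("7AAD-", ~aad)):
                quadrants[(fsc_class, s16_sign, aad_sign)] = int(
                    (s16_mask & aad_mask).sum()
                )
        double_negative += int((~s16 & ~aad).sum())
        n_gated += len(grp)
    pct = 100.0 * double_negative / n_gated if n_gated else float("nan")
    return GateResult(n_events=n_gated, quadrants=quadrants, enucleation_pct=pct)


def calibrate_flow_thresholds(
    reference_events: pd.DataFrame,
    method: str = "otsu",
) -> Tuple[float, float]:
    """SYTO 16 and 7AAD cutoffs from a stained reference sample (e.g. a
    DMSO-treated well), using the same mode-separation calibration as the
    imaging stage."""
    s16 = intensity_threshold(reference_events["syto16"].to_numpy(), method=method)
    aad = intensity_threshold(reference_events["aad7"].to_numpy(), method=method)
    return s16, aad
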