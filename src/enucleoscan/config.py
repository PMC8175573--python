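"""Shared constants and model-parameter containers.

The screen reads three fluorescent signals per object:

* **KuO** (Kusabira Orange) — reporter coupled to the immortalizing
  transgene; marks everything that is (or recently was) a cell of the line.
* **SYTO 16** — cell-permeant nucleic-acid dye; stains any nucleus, in
  live or dead cells.
* **SYTOX Red** — cell-impermeant nucleic-acid dye; stains nuclei of
  membrane-compromised (dead) cells and extruded nuclei.

The four biological states the screen distinguishes, and their expected
signal patterns, are encoded in :data:`STATE_CHANNEL_POSITIVITY`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

CHANNELS: Tuple[str, ...] = ("KuO", "SYTO16", "SYTOXRed")

STATES: Tuple[str, ...] = (
    "viable_nucleated",
    "enucleated",
    "dead_cell",
    "free_nucleus",
)
DEBRIS = "debris"

#: Expected dye pattern per state (imaging convention: extruded nuclei are
#: membrane-compromised, hence SYTOX Red positive).
STATE_CHANNEL_POSITIVITY: Mapping[str, Mapping[str, bool]] = {
    "viable_nucleated": {"KuO": True, "SYTO16": True, "SYTOXRed": False},
    "enucleated": {"KuO": True, "SYTO16": False, "SYTOXRed": False},
    "dead_cell": {"KuO": True, "SYTO16": True, "SYTOXRed": True},
    "free_nucleus": {"KuO": False, "SYTO16": True, "SYTOXRed": True},
}

#: Test concentrations (µM) and the DMSO volume class matched to each.
TEST_CONCENTRATIONS: Tuple[float, float] = (0.5, 10.0)
DMSO_VOLUME_CLASS: Mapping[float, str] = {0.5: "0.005%", 10.0: "0.1%"}

PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = tuple(range(1, 13))
WELLS_PER_PLATE = 96


def well_addresses() -> Tuple[str, ...]:
    """All 96 well addresses in row-major order (A1 .. H12)."""
    return tuple(f"{r}{c}" for r in PLATE_ROWS for c in PLATE_COLUMNS)


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal per-state per-channel intensity model for rendering.

    Channels that are "positive" for a state draw object amplitudes around
    ``positive_median`` counts; negative channels around
    ``negative_median``.  The camera background is a constant offset with
    additive Gaussian read noise.  Defaults give clean bimodality between
    the positive and negative modes at the default noise level.
    """

    positive_median: float = 10_000.0
    negative_median: float = 300.0
    sigma_log: float = 0.25
    background_offset: float = 200.0
    background_sigma: float = 50.0
    #: Fraction of dead cells rendered KuO-positive.  The reporter status of
    #: dead cells is not constrained by the assay design; 1.0 keeps dead
    #: cells distinguishable from free nuclei in the truth table.
    dead_kuo_positive_fraction: float = 1.0

    def validate(self) -> None:
        if self.positive_median <= self.negative_median:
            raise ValueError(
                "degenerate intensity model: positive median "
                f"({self.positive_median}) must exceed negative median "
                f"({self.negative_median})"
            )
        if self.negative_median <= 0:
            raise ValueError("negative_median must be positive")
        if self.sigma_log < 0 or self.background_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.dead_kuo_positive_fraction <= 1.0:
            raise ValueError("dead_kuo_positive_fraction must be in [0, 1]")


@dataclass(frozen=True)
class RenderParams:
    """Geometry of rendered objects (pixel units, no physical calibration)."""

    image_shape: Tuple[int, int] = (1024, 1024)
    blur_sigma: float = 1.2
    state_radius: Mapping[str, float] = field(
        default_factory=lambda: {
            "viable_nucleated": 5.0,
            "enucleated": 4.0,
            "dead_cell": 5.0,
            "free_nucleus": 3.0,
        }
    )
    radius_jitter: float = 0.4
    min_radius: float = 2.0
    #: Ruptured enucleated cells are drawn as 2-5 small dim fragments.
    fragment_radius: float = 1.2
    fragment_amplitude_scale: float = 0.5
    #: Objects are placed at least ``margin`` px inside the field so that
    #: rendered objects — including their detectable blur halo — never
    #: touch the border (fields are a sample of the well; border clipping
    #: would only bias intensity measurements).
    margin: int = 14
    min_center_distance: float = 13.0
    max_place_attempts: int = 500


#: Flow-cytometry convention for dye status per state.  Note the free-nucleus
#: convention differs from imaging: intact extruded nuclei sit in the
#: SYTO 16+ 7AAD− population on the cytometer.
FLOW_POSITIVITY: Mapping[str, Mapping[str, bool]] = {
    "viable_nucleated": {"kuo": True, "syto16": True, "aad7": False},
    "enucleated": {"kuo": True, "syto16": False, "aad7": False},
    "dead_cell": {"kuo": True, "syto16": True, "aad7": True},
    "free_nucleus": {"kuo": False, "syto16": True, "aad7": False},
}

#: States whose events are small (low forward scatter).
FSC_LOW_STATES: Tuple[str, ...] = ("enucleated", "free_nucleus")


@dataclass(frozen=True)
class FlowSignalModel:
    """Log-normal event-signal model for the flow-cytometry stage.

    FSC is a unitless size surrogate: whole cells scatter high, enucleated
    reticulocytes and free nuclei scatter low.  Dye channels reuse the
    imaging positive/negative medians.
    """

    fsc_median: Mapping[str, float] = field(
        default_factory=lambda: {
            "viable_nucleated": 10.0,
            "enucleated": 3.0,
            "dead_cell": 8.0,
            "free_nucleus": 2.0,
        }
    )
    fsc_sigma_log: float = 0.2
    positive_median: float = 10_000.0
    negative_median: float = 300.0
    sigma_log: float = 0.25
    #: Fallback FSC cutoff when the low/high split degenerates.
    fixed_fsc_cutoff: float = 5.5

    def validate(self) -> None:
        if self.positive_median <= self.negative_median:
            raise ValueError("degenerate flow model: positive <= negative")
        if any(v <= 0 for v in self.fsc_median.values()):
            raise ValueError("FSC medians must be positive")
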