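"""Synthetic enucleation-screen generator.

Emulates the study design of an imaging-based compound screen for erythroid
enucleation: 96-well plates seeded with ~10,000 immortalized erythroid
cells per well, compounds at 0.5 and 10 µM with volume-matched in-plate
DMSO controls, four cell states (viable nucleated cell, enucleated cell,
dead cell, free nucleus) whose fractions shift under treatment, and
multi-channel fluorescence fields rendered as blurred blobs over noisy
background.  Every emitter returns full ground truth so the downstream
detection/classification/scoring stages can be tested without any
external data.

Randomness: every public function takes a ``seed`` that may be an int,
a :class:`numpy.random.SeedSequence` or a ``Generator``; fixed seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (
    CHANNELS,
    DMSO_VOLUME_CLASS,
    FLOW_POSITIVITY,
    STATES,
    STATE_CHANNEL_POSITIVITY,
    TEST_CONCENTRATIONS,
    WELLS_PER_PLATE,
    FlowSignalModel,
    IntensityModel,
    RenderParams,
    well_addresses,
)

__all__ = [
    "CompoundEntry",
    "WellAssignment",
    "PlateLayout",
    "WellTruth",
    "FieldImage",
    "make_library",
    "make_plate_layouts",
    "sample_well_population",
    "render_field_images",
    "simulate_flow_events",
    "dmso_well_template",
    "treated_well_template",
    "GROUND_TRUTH_COLUMNS",
    "FLOW_EVENT_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "field_index",
    "row",
    "col",
    "state",
    "radius",
    "kuo_positive",
    "ruptured",
]

FLOW_EVENT_COLUMNS = ["fsc", "syto16", "aad7", "kuo", "true_state"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CompoundEntry:
    """One library compound with its true (simulated) effect sizes.

    ``true_enuc_fold`` multiplies the baseline enucleated fraction;
    ``true_cellnum_fold`` multiplies the baseline seeded cell number.
    A null compound has both folds near 1.
    """

    compound_id: str
    name: str
    true_enuc_fold: float
    true_cellnum_fold: float
    library_tag: str = "synthetic"

    def __post_init__(self) -> None:
        if self.true_enuc_fold <= 0 or self.true_cellnum_fold <= 0:
            raise ValueError(
                f"compound {self.name!r}: true folds must be positive"
            )


@dataclass(frozen=True)
class WellAssignment:
    """Treatment of one well: a compound at a concentration, a DMSO
    control of a given volume class, or an unused (empty) well."""

    well: str
    role: str  # "test" | "dmso" | "empty"
    compound_id: Optional[str] = None
    name: Optional[str] = None
    concentration_uM: Optional[float] = None
    dmso_volume_class: Optional[str] = None


@dataclass(frozen=True)
class PlateLayout:
    plate_id: str
    wells: Tuple[WellAssignment, ...]

    def __post_init__(self) -> None:
        if len(self.wells) > WELLS_PER_PLATE:
            raise ValueError("a plate holds at most 96 wells")
        addresses = [w.well for w in self.wells]
        if len(set(addresses)) != len(addresses):
            raise ValueError("well addresses must be unique within a plate")

    @property
    def control_wells(self) -> Tuple[WellAssignment, ...]:
        return tuple(w for w in self.wells if w.role == "dmso")

    @property
    def test_wells(self) -> Tuple[WellAssignment, ...]:
        return tuple(w for w in self.wells if w.role == "test")


@dataclass(frozen=True)
class WellTruth:
    """Ground-truth composition of one well.

    ``state_fractions`` are the expected fractions of the four states among
    all objects present; ``rupture_fraction`` is the fraction of enucleated
    objects rendered as fragmented (damaged) events.
    """

    well_address: str
    total_cells: int
    state_fractions: Mapping[str, float]
    rupture_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.total_cells < 0:
            raise ValueError("total_cells must be non-negative")
        if set(self.state_fractions) != set(STATES):
            raise ValueError(f"state_fractions must have keys {STATES}")
        total = sum(self.state_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total!r}, not 1")
        if any(not 0.0 <= f <= 1.0 for f in self.state_fractions.values()):
            raise ValueError("state fractions must lie in [0, 1]")
        if not 0.0 <= self.rupture_fraction <= 1.0:
            raise ValueError("rupture_fraction must lie in [0, 1]")

    def fraction_vector(self) -> np.ndarray:
        return np.array([self.state_fractions[s] for s in STATES], float)


@dataclass(frozen=True)
class FieldImage:
    """One imaged field: a 16-bit grayscale array per channel."""

    plate_id: str
    well_address: str
    field_index: int
    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")


# ---------------------------------------------------------------------------
# study-condition presets (cytospin-count-scale compositions)

#: DMSO control composition: ~4% enucleated events, trace dead cells and
#: free nuclei from spontaneous death/enucleation.
DMSO_STATE_FRACTIONS: Mapping[str, float] = {
    "viable_nucleated": 0.94,
    "enucleated": 0.04,
    "dead_cell": 0.01,
    "free_nucleus": 0.01,
}

#: HDACi-treated composition: ~23% enucleated events.
TREATED_STATE_FRACTIONS: Mapping[str, float] = {
    "viable_nucleated": 0.75,
    "enucleated": 0.23,
    "dead_cell": 0.01,
    "free_nucleus": 0.01,
}


def dmso_well_template(total_cells: int = 10_000, well: str = "DMSO") -> WellTruth:
    """Baseline vehicle-control well (~4% enucleated)."""
    return WellTruth(well, total_cells, dict(DMSO_STATE_FRACTIONS))


def treated_well_template(total_cells: int = 10_000, well: str = "TREATED") -> WellTruth:
    """Effective-HDACi-treated well (~23% enucleated)."""
    return WellTruth(well, total_cells, dict(TREATED_STATE_FRACTIONS))


# ---------------------------------------------------------------------------
# operations


def make_library(
    n_compounds: int,
    hit_spec: Sequence[Tuple[str, float, float]] = (),
    seed=0,
    toxic_fraction: float = 0.03,
) -> List[CompoundEntry]:
    """Build a compound library with known true effects.

    Entries named in ``hit_spec`` (``(name, true_enuc_fold,
    true_cellnum_fold)``) carry exactly the given folds; the remaining
    compounds are nulls with folds near 1, except for a small toxic tail
    with strongly reduced cell-number fold.
    """
    if n_compounds < len(hit_spec):
        raise ValueError("n_compounds must be >= len(hit_spec)")
    for name, ef, cf in hit_spec:
        if ef <= 0 or cf <= 0:
            raise ValueError(f"hit_spec entry {name!r}: folds must be positive")
    rng = _rng(seed)
    entries: List[CompoundEntry] = []
    for i, (name, ef, cf) in enumerate(hit_spec):
        entries.append(CompoundEntry(f"CMPD-{i:04d}", name, float(ef), float(cf)))
    for i in range(len(hit_spec), n_compounds):
        enuc_fold = float(np.exp(rng.normal(0.0, 0.05)))
        if rng.random() < toxic_fraction:
            cellnum_fold = float(rng.uniform(0.02, 0.15))
        else:
            cellnum_fold = float(np.exp(rng.normal(0.0, 0.08)))
        entries.append(
            CompoundEntry(f"CMPD-{i:04d}", f"compound-{i:04d}", enuc_fold, cellnum_fold)
        )
    return entries


def make_plate_layouts(
    library: Sequence[CompoundEntry],
    controls_per_plate: int = 8,
    seed=0,
    concentrations: Sequence[float] = TEST_CONCENTRATIONS,
) -> List[PlateLayout]:
    """Lay a library out on 96-well plates.

    Every compound appears at every test concentration; each plate carries
    its own DMSO controls split evenly between the volume classes matching
    the test concentrations (at least 2 per class, so the per-plate control
    mean is defined).  Unused wells on the last plate are tagged empty.
    """
    if not library:
        raise ValueError("library too small to fill any plate")
    ids = [c.compound_id for c in library]
    if len(set(ids)) != len(ids):
        raise ValueError("compound_id values must be unique within a library")
    n_classes = len(concentrations)
    if controls_per_plate < 2 * n_classes:
        raise ValueError(
            f"need >= 2 DMSO controls per volume class "
            f"({2 * n_classes} total for {n_classes} concentrations)"
        )
    capacity = WELLS_PER_PLATE - controls_per_plate
    if capacity < 1:
        raise ValueError("controls_per_plate leaves no test wells")

    rng = _rng(seed)
    pairs = [(c, conc) for c in library for conc in concentrations]
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    addresses = well_addresses()
    layouts: List[PlateLayout] = []
    for start in range(0, len(pairs), capacity):
        chunk = pairs[start : start + capacity]
        plate_id = f"P{len(layouts) + 1:03d}"
        control_pos = set(
            rng.choice(WELLS_PER_PLATE, size=controls_per_plate, replace=False).tolist()
        )
        # alternate classes so each gets controls_per_plate / n_classes wells
        classes = [
            DMSO_VOLUME_CLASS.get(concentrations[i % n_classes], f"class{i % n_classes}")
            for i in range(controls_per_plate)
        ]
        wells: List[WellAssignment] = []
        ctrl_i = 0
        test_iter = iter(chunk)
        for pos, addr in enumerate(addresses):
            if pos in control_pos:
                wells.append(
                    WellAssignment(addr, "dmso", dmso_volume_class=classes[ctrl_i])
                )
                ctrl_i += 1
                continue
            try:
                compound, conc = next(test_iter)
            except StopIteration:
                wells.append(WellAssignment(addr, "empty"))
                continue
            wells.append(
                WellAssignment(
                    addr,
                    "test",
                    compound_id=compound.compound_id,
                    name=compound.name,
                    concentration_uM=float(conc),
                    dmso_volume_class=DMSO_VOLUME_CLASS.get(float(conc)),
                )
            )
        layouts.append(PlateLayout(plate_id, tuple(wells)))
    return layouts


def sample_well_population(
    layout_entry: WellAssignment,
    compound: Optional[CompoundEntry],
    baseline: WellTruth,
    seed=0,
    max_enuc_fraction: float = 0.95,
) -> WellTruth:
    """Draw the ground-truth population of one well.

    Total cell number is Poisson around ``baseline.total_cells *
    true_cellnum_fold``; the enucleated fraction is the baseline fraction
    times ``true_enuc_fold`` (clamped to ``max_enuc_fraction``), with the
    other state fractions rescaled proportionally.  DMSO and empty wells
    use folds of 1.  A baseline enucleated fraction of 0 stays 0 under any
    fold.
    """
    if baseline.total_cells <= 0:
        raise ValueError("baseline total_cells must be positive")
    rng = _rng(seed)
    if compound is None or layout_entry.role != "test":
        enuc_fold = cellnum_fold = 1.0
    else:
        enuc_fold = compound.true_enuc_fold
        cellnum_fold = compound.true_cellnum_fold

    total = int(rng.poisson(baseline.total_cells * cellnum_fold))
    base_enuc = baseline.state_fractions["enucleated"]
    enuc = min(max(base_enuc * enuc_fold, 0.0), max_enuc_fraction)
    if base_enuc >= 1.0:
        scale = 0.0
    else:
        scale = (1.0 - enuc) / (1.0 - base_enuc)
    fractions = {
        s: baseline.state_fractions[s] * scale for s in STATES if s != "enucleated"
    }
    fractions["enucleated"] = enuc
    norm = sum(fractions.values())
    fractions = {s: f / norm for s, f in fractions.items()}
    return WellTruth(
        layout_entry.well, total, fractions, baseline.rupture_fraction
    )


class _PlacementGrid:
    """Uniform rejection sampler enforcing a minimum center distance."""

    def __init__(self, shape, min_distance: float, margin: int):
        self.shape = shape
        self.min_distance = float(min_distance)
        self.margin = margin
        self.cell = max(self.min_distance, 1.0)
        self.buckets: dict = {}

    def _key(self, r: float, c: float) -> Tuple[int, int]:
        return (int(r // self.cell), int(c // self.cell))

    def _ok(self, r: float, c: float) -> bool:
        kr, kc = self._key(r, c)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for (pr, pc) in self.buckets.get((kr + dr, kc + dc), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < self.min_distance**2:
                        return False
        return True

    def sample(self, rng: np.random.Generator, attempts: int) -> Tuple[float, float]:
        lo_r, hi_r = self.margin, self.shape[0] - 1 - self.margin
        lo_c, hi_c = self.margin, self.shape[1] - 1 - self.margin
        if hi_r <= lo_r or hi_c <= lo_c:
            raise ValueError("image too small for the placement margin")
        for _ in range(attempts):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if self._ok(r, c):
                self.buckets.setdefault(self._key(r, c), []).append((r, c))
                return r, c
        raise RuntimeError(
            "could not place object: field too crowded for min_center_distance"
        )


def _draw_disk(img: np.ndarray, r0: float, c0: float, radius: float, amplitude: float) -> None:
    rad = int(np.ceil(radius))
    r_lo = max(int(np.floor(r0)) - rad, 0)
    r_hi = min(int(np.ceil(r0)) + rad + 1, img.shape[0])
    c_lo = max(int(np.floor(c0)) - rad, 0)
    c_hi = min(int(np.ceil(c0)) + rad + 1, img.shape[1])
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    img[r_lo:r_hi, c_lo:c_hi][mask] += amplitude


def render_field_images(
    truth: WellTruth,
    n_fields: int = 50,
    image_shape: Optional[Tuple[int, int]] = None,
    intensity_model: Optional[IntensityModel] = None,
    render_params: Optional[RenderParams] = None,
    seed=0,
    plate_id: str = "SIM",
) -> Tuple[List[FieldImage], pd.DataFrame]:
    """Render one well as ``n_fields`` multi-channel 16-bit field images.

    Cells are allocated to fields multinomially (the rendered fields are
    treated as a census of the well, so ground-truth counts are conserved
    exactly).  Each object is a Gaussian-blurred disk whose per-channel
    amplitude follows the state's expected dye pattern; a
    ``truth.rupture_fraction`` share of enucleated objects is drawn as 2-5
    small dim fragments instead of one disk.

    Returns the images and a per-object ground-truth table with columns
    ``field_index, row, col, state, radius, kuo_positive, ruptured``
    (one row per object, fragments included under their parent).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    model = intensity_model or IntensityModel()
    model.validate()
    params = render_params or RenderParams()
    shape = tuple(image_shape) if image_shape is not None else params.image_shape

    rng = _rng(seed)
    state_counts = rng.multinomial(truth.total_cells, truth.fraction_vector())
    state_codes = np.repeat(np.arange(len(STATES)), state_counts)
    rng.shuffle(state_codes)
    field_of = rng.integers(0, n_fields, size=truth.total_cells)

    images: List[FieldImage] = []
    records: List[dict] = []
    for f in range(n_fields):
        codes = state_codes[field_of == f]
        chan = {ch: np.zeros(shape, dtype=np.float64) for ch in CHANNELS}
        grid = _PlacementGrid(shape, params.min_center_distance, params.margin)
        for code in codes:
            state = STATES[code]
            r0, c0 = grid.sample(rng, params.max_place_attempts)
            radius = max(
                params.state_radius[state] + rng.normal(0.0, params.radius_jitter),
                params.min_radius,
            )
            positivity = dict(STATE_CHANNEL_POSITIVITY[state])
            if state == "dead_cell":
                positivity["KuO"] = bool(
                    rng.random() < model.dead_kuo_positive_fraction
                )
            amplitudes = {}
            for ch in CHANNELS:
                median = (
                    model.positive_median if positivity[ch] else model.negative_median
                )
                amplitudes[ch] = median * float(np.exp(rng.normal(0.0, model.sigma_log)))
            ruptured = state == "enucleated" and rng.random() < truth.rupture_fraction
            if ruptured:
                n_frag = int(rng.integers(2, 6))
                for _ in range(n_frag):
                    angle = rng.uniform(0, 2 * np.pi)
                    dist = rng.uniform(0.5, 1.5) * radius
                    fr = np.clip(r0 + dist * np.sin(angle), 1, shape[0] - 2)
                    fc = np.clip(c0 + dist * np.cos(angle), 1, shape[1] - 2)
                    for ch in CHANNELS:
                        _draw_disk(
                            chan[ch],
                            fr,
                            fc,
                            params.fragment_radius,
                            amplitudes[ch] * params.fragment_amplitude_scale,
                        )
            else:
                for ch in CHANNELS:
                    _draw_disk(chan[ch], r0, c0, radius, amplitudes[ch])
            records.append(
                {
                    "field_index": f,
                    "row": r0,
                    "col": c0,
                    "state": state,
                    "radius": radius,
                    "kuo_positive": positivity["KuO"],
                    "ruptured": ruptured,
                }
            )
        rendered = {}
        for ch in CHANNELS:
            img = gaussian_filter(chan[ch], params.blur_sigma)
            img += model.background_offset
            if model.background_sigma > 0:
                img += rng.normal(0.0, model.background_sigma, size=shape)
            rendered[ch] = np.rint(np.clip(img, 0, 65535)).astype(np.uint16)
        images.append(FieldImage(plate_id, truth.well_address, f, rendered))

    table = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return images, table


def simulate_flow_events(
    truth: WellTruth,
    n_events: int,
    signal_model: Optional[FlowSignalModel] = None,
    seed=0,
) -> pd.DataFrame:
    """Draw flow-cytometer events from a well's ground-truth composition.

    Returns a table with one row per event (columns ``fsc, syto16, aad7,
    kuo, true_state``).  Signals are log-normal around state medians; dye
    positivity follows the flow convention (intact free nuclei are
    7AAD-negative, dead cells 7AAD-positive).
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    model = signal_model or FlowSignalModel()
    model.validate()
    if n_events == 0:
        return pd.DataFrame(columns=FLOW_EVENT_COLUMNS)
    rng = _rng(seed)
    states = rng.choice(len(STATES), size=n_events, p=truth.fraction_vector())
    fsc = np.empty(n_events)
    dye = {sig: np.empty(n_events) for sig in ("syto16", "aad7", "kuo")}
    for code, state in enumerate(STATES):
        idx = np.flatnonzero(states == code)
        if idx.size == 0:
            continue
        fsc[idx] = model.fsc_median[state] * np.exp(
            rng.normal(0.0, model.fsc_sigma_log, size=idx.size)
        )
        for sig in ("syto16", "aad7", "kuo"):
            median = (
                model.positive_median
                if FLOW_POSITIVITY[state][sig]
                else model.negative_median
            )
            dye[sig][idx] = median * np.exp(
                rng.normal(0.0, model.sigma_log, size=idx.size)
            )
    return pd.DataFrame(
        {
            "fsc": fsc,
            "syto16": dye["syto16"],
            "aad7": dye["aad7"],
            "kuo": dye["kuo"],
            "true_state": [STATES[c] for c in states],
        },
        columns=FLOW_EVENT_COLUMNS,
    )
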