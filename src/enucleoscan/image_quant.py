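"""Object detection and per-channel intensity quantification.

Detection runs on the pixel-wise maximum across channels so that objects
visible in any single channel (KuO-only enucleated cells, SYTO-only free
nuclei) are all found.  Touching objects are split by marker-based
watershed seeded at intensity local maxima.  Per-object mean intensities
are measured per channel after subtracting a per-image median background,
which makes them invariant to constant illumination offsets.

Per-channel positive/negative cutoffs are calibrated from the objects of
a plate's own DMSO control wells (mirroring the screen's in-plate
normalization design), by Otsu's method on log-intensities or a
quantile-midpoint rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .config import CHANNELS
from .synth_screen import FieldImage

__all__ = [
    "CalibrationError",
    "ChannelThresholds",
    "OBJECT_COLUMNS",
    "detect_objects",
    "calibrate_thresholds",
    "intensity_threshold",
]

OBJECT_COLUMNS = (
    ["plate_id", "well", "field_index", "row", "col", "area", "touches_border"]
    + [f"mean_{ch}" for ch in CHANNELS]
    + [f"integrated_{ch}" for ch in CHANNELS]
)


class CalibrationError(RuntimeError):
    """Raised when a channel has no separable intensity modes."""


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel positive/negative cutoffs (linear intensity counts)."""

    cutoffs: Mapping[str, float]
    plate_id: Optional[str] = None
    method: str = "otsu"

    def __post_init__(self) -> None:
        for ch, cut in self.cutoffs.items():
            if cut <= 0:
                raise ValueError(f"cutoff for {ch} must be strictly positive")


def _channel_arrays(image: Union[FieldImage, Mapping[str, np.ndarray]]):
    channels = image.channels if isinstance(image, FieldImage) else image
    arrays = {ch: np.asarray(channels[ch], dtype=np.float64) for ch in channels}
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: { {ch: a.shape for ch, a in arrays.items()} }")
    return arrays


def detect_objects(
    image: Union[FieldImage, Mapping[str, np.ndarray]],
    min_area: int = 20,
    min_separation: int = 5,
    smooth_sigma: float = 1.0,
    threshold_nsigma: float = 6.0,
    min_contrast: float = 50.0,
) -> pd.DataFrame:
    """Detect objects in one field and measure per-channel intensities.

    Foreground is everything above ``median + max(threshold_nsigma * sigma,
    min_contrast)`` of the smoothed cross-channel maximum, where sigma is a
    robust (MAD-based) noise estimate; the ``min_contrast`` floor keeps
    masks compact on (near-)noiseless images, where the noise estimate
    collapses and the mask would otherwise swallow the whole blur skirt.
    Connected foreground is split at intensity maxima at least
    ``min_separation`` px apart.  Objects smaller than ``min_area``
    px are dropped; objects whose mask touches the field border are kept
    but flagged ``touches_border`` (the counting stage excludes them).

    Returns one row per object with 0-based ``(row, col)`` centroids and
    background-subtracted mean and integrated intensities per channel.
    """
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    arrays = _channel_arrays(image)
    if isinstance(image, FieldImage):
        plate_id, well, field_index = image.plate_id, image.well_address, image.field_index
    else:
        plate_id, well, field_index = None, None, 0

    stack = np.stack([arrays[ch] for ch in arrays])
    composite = stack.max(axis=0)
    smoothed = ndi.gaussian_filter(composite, smooth_sigma)

    bg = float(np.median(smoothed))
    sigma = 1.4826 * float(np.median(np.abs(smoothed - bg)))
    thresh = bg + max(threshold_nsigma * sigma, min_contrast)
    mask = smoothed > thresh

    empty = pd.DataFrame(columns=OBJECT_COLUMNS)
    if not mask.any():
        return empty

    labels, n_blobs = ndi.label(mask)
    peaks = peak_local_max(
        smoothed, min_distance=int(min_separation), labels=labels, exclude_border=False
    )
    if len(peaks) == 0:
        return empty
    markers = np.zeros_like(labels)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    segmented = watershed(-smoothed, markers, mask=mask)

    channel_bg = {ch: float(np.median(arrays[ch])) for ch in arrays}
    nrows, ncols = composite.shape
    objects = ndi.find_objects(segmented)
    rows = []
    for label_idx, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        region = segmented[slc] == label_idx
        area = int(region.sum())
        if area < min_area:
            continue
        rr, cc = np.nonzero(region)
        rr = rr + slc[0].start
        cc = cc + slc[1].start
        touches = bool(
            rr.min() == 0 or cc.min() == 0 or rr.max() == nrows - 1 or cc.max() == ncols - 1
        )
        rec = {
            "plate_id": plate_id,
            "well": well,
            "field_index": field_index,
            "row": float(rr.mean()),
            "col": float(cc.mean()),
            "area": area,
            "touches_border": touches,
        }
        for ch, arr in arrays.items():
            vals = arr[rr, cc]
            rec[f"mean_{ch}"] = float(vals.mean() - channel_bg[ch])
            rec[f"integrated_{ch}"] = float(vals.sum() - channel_bg[ch] * area)
        rows.append(rec)
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def _two_means_1d(values: np.ndarray, n_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D 2-means labels (0 = low mode, 1 = high mode)."""
    lo, hi = float(values.min()), float(values.max())
    centers = np.array([lo, hi])
    labels = np.zeros(values.shape, dtype=int)
    for _ in range(n_iter):
        new_labels = (np.abs(values - centers[1]) < np.abs(values - centers[0])).astype(int)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in (0, 1):
            sel = values[labels == k]
            if sel.size:
                centers[k] = sel.mean()
    return labels


def intensity_threshold(
    values: Sequence[float],
    method: str = "otsu",
    min_separation_score: float = 2.0,
    nbins: int = 256,
) -> float:
    """Positive/negative cutoff for one channel from reference intensities.

    Works in log10 space.  ``otsu`` maximizes between-class variance over a
    256-bin histogram; ``quantile_midpoint`` takes the geometric mean of the
    10th percentile of the high mode and the 90th percentile of the low
    mode (modes seeded by 1-D 2-means).  Raises :class:`CalibrationError`
    when the channel is constant or the two sides of the cut are not
    separated by at least ``min_separation_score`` pooled standard
    deviations — the sign of a unimodal channel needing a manual cutoff.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        raise CalibrationError("no reference intensities supplied")
    logv = np.log10(np.clip(vals, 1.0, None))
    if logv.max() - logv.min() < 1e-9:
        raise CalibrationError(
            "constant channel intensities: cannot calibrate, supply a manual cutoff"
        )
    if method == "otsu":
        t = float(threshold_otsu(logv, nbins=nbins))
        # threshold_otsu returns the *center* of the last background bin;
        # snap to that bin's upper edge so the value partition matches the
        # histogram partition the objective was maximized over, then
        # recenter the cut in the margin between the two modes (the
        # objective is flat across the empty gap and its argmax hugs one
        # mode, which generalizes poorly to unseen objects).  Both steps
        # preserve the maximizing partition.
        edges = np.histogram_bin_edges(logv, bins=nbins)
        t_edge = float(edges[min(np.searchsorted(edges, t, side="right"), nbins)])
        low_side = logv[logv < t_edge]
        high_side = logv[logv >= t_edge]
        if low_side.size and high_side.size:
            t = 0.5 * (float(low_side.max()) + float(high_side.min()))
    elif method == "quantile_midpoint":
        labels = _two_means_1d(logv)
        lo_mode, hi_mode = logv[labels == 0], logv[labels == 1]
        if lo_mode.size == 0 or hi_mode.size == 0:
            raise CalibrationError("mode seeding failed: supply a manual cutoff")
        t = 0.5 * (
            float(np.quantile(hi_mode, 0.10)) + float(np.quantile(lo_mode, 0.90))
        )  # arithmetic mean in log space == geometric mean in linear space
    else:
        raise ValueError(f"unknown method {method!r}")

    low, high = logv[logv <= t], logv[logv > t]
    if low.size == 0 or high.size == 0:
        raise CalibrationError(
            "all intensities fall on one side of the cut: supply a manual cutoff"
        )
    spread = float(low.std() + high.std())
    separation = (float(high.mean()) - float(low.mean())) / max(spread, 1e-12)
    if separation < min_separation_score:
        raise CalibrationError(
            f"channel modes not separable (score {separation:.2f} < "
            f"{min_separation_score}): supply a manual cutoff"
        )
    return float(10.0**t)


def calibrate_thresholds(
    control_objects: pd.DataFrame,
    method: str = "otsu",
    min_objects: int = 50,
    plate_id: Optional[str] = None,
) -> ChannelThresholds:
    """Calibrate per-channel cutoffs from a plate's DMSO-well objects.

    ``control_objects`` is the object table (from :func:`detect_objects`)
    of all DMSO control wells of one plate.  Each channel's cutoff
    separates the low and high intensity populations among those objects.
    """
    if len(control_objects) < min_objects:
        raise CalibrationError(
            f"need at least {min_objects} control objects, got {len(control_objects)}"
        )
    cutoffs = {}
    for ch in CHANNELS:
        cutoffs[ch] = intensity_threshold(
            control_objects[f"mean_{ch}"].to_numpy(), method=method
        )
    return ChannelThresholds(cutoffs=cutoffs, plate_id=plate_id, method=method)
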