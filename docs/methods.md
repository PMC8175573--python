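# Methods

This note records the models behind `enucleoscan`, the defaults and why
they were chosen, and what the synthetic data does and does not emulate.

## The screen model

One well holds a population of objects in four states — viable nucleated
cells, enucleated cells (reticulocyte-like, KuO+ but DNA-dye negative),
dead cells, and free (extruded) nuclei — plus debris.  The assay observes
three fluorescent signals per object (KuO reporter, SYTO 16, SYTOX Red);
each state has a characteristic positive/negative pattern, and state
assignment is a total function of the three positivity calls (every one of
the 8 patterns maps to exactly one state or debris).

Two patterns are genuinely ambiguous in the assay design and are handled
explicitly:

- **(KuO−, S16+, SX−)** — a membrane-intact nucleus-like object without
  reporter signal — is not among the expected patterns.  Default: debris;
  `kuo_negative_nucleus_as="free_nucleus"` reassigns it.
- **Dead-cell KuO status** is not constrained by the assay.  The simulator
  renders dead cells KuO+ by default
  (`IntensityModel.dead_kuo_positive_fraction = 1.0`); lowering the
  fraction produces KuO− dead objects, which the truth table necessarily
  calls free nuclei.  Only KuO+ dead cells count toward the "KuO+ cell
  number" used by the screen statistic.

### Enucleation frequency

Two denominators are implemented because the assay description itself uses
two:

- `methods` (default): enucleated / (viable nucleated + enucleated) —
  i.e., KuO+ SYTOX Red− cells;
- `kuo_total`: enucleated / all KuO+ events (adds KuO+ dead cells).

`methods` is the default because it is the more precisely stated formula;
the two agree except in wells with substantial KuO+ death, where `methods`
is always ≥ `kuo_total` (a tested invariant).

### Plate normalization and hit calling

Folds are computed strictly within plate, against the mean of that plate's
DMSO control wells — controls of the volume class matched to the test
concentration (0.5 µM ↔ 0.005%, 10 µM ↔ 0.1%) when at least two such
wells are valid, pooled controls otherwise.  DMSO wells are scored against
their own class mean, so the average DMSO fold is exactly 1 per plate.
The hit rule is `enuc_fold > 9.0` (strict) **and** `cellnum_fold ≥ 0.25`
(inclusive); the fold entering the rule is the frequency fold, with the
count-based fold available as an auxiliary column.  Each compound ×
concentration is an independent row; nothing is aggregated across
concentrations.  Wells with an undefined frequency (zero denominator) are
dropped with a warning, never imputed; a plate with a zero control mean is
flagged entirely unscorable.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

- **Scale**: 10,000 cells seeded per well (Poisson-varied), 96-well plates,
  compounds at 0.5 and 10 µM, ≥2 DMSO controls per volume class per plate.
  The volume classes are layout tags only; they have no effect on truth.
- **Condition presets**: DMSO composition
  (viable/enucleated/dead/free nucleus = 0.94/0.04/0.01/0.01) and treated
  composition (0.75/0.23/0.01/0.01).  The enucleated fractions are the two
  morphologically counted frequencies the screen is anchored to (≈4% for
  vehicle, ≈23% for an effective HDAC inhibitor); the 1% dead and free
  nucleus fractions are a modeling choice representing trace spontaneous
  death, kept small so that the enucleated fraction among *intact* cells
  (the `methods` statistic, 4.1% and 23.5% under these presets) stays
  within half a point of the nominal compositions.
- **Compound effects** multiply the baseline enucleated fraction (clamped
  at 0.95, with the other fractions rescaled proportionally) and the
  seeded cell number.  Null compounds draw folds log-normally around 1
  (σ=0.05 / 0.08); 3% of nulls are "toxic" with cell-number folds of
  0.02–0.15, giving hit-calling something to reject.
- **Rendering**: the captured fields are treated as a census of the well —
  cells are allocated to fields multinomially, so ground-truth counts are
  conserved exactly and every downstream count is testable.  Objects are
  uniform-random placed with a minimum center distance (13 px) and a 14 px
  border margin (so no rendered object, including its blur halo, touches
  the field border), drawn as disks (state-dependent radii 3–5 px ± 0.4
  jitter), Gaussian-blurred (σ=1.2), over a constant background offset
  (200 counts) with Gaussian read noise (σ=50).  Per-state per-channel
  amplitudes are log-normal: positive channels median 10,000 counts,
  negative channels median 300, σ_log=0.25 — cleanly bimodal at default
  noise.
- **Rupture**: a configurable fraction of enucleated objects is rendered
  as 2–5 small dim fragments (radius ~1.2 px, half amplitude) instead of
  one disk, emulating membrane-fragile enucleated cells breaking up.
  Rupture affects only rendering/detection; it is not a fifth classified
  state, and the condition presets default to `rupture_fraction = 0`
  because the preset fractions describe enucleated *events*, with damage
  historically assessed on cytospin slides rather than in the screen.
- **Flow events**: log-normal signals around state medians.  FSC medians
  10 / 3 / 8 / 2 (viable / enucleated / dead / free nucleus), σ_log=0.2;
  dye channels reuse the imaging medians.  Free nuclei are 7AAD− in flow
  (intact extruded nuclei) although they are SYTOX Red+ in imaging — the
  two assays' stated conventions differ, and each module follows its own.
- **Seeds**: every emitter takes a seed (int, `SeedSequence`, or
  `Generator`) and is bit-reproducible; pipeline helpers derive
  per-well substreams from one master seed via `SeedSequence`.

### What the generator does *not* emulate

Spectral bleed-through, uneven illumination, focus drift, 3-D structure,
overlapping/clumped cells beyond the minimum-distance geometry, time-lapse
dynamics, and proprietary instrument file formats.  Passing tests
demonstrate that the measurement chain is correct under the stated noise
model, not that it is robust to every artifact of real microscopy.

## Detection and calibration

- Detection runs on the pixel-wise maximum across channels (so KuO-only
  enucleated cells and dye-only free nuclei are both found), smoothed with
  σ=1; foreground is everything above the image median plus
  `max(6 × robust σ, 50)` counts.  The MAD-based noise term adapts to the
  image; the 50-count floor keeps masks compact on (near-)noiseless
  images where the noise estimate collapses.  Connected foreground is
  split by watershed seeded at intensity maxima ≥ 5 px apart; objects
  < 20 px² are dropped; objects touching the field border are flagged and
  excluded from counting (fields sample the well, so exclusion is
  unbiased).
- Mean intensity per channel is measured over the object mask after
  subtracting the per-image per-channel median background, making it
  invariant to constant offsets (tested to 1 count).  Integrated
  intensities are emitted as auxiliary columns.
- Thresholds are calibrated per plate from that plate's DMSO-well objects
  only, mirroring the in-plate normalization philosophy.  Otsu's method
  runs on a 256-bin histogram of log10 intensities; the returned cut is
  snapped to its bin edge and then recentered in the empty margin between
  the two calibration modes (the Otsu objective is flat across the gap and
  its argmax hugs one mode, which generalizes poorly to unseen wells;
  recentering preserves the maximizing partition).  A channel whose two
  sides are separated by less than 2 pooled standard deviations (log
  scale) raises a calibration error instructing a manual cutoff — the
  classical between/total-variance ratio cannot flag unimodality (it is
  ≈0.64 even for a pure Gaussian), the separation score can.  A
  `quantile_midpoint` alternative takes the geometric mean of the high
  mode's 10th and the low mode's 90th percentile (modes seeded by 1-D
  2-means).

## Flow gating

Events below the 2nd FSC percentile are discarded as debris; the remainder
is split into FSC-low/high by deterministic 2-means on log10(FSC) (seeded
at the extremes), falling back to a fixed cutoff (5.5) with a warning when
the two centers are closer than 0.1 decades.  SYTO 16 / 7AAD cutoffs come
from the same mode-separation calibration as imaging, applied to a stained
reference (DMSO) sample.  The flow enucleation efficiency is the
percentage of SYTO 16− 7AAD− events among all gated events.  The
FSC-low/high boundary of the original instrument is unknowable; any split
that cleanly separates the two size modes serves, which the 2-means split
does with ≥98% assignment accuracy under the default signal model (tested).

## Desk-scale study sizes

The full screen (3,327 compounds × 2 concentrations on live cells) is not
reproducible computationally; the package's own experiments run at sizes
chosen once as its desk-scale defaults: preset-recovery runs use 5 wells ×
5,000 cells × 10 fields per condition (acceptance script; the test suite
uses 2 wells), and fold-recovery uses one plate with 2 test wells and 8
DMSO controls at 5,000 cells/well.  At these sizes the recovered
enucleation percentages sit within ~0.5 points of the generating truth and
recovered folds within ~2% of the true folds, comfortably inside the ±2
point / ±10% bands the tests assert.

## Numerical conventions

Pixel coordinates are 0-based `(row, col)`; areas are pixel counts; no
physical calibration is assumed.  Report folds are rendered to two
decimals with decimal half-up rounding (so 10.005 → 10.01), and overlap
percentages to one decimal the same way.  Ranking sorts by enucleation
fold descending, ties by cell-number fold descending, then name.  An
empty well yields all-zero counts (not an error); a zero-denominator
frequency is NaN and the well is dropped from folds with a warning.

## Known limitations

Segmentation is classical (threshold + watershed); heavily clumped or
textured real images would need a learned segmenter upstream, after which
the measurement, classification, and scoring stages apply unchanged.
Detection accuracy claims (F1 ≥ 0.99) hold at ≤ ~100 objects per
512×512-equivalent field density under the default intensity model.
Threshold calibration assumes each channel is bimodal among control
objects; a plate whose controls lack any positive (or any negative)
objects in some channel correctly refuses to calibrate and requires a
manual cutoff.
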