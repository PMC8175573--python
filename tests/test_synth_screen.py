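"""Unit and property tests for the synthetic-screen generator."""

import numpy as np
import pandas as pd
import pytest

from enucleoscan.config import STATES, IntensityModel, RenderParams
from enucleoscan.synth_screen import (
    CompoundEntry,
    WellAssignment,
    WellTruth,
    dmso_well_template,
    make_library,
    make_plate_layouts,
    render_field_images,
    sample_well_population,
    simulate_flow_events,
    treated_well_template,
)


class TestMakeLibrary:
    def test_hit_spec_entries_carry_exact_folds(self):
        lib = make_library(3, [("TSA", 11.60, 0.46)], seed=1)
        assert len(lib) == 3
        tsa = [c for c in lib if c.name == "TSA"]
        assert len(tsa) == 1
        assert (tsa[0].true_enuc_fold, tsa[0].true_cellnum_fold) == (11.60, 0.46)

    def test_identity_compound(self):
        (entry,) = make_library(1, [("null", 1.0, 1.0)])
        assert entry.true_enuc_fold == 1.0 and entry.true_cellnum_fold == 1.0

    def test_deterministic_for_fixed_seed(self):
        assert make_library(100, [], seed=7) == make_library(100, [], seed=7)
        assert make_library(100, [], seed=7) != make_library(100, [], seed=8)

    def test_null_compounds_near_one_with_toxic_tail(self):
        lib = make_library(2000, [], seed=3)
        enuc = np.array([c.true_enuc_fold for c in lib])
        cell = np.array([c.true_cellnum_fold for c in lib])
        assert abs(np.median(enuc) - 1.0) < 0.05
        toxic = (cell < 0.2).mean()
        assert 0.01 < toxic < 0.06

    def test_invalid_folds_rejected(self):
        with pytest.raises(ValueError):
            make_library(1, [("bad", -1.0, 1.0)])
        with pytest.raises(ValueError):
            make_library(1, [("bad", 1.0, 0.0)])
        with pytest.raises(ValueError):
            make_library(0, [("x", 1.0, 1.0)])


class TestPlateLayouts:
    def test_layout_arithmetic_and_pair_coverage(self):
        lib = make_library(40, [], seed=0)
        layouts = make_plate_layouts(lib, controls_per_plate=8, seed=0)
        assert len(layouts) == 1
        plate = layouts[0]
        assert len(plate.wells) == 96
        assert len(plate.control_wells) == 8
        assert len(plate.test_wells) == 80  # 40 compounds x 2 concentrations
        pairs = {(w.compound_id, w.concentration_uM) for w in plate.test_wells}
        assert pairs == {(c.compound_id, conc) for c in lib for conc in (0.5, 10.0)}
        classes = [w.dmso_volume_class for w in plate.control_wells]
        assert classes.count("0.005%") >= 2 and classes.count("0.1%") >= 2

    def test_single_compound_layout(self):
        lib = make_library(1, [("x", 2.0, 1.0)])
        (plate,) = make_plate_layouts(lib, controls_per_plate=8, seed=1)
        assert len(plate.test_wells) == 2
        assert {w.concentration_uM for w in plate.test_wells} == {0.5, 10.0}
        assert all(w.role in ("test", "dmso", "empty") for w in plate.wells)

    def test_addresses_unique_and_deterministic(self):
        lib = make_library(120, [], seed=2)
        a = make_plate_layouts(lib, controls_per_plate=8, seed=5)
        b = make_plate_layouts(lib, controls_per_plate=8, seed=5)
        assert a == b
        for plate in a:
            addrs = [w.well for w in plate.wells]
            assert len(set(addrs)) == len(addrs)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_plate_layouts([], controls_per_plate=8)
        lib = make_library(2, [], seed=0)
        with pytest.raises(ValueError):
            make_plate_layouts(lib, controls_per_plate=3)  # <2 per volume class


class TestSampleWellPopulation:
    def test_dmso_keeps_baseline_fractions(self):
        entry = WellAssignment("A1", "dmso")
        truth = sample_well_population(entry, None, dmso_well_template(10_000), seed=0)
        assert truth.state_fractions["enucleated"] == pytest.approx(0.04)
        assert sum(truth.state_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_all_viable_composition(self):
        baseline = WellTruth("X", 1000, {
            "viable_nucleated": 1.0, "enucleated": 0.0,
            "dead_cell": 0.0, "free_nucleus": 0.0,
        })
        entry = WellAssignment("A2", "test", compound_id="c", name="c", concentration_uM=10.0)
        compound = CompoundEntry("c", "c", 50.0, 1.0)
        truth = sample_well_population(entry, compound, baseline, seed=1)
        assert truth.state_fractions["viable_nucleated"] == pytest.approx(1.0)
        assert truth.state_fractions["enucleated"] == 0.0  # 0 x fold stays 0

    def test_enucleated_fraction_scales_and_clamps(self):
        entry = WellAssignment("B1", "test", compound_id="c", name="c", concentration_uM=0.5)
        mild = CompoundEntry("c", "c", 11.60, 0.46)
        truth = sample_well_population(entry, mild, dmso_well_template(10_000), seed=2)
        assert truth.state_fractions["enucleated"] == pytest.approx(0.04 * 11.60)
        extreme = CompoundEntry("c", "c", 1000.0, 1.0)
        truth = sample_well_population(entry, extreme, dmso_well_template(10_000), seed=2)
        assert truth.state_fractions["enucleated"] == pytest.approx(0.95)

    def test_poisson_total_monte_carlo(self):
        entry = WellAssignment("A1", "dmso")
        baseline = dmso_well_template(10_000)
        rng = np.random.default_rng(0)
        totals = [
            sample_well_population(entry, None, baseline, seed=rng.integers(2**31)).total_cells
            for _ in range(1000)
        ]
        # mean of 1000 Poisson(10000) draws: SE = sqrt(10000/1000)
        assert abs(np.mean(totals) - 10_000) < 3 * np.sqrt(10_000 / 1000)


class TestRenderFieldImages:
    def test_object_count_conservation(self, small_render_params):
        truth = treated_well_template(200, "W1")
        images, gt = render_field_images(truth, n_fields=4, seed=3,
                                         render_params=small_render_params)
        assert len(gt) == 200
        assert len(images) == 4
        assert gt["field_index"].value_counts().sum() == 200
        for img in images:
            shapes = {a.shape for a in img.channels.values()}
            assert shapes == {small_render_params.image_shape}
            for a in img.channels.values():
                assert a.dtype == np.uint16

    def test_empty_well_renders_background_only(self, small_render_params):
        truth = WellTruth("W0", 0, dict(dmso_well_template(1).state_fractions))
        images, gt = render_field_images(truth, n_fields=2, seed=0,
                                         render_params=small_render_params)
        assert len(gt) == 0
        for img in images:
            # background offset 200, noise sigma 50: nothing object-like
            assert img.channels["KuO"].mean() < 300

    def test_bit_reproducible_for_fixed_seed(self, small_render_params):
        truth = treated_well_template(100, "W1")
        a, gt_a = render_field_images(truth, n_fields=2, seed=11, render_params=small_render_params)
        b, gt_b = render_field_images(truth, n_fields=2, seed=11, render_params=small_render_params)
        pd.testing.assert_frame_equal(gt_a, gt_b)
        for ia, ib in zip(a, b):
            for ch in ia.channels:
                np.testing.assert_array_equal(ia.channels[ch], ib.channels[ch])

    def test_degenerate_intensity_model_rejected(self):
        truth = dmso_well_template(10, "W")
        with pytest.raises(ValueError, match="degenerate"):
            render_field_images(
                truth, n_fields=1,
                intensity_model=IntensityModel(positive_median=100.0, negative_median=300.0),
            )

    def test_kuo_signal_grows_linearly_with_object_count(self, noiseless_model):
        """Total KuO signal above background is proportional to the number
        of KuO+ objects; the slope is the per-object integrated amplitude."""
        params = RenderParams(image_shape=(512, 512), radius_jitter=0.0)
        all_viable = {
            "viable_nucleated": 1.0, "enucleated": 0.0,
            "dead_cell": 0.0, "free_nucleus": 0.0,
        }
        counts = np.arange(10, 110, 10)
        totals = []
        for i, n in enumerate(counts):
            truth = WellTruth("W", int(n), all_viable)
            (img,), _ = render_field_images(
                truth, n_fields=1, intensity_model=noiseless_model,
                render_params=params, seed=100 + i,
            )
            kuo = img.channels["KuO"].astype(float)
            totals.append(kuo.sum() - noiseless_model.background_offset * kuo.size)
        slope = np.polyfit(counts, totals, 1)[0]
        # independent expectation: amplitude x number of lattice pixels in a
        # radius-5 disk (blur redistributes but conserves the integral)
        rr, cc = np.mgrid[-6:7, -6:7]
        npix = int((rr**2 + cc**2 <= 5.0**2).sum())
        expected = noiseless_model.positive_median * npix
        assert slope == pytest.approx(expected, rel=0.05)

    def test_empirical_state_fractions_match_truth(self, small_render_params):
        """Pooled over many replicate wells, the rendered enucleated fraction
        matches the ground-truth fraction within its binomial 99% CI."""
        cells, reps = 30, 500
        enuc_total = 0
        for i in range(reps):
            truth = treated_well_template(cells, "W")
            _, gt = render_field_images(
                truth, n_fields=1, seed=5000 + i,
                render_params=RenderParams(image_shape=(256, 256)),
            )
            enuc_total += int((gt["state"] == "enucleated").sum())
        n = cells * reps
        p = 0.23
        ci = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(enuc_total / n - p) < ci

    def test_rupture_renders_fragments(self, small_render_params):
        fractions = {
            "viable_nucleated": 0.0, "enucleated": 1.0,
            "dead_cell": 0.0, "free_nucleus": 0.0,
        }
        truth = WellTruth("W", 60, fractions, rupture_fraction=1.0)
        images, gt = render_field_images(truth, n_fields=1, seed=7,
                                         render_params=small_render_params)
        assert gt["ruptured"].all()
        assert len(gt) == 60  # fragments stay under their parent row
        intact = WellTruth("W", 60, fractions, rupture_fraction=0.0)
        images_i, _ = render_field_images(intact, n_fields=1, seed=7,
                                          render_params=small_render_params)
        # fragmented rendering deposits less integrated signal per parent
        total_r = images[0].channels["KuO"].astype(float).sum()
        total_i = images_i[0].channels["KuO"].astype(float).sum()
        assert total_r < total_i


class TestSimulateFlowEvents:
    def test_all_viable_population_gates_high_and_double_positive(self):
        truth = WellTruth("W", 100, {
            "viable_nucleated": 1.0, "enucleated": 0.0,
            "dead_cell": 0.0, "free_nucleus": 0.0,
        })
        events = simulate_flow_events(truth, 10_000, seed=0)
        # region bounds: geometric midpoints between positive/negative medians
        fsc_cut = np.sqrt(10.0 * 3.0)
        dye_cut = np.sqrt(10_000.0 * 300.0)
        frac = (
            (events["fsc"] > fsc_cut)
            & (events["syto16"] > dye_cut)
            & (events["aad7"] < dye_cut)
        ).mean()
        assert frac >= 0.99

    def test_empty_and_deterministic(self):
        truth = treated_well_template(100, "W")
        assert len(simulate_flow_events(truth, 0)) == 0
        a = simulate_flow_events(truth, 500, seed=9)
        b = simulate_flow_events(truth, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_event_fractions_follow_truth(self):
        truth = treated_well_template(100, "W")
        events = simulate_flow_events(truth, 20_000, seed=1)
        frac = (events["true_state"] == "enucleated").mean()
        assert frac == pytest.approx(0.23, abs=0.01)
        assert (events[["fsc", "syto16", "aad7", "kuo"]] > 0).all().all()
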