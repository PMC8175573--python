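"""Shared fixtures: the published hit-table fold pairs and small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from enucleoscan.config import IntensityModel, RenderParams

# The 40 published hit rows: (name, concentration µM, enucleation fold,
# cell-number fold).  Used as the fixture for the dual hit criterion.
TABLE1_HITS = [
    ("Trichostatin A", 0.5, 11.60, 0.46),
    ("Trichostatin A", 10, 11.53, 0.63),
    ("Vorinostat (SAHA)", 10, 11.52, 0.99),
    ("Cantharidic acid", 10, 11.49, 0.64),
    ("CI-994", 10, 11.44, 0.80),
    ("BML-281", 10, 11.40, 0.49),
    ("NCH-51", 10, 11.40, 0.59),
    ("Fluorescein", 10, 11.37, 0.77),
    ("d-Isoleucine", 10, 11.30, 1.38),
    ("Fluoro-SAHA", 10, 11.26, 0.97),
    ("l-Cysteine sulfinic acid", 10, 11.26, 1.01),
    ("d-Histidine", 10, 11.22, 1.02),
    ("d-Aspartic acid", 10, 11.22, 1.41),
    ("Cantharidin", 10, 11.14, 0.42),
    ("N-Acetyltryptamine", 10, 11.13, 0.79),
    ("Apicidin", 10, 10.98, 0.40),
    ("M344", 0.5, 10.98, 0.31),
    ("Scriptaid", 10, 10.94, 0.42),
    ("Vorinostat (SAHA)", 0.5, 10.93, 0.86),
    ("Apicidin", 0.5, 10.90, 0.35),
    ("d-Histidine", 0.5, 10.83, 2.19),
    ("5-Methoxytryptamine", 10, 10.82, 0.86),
    ("n-Octyl caffeate", 10, 10.78, 0.31),
    ("Suberoyl bis-hydroxamic acid", 10, 10.76, 0.27),
    ("M344", 10, 10.66, 0.73),
    ("9,10-Phenanthrenequinone", 0.5, 10.50, 0.44),
    ("Oxamflatin", 10, 10.24, 0.38),
    ("Tanshinone IIA", 10, 10.22, 0.46),
    ("PYRROMYCIN", 10, 10.09, 0.40),
    ("9,10-Phenanthrenequinone", 10, 10.04, 0.43),
    ("U74389G maleate", 10, 9.84, 0.53),
    ("Myosmine", 10, 9.70, 1.12),
    ("Tryptamine HCl", 10, 9.63, 1.18),
    ("EPIRUBICIN HYDROCHLORIDE", 10, 9.60, 0.28),
    ("C27H22Cl2N4", 10, 9.56, 0.78),
    ("C16H26O5", 10, 9.54, 0.34),
    ("Foxy-5", 0.5, 9.18, 0.93),
    ("C43H55N5O7.H2O4S", 0.5, 9.12, 0.49),
    ("BML-210", 10, 9.09, 0.33),
    ("d-Aspartic acid", 0.5, 9.07, 1.87),
]


@pytest.fixture(scope="session")
def table1_folds():
    return list(TABLE1_HITS)


@pytest.fixture(scope="session")
def noiseless_model():
    """Zero-variance intensity model: deterministic amplitudes, no read noise."""
    return IntensityModel(sigma_log=0.0, background_sigma=0.0)


@pytest.fixture(scope="session")
def small_render_params():
    """Smaller fields for fast tests."""
    return RenderParams(image_shape=(384, 384))


def match_centroids(truth_table: pd.DataFrame, objects: pd.DataFrame, tol: float = 1.5):
    """Greedy nearest-centroid matching between ground truth and detections
    within one well, per field.  Returns (n_matched, n_truth, n_detected)."""
    n_matched = 0
    for f in sorted(set(truth_table["field_index"])):
        gt = truth_table[truth_table["field_index"] == f][["row", "col"]].to_numpy()
        det = objects[objects["field_index"] == f][["row", "col"]].to_numpy()
        if len(gt) == 0 or len(det) == 0:
            continue
        d2 = ((gt[:, None, :] - det[None, :, :]) ** 2).sum(axis=2)
        pairs = [
            (d2[i, j], i, j)
            for i in range(len(gt))
            for j in range(len(det))
            if d2[i, j] <= tol**2
        ]
        used_gt, used_det = set(), set()
        for _, i, j in sorted(pairs):
            if i not in used_gt and j not in used_det:
                used_gt.add(i)
                used_det.add(j)
                n_matched += 1
    return n_matched, len(truth_table), len(objects)
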