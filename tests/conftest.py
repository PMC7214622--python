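"""Shared fixtures: study-scale synthetic scans and their detection runs.

The expensive 50-image fixture set (the default study geometry: 2 um x 2 um
fields, two volume subpopulations) is generated and analysed once per
session and reused by every test that needs end-to-end ground truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from afmstoich import (
    BackgroundSpec,
    ComponentSpec,
    PixelGeometry,
    PopulationSpec,
    detect_particles,
    flatten_image,
    read_image,
)
from afmstoich.detect import unflagged
from afmstoich.evaluate import match_detections
from afmstoich.synthetic import write_fixture_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

# cap aspect ratio giving a 417 nm^3 particle an apex height of 3 nm —
# typical for a membrane receptor dried on mica
DEFAULT_ASPECT = 0.1026

MONOMER = ComponentSpec(0.58, 417.0, 60.0, DEFAULT_ASPECT)
COMPLEX = ComponentSpec(0.42, 1174.0, 120.0, DEFAULT_ASPECT)

STUDY_GEOMETRY = PixelGeometry(1024, 1024, 2000.0 / 1024)  # 2 um x 2 um
STUDY_BACKGROUND = BackgroundSpec(
    rms_roughness=0.3, line_offset_sd=1.0, plane_tilt=(0.005, 0.005), seed=202
)
PARTICLES_PER_IMAGE = 40
N_IMAGES = 50


@pytest.fixture(scope="session")
def study_fixture_dir(tmp_path_factory) -> Path:
    """The default 50-image two-population fixture set on disk."""
    directory = tmp_path_factory.mktemp("study_fixture")
    population = PopulationSpec(
        components=(MONOMER, COMPLEX), n_particles=PARTICLES_PER_IMAGE, seed=101
    )
    write_fixture_set(
        directory, STUDY_GEOMETRY, population, STUDY_BACKGROUND, N_IMAGES
    )
    return directory


@pytest.fixture(scope="session")
def study_detection(study_fixture_dir) -> dict:
    """Flatten + detect every image of the study fixture once.

    Returns truth/detection tables, one-to-one matches, and the total
    scanned area, for reuse by recovery and concentration tests.
    """
    import json

    manifest = json.loads((study_fixture_dir / "manifest.json").read_text())
    truths, tables, matches = [], [], []
    for entry in manifest["images"]:
        img = read_image(study_fixture_dir / entry["image"])
        flat = flatten_image(img)
        table = detect_particles(flat)
        truth = pd.read_csv(study_fixture_dir / entry["truth"])
        truths.append(truth)
        tables.append(table)
        matches.append(match_detections(truth, table, max_dist=40.0))
    truth_all = pd.concat(truths, ignore_index=True)
    table_all = pd.concat(tables, ignore_index=True)
    return {
        "manifest": manifest,
        "truth": truth_all,
        "tables": tables,
        "table": table_all,
        "matches": pd.concat(matches, ignore_index=True),
        "n_truth": len(truth_all),
        "n_unflagged": len(unflagged(table_all)),
        "scanned_area_um2": N_IMAGES * STUDY_GEOMETRY.area_um2,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(8675309)
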