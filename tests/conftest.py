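"""Shared fixtures: one desk-scale biventricular model per session."""

from __future__ import annotations

import numpy as np
import pytest

from cardiotwin.mesh import (
    GeometryParams,
    assign_fibers,
    build_idealized_biventricle,
    compute_ventricular_coordinates,
    place_landmarks,
    segment_lv,
)
from cardiotwin.params import load_baseline
from cardiotwin.personalize import EikonalQrsModel
from cardiotwin.propagation.calibrate import CvCalibrator


@pytest.fixture(scope="session")
def baseline():
    return load_baseline()


@pytest.fixture(scope="session")
def small_geometry():
    # reduced-size ventricle, coarse lattice: fast enough for fitting loops
    return GeometryParams(scale=0.55, edge_mm=1.2)


@pytest.fixture(scope="session")
def small_biv(small_geometry):
    mesh = build_idealized_biventricle(small_geometry)
    coords = compute_ventricular_coordinates(mesh)
    mesh = assign_fibers(mesh, coords)
    return mesh, coords


@pytest.fixture(scope="session")
def small_landmarks(small_biv):
    mesh, coords = small_biv
    return place_landmarks(mesh, coords)


@pytest.fixture(scope="session")
def small_segmentation(small_biv):
    mesh, coords = small_biv
    return segment_lv(mesh, coords)


@pytest.fixture(scope="session")
def shared_calibrator(baseline):
    return CvCalibrator(baseline)


@pytest.fixture(scope="session")
def eik_factory(small_biv, small_landmarks, baseline, shared_calibrator):
    mesh, _ = small_biv
    return EikonalQrsModel.factory(mesh, small_landmarks, baseline,
                                   calibrator=shared_calibrator)
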