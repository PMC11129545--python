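"""Shared fixtures: geometry, spectrum, phantoms and one simulated scan.

The session-scoped study-I scan is the workhorse for imaging and metrics
tests; it uses the benchtop protocol (37 positions x 0.5 mm, 600 s dwell)
at a desk-scale beam flux with a thinned Compton background.
"""

import numpy as np
import pytest

from pyxfet import physics as ph
from pyxfet.geometry import build_geometry, make_scan_plan
from pyxfet.imaging import form_images
from pyxfet.phantom import phantom_study_I, phantom_study_II
from pyxfet.simulate import DetectorResponseModel, simulate_scan


@pytest.fixture(scope="session")
def geometry():
    return build_geometry()


@pytest.fixture(scope="session")
def spectrum():
    return ph.simulate_source_spectrum(90.0)


@pytest.fixture()
def response():
    return DetectorResponseModel()


@pytest.fixture(scope="session")
def study1():
    return phantom_study_I()


@pytest.fixture(scope="session")
def study2():
    return phantom_study_II()


@pytest.fixture(scope="session")
def plan():
    return make_scan_plan(37, 0.5, 600.0)


@pytest.fixture(scope="session")
def scan_I(study1, plan, geometry, spectrum):
    """Simulated study-I scan, ~8e5 emitted Gd K-alpha photons."""
    return simulate_scan(
        study1, plan, geometry, spectrum, flux=2e6, seed=42, compton_scale=1e-3
    )


@pytest.fixture(scope="session")
def images_I(scan_I, geometry, plan):
    return form_images(scan_I, geometry, plan, ["Gd"])


@pytest.fixture(scope="session")
def scan_II(study2, plan, geometry, spectrum):
    """Simulated two-element study, >= 2e5 emitted XRF photons per tube."""
    return simulate_scan(
        study2, plan, geometry, spectrum, flux=2.4e6, seed=0, compton_scale=1e-3
    )


@pytest.fixture(scope="session")
def images_II(scan_II, geometry, plan):
    return form_images(scan_II, geometry, plan, ["Gd", "La"])
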