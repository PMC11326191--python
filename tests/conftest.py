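"""Shared fixtures: default optics, a calibrated bead phantom, and access to
the acceptance-script computations (loaded by path so the tests exercise the
same code that regenerates the headline numbers)."""

from __future__ import annotations

import importlib.util
import sys
from pathlib import Path

import pytest

from qdf import simulate as sim
from qdf.pipeline import FrameParams, analyze_frame

REPO_ROOT = Path(__file__).resolve().parents[1]

# background-fit degree for ~128 px synthetic fields (see docs/methods.md)
SMALL_FIELD_PARAMS = FrameParams(poly_degree=3)


@pytest.fixture(scope="session")
def acceptance():
    """The scripts/acceptance.py module, imported by file path."""
    path = REPO_ROOT / "scripts" / "acceptance.py"
    spec = importlib.util.spec_from_file_location("qdf_acceptance_script", path)
    module = importlib.util.module_from_spec(spec)
    sys.modules["qdf_acceptance_script"] = module
    spec.loader.exec_module(module)
    return module


@pytest.fixture(scope="session")
def optics():
    return sim.OpticsSpec()


@pytest.fixture(scope="session")
def bead_calibration():
    """Scaling factor calibrated on a noisy bead phantom, shared across tests."""
    bead = sim.bead_phantom(seed=11)
    result = analyze_frame(
        sim.render_quadrants(bead),
        sim.render_reference_set(bead),
        sim.render_phase(bead),
        c=None,
        params=SMALL_FIELD_PARAMS,
    )
    return result.calibration
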