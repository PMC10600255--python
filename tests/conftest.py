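"""Shared fixtures: small probes and synthetic acquisitions.

Heavy simulation fixtures are session-scoped so that several test modules
can reuse them without re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

import umi


@pytest.fixture(scope="session")
def probe8():
    """Tiny 8×8 matrix probe for fast unit tests (c0 = 1.5 mm/µs)."""
    return umi.matrix_probe(n_x=8, n_y=8, pitch=0.5, reference_sound_speed=1.5)


@pytest.fixture(scope="session")
def probe12():
    return umi.matrix_probe(n_x=12, n_y=12, pitch=0.5, reference_sound_speed=1.54)


@pytest.fixture(scope="session")
def point_raw8(probe8):
    """Single on-axis point target, transducer basis, no aberration."""
    med = umi.point_target_medium((0.0, 0.0, 15.0))
    return umi.simulate_acquisition(probe8, med, seed=1)


@pytest.fixture(scope="session")
def small_grid8():
    return umi.ImagingGrid.regular((-1.0, 1.0), (-1.0, 1.0), (14.0, 16.0), pitch=0.5)


@pytest.fixture(scope="session")
def speckle12(probe12):
    """Aberration-free speckle acquisition + focused matrix (12×12 probe)."""
    med = umi.sample_speckle_medium(
        ((-5.0, 5.0), (-5.0, 5.0), (18.0, 22.0)),
        density=0.055,
        seed=7,
        geometry=probe12,
    )
    raw = umi.simulate_acquisition(probe12, med, seed=1)
    grid = umi.ImagingGrid.regular((-4.0, 4.0), (-4.0, 4.0), (18.5, 21.5), pitch=0.5)
    focused = umi.beamform_focused_matrix(raw, grid, drho_max=8.0)
    return {"geometry": probe12, "medium": med, "raw": raw, "grid": grid, "focused": focused}


@pytest.fixture(scope="session")
def speckle12_deep(probe12):
    """Deeper aberration-free speckle slab: enough resolution cells that a
    null-case estimate is statistically indistinguishable from flat."""
    med = umi.sample_speckle_medium(
        ((-5.0, 5.0), (-5.0, 5.0), (16.0, 24.0)),
        density=0.055,
        seed=7,
        geometry=probe12,
    )
    raw = umi.simulate_acquisition(probe12, med, seed=1)
    grid = umi.ImagingGrid.regular((-4.0, 4.0), (-4.0, 4.0), (16.5, 23.5), pitch=0.5)
    focused = umi.beamform_focused_matrix(raw, grid, drho_max=8.0)
    return {"geometry": probe12, "raw": raw, "grid": grid, "focused": focused}


@pytest.fixture(scope="session")
def guide_star12(probe12):
    """Point target seen through a known phase screen (12×12 probe)."""
    screen = umi.make_phase_screen(
        probe12, correlation_length=2.0, rms_delay=1.5 / (2 * np.pi * 3.0) * 1e3, seed=3
    )
    med = umi.point_target_medium((0.0, 0.0, 20.0))
    raw = umi.simulate_acquisition(probe12, med, screen, seed=1)
    grid = umi.ImagingGrid.regular((-3.0, 3.0), (-3.0, 3.0), (19.5, 20.5), pitch=0.5)
    focused = umi.beamform_focused_matrix(raw, grid, drho_max=8.0)
    return {"geometry": probe12, "screen": screen, "raw": raw, "grid": grid, "focused": focused}
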