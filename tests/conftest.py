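"""Shared fixtures: one calibration and one set of study runs per session.

Every simulation in the suite is deterministic (fixed grids, fixed
iteration order, no random numbers), so session-scoped caching is safe and
keeps the suite fast.
"""

from __future__ import annotations

import pytest

import bonedrill as bd


@pytest.fixture(scope="session")
def calibration():
    """Default calibration at the production grid spacing."""
    return bd.default_calibration(0.05)


@pytest.fixture(scope="session")
def validation_runs(calibration):
    probe = (0.5, 4.0)
    out = {}
    for name in ("validation-fig3a", "validation-fig3b"):
        sc = bd.preset_scenario(name, calibration)
        out[name] = bd.simulate(sc, probe_points_mm=[probe])
    return out


@pytest.fixture(scope="session")
def feedforce_runs(calibration):
    out = {}
    for force in (10, 20, 40, 60):
        sc = bd.preset_scenario(f"feedforce-fig5-{force}", calibration)
        out[force] = bd.simulate(sc, probe_points_mm=[(0.1, 1.0)])
    return out


@pytest.fixture(scope="session")
def predrill_runs(calibration):
    probes = [(0.1, z) for z in (1.0, 2.0, 3.0, 4.0)]
    return {
        "direct": bd.simulate(
            bd.preset_scenario("predrill-fig6-direct", calibration),
            probe_points_mm=probes),
        "pilot": bd.simulate(
            bd.preset_scenario("predrill-fig6-pilot", calibration),
            probe_points_mm=probes),
    }


@pytest.fixture(scope="session")
def taz_runs(calibration):
    out = {}
    for name in ("taz-fig7a-800", "taz-fig7a-2000",
                 "taz-fig7b-800", "taz-fig7b-2000"):
        sc = bd.preset_scenario(name, calibration)
        out[name] = bd.simulate(sc, probe_points_mm=[(0.1, 1.0)])
    return out


@pytest.fixture(scope="session")
def taz_extents(taz_runs):
    return {name: bd.taz_extent(hist, 45.0, (1.0, 2.0, 3.0, 4.0))
            for name, hist in taz_runs.items()}
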