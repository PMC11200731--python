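"""Calibration of the force-controlled feed model.

The simulator has exactly two empirical constants:

* the **feed compliance** c (mm per revolution per newton), which sets the
  penetration rate ``v = c * F * n_rev`` and hence all drilling times, and
* the **specific cutting energy** u_c (J/mm^3), which sets the magnitude of
  the plastic-work heat source and hence all temperature rises.

Both are anchored on printed bench observations rather than asserted:
c is a least-squares fit (in relative error) to observed times to drill
through the cortex, and u_c is solved so that a simulated probe peak matches
an observed peak temperature.  Because the conduction problem is linear in
the sources and the removal kinematics do not depend on temperature, the
probe-peak response to u_c is known exactly from two simulations (u_c = 0
and u_c = 1); the anchor equation is then solved by 1-D root finding on
that closed form.  The whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .heat import FeedCalibration
from .materials import Scenario, preset_scenario


class CalibrationError(RuntimeError):
    """The calibration problem is degenerate or unsatisfiable."""


@dataclass(frozen=True)
class TimeAnchor:
    """Observed time to drill through the cortex under one condition."""

    feed_force_n: float
    rotational_speed_rpm: float
    time_s: float
    depth_mm: float = 4.0


@dataclass(frozen=True)
class PeakAnchor:
    """Observed peak probe temperature for one scenario."""

    scenario: Scenario
    probe_x_mm: float
    probe_z_mm: float
    peak_temperature_c: float


#: Default anchors: the two printed extreme times of the feed-force study
#: (~1 s at 60 N, ~9 s at 10 N, both 800 rpm) and the validation peak
#: 34.6 °C at x=0.5 mm, z=4 mm (3.5 mm bit, 20 N, 1200 rpm).  Everything
#: else the model reports is held out of the calibration.
DEFAULT_TIME_ANCHORS = (
    TimeAnchor(feed_force_n=60.0, rotational_speed_rpm=800.0, time_s=1.0),
    TimeAnchor(feed_force_n=10.0, rotational_speed_rpm=800.0, time_s=9.0),
)
DEFAULT_PEAK_TEMPERATURE_C = 34.6


def fit_compliance(anchors: Sequence[TimeAnchor]) -> tuple[float, float]:
    """Least-squares feed compliance from time-to-depth anchors.

    Under the linear feed law the predicted time is
    ``t = depth / (c * F * n_rev)``; minimising the summed squared relative
    error ``sum((t_model/t_obs - 1)^2)`` is linear in ``a = 1/c`` and solved
    in closed form.  Returns ``(compliance, residual)``.  Exact duplicate
    anchors are collapsed first, and at least two distinct feed forces are
    required (with one force level the product c*F is unidentifiable from a
    single time scale against the model's force dependence).
    """
    anchors = list(dict.fromkeys(anchors))
    if len(anchors) < 2:
        raise CalibrationError("need at least two distinct time anchors")
    if len({a.feed_force_n for a in anchors}) < 2:
        raise CalibrationError(
            "time anchors span a single feed force; the objective is "
            "under-determined — provide anchors at >=2 distinct forces")
    b = np.array([a.depth_mm / (a.feed_force_n * a.rotational_speed_rpm / 60.0
                                * a.time_s) for a in anchors])
    a_star = float(np.sum(b) / np.sum(b ** 2))
    residual = float(np.sum((a_star * b - 1.0) ** 2))
    return 1.0 / a_star, residual


def _peak_response(scenario: Scenario, probe: tuple[float, float],
                   compliance: float) -> tuple[np.ndarray, np.ndarray]:
    """Probe series at u_c -> 0 and its per-step sensitivity to u_c.

    Runs the scenario twice (u_c tiny, u_c = 1); by source linearity the
    probe series at any u_c is ``s0 + u_c * (s1 - s0)``.
    """
    from .solver import simulate  # deferred: keeps module import-light

    u_eps = 1e-9
    series = []
    for u in (u_eps, 1.0):
        calib = FeedCalibration(feed_compliance_mm_per_rev_n=compliance,
                                specific_cutting_energy_j_mm3=u)
        hist = simulate(replace(scenario, calibration=calib),
                        probe_points_mm=[probe])
        series.append(hist.probe_series_c[:, 0])
    s0, s1 = series
    return s0, s1 - s0


def calibrate_feed(time_anchors: Sequence[TimeAnchor] = DEFAULT_TIME_ANCHORS,
                   peak_anchors: Optional[Sequence[PeakAnchor]] = None,
                   grid_spacing_mm: Optional[float] = None) -> FeedCalibration:
    """Fit (feed compliance, specific cutting energy) to printed anchors.

    ``peak_anchors`` defaults to the single validation-scenario peak.  With
    one peak anchor the cutting energy is solved exactly (root finding on
    the linear-response closed form); with several it minimises the summed
    squared relative peak error on a dense deterministic grid of the same
    closed forms.
    """
    compliance, t_residual = fit_compliance(time_anchors)

    if peak_anchors is None:
        sc = preset_scenario("validation-fig3a")
        if grid_spacing_mm is not None:
            sc = replace(sc, grid_spacing_mm=grid_spacing_mm)
        peak_anchors = [PeakAnchor(sc, 0.5, 4.0, DEFAULT_PEAK_TEMPERATURE_C)]

    responses = []
    for a in peak_anchors:
        sc = a.scenario
        if grid_spacing_mm is not None:
            sc = replace(sc, grid_spacing_mm=grid_spacing_mm)
        s0, g = _peak_response(sc, (a.probe_x_mm, a.probe_z_mm), compliance)
        responses.append((s0, g, a.peak_temperature_c))

    def peak(u: float, s0: np.ndarray, g: np.ndarray) -> float:
        return float(np.max(s0 + u * g))

    if len(responses) == 1:
        s0, g, target = responses[0]
        f = lambda u: peak(u, s0, g) - target
        if f(0.0) >= 0.0:
            raise CalibrationError(
                "frictional heating alone already exceeds the peak anchor "
                f"({peak(0.0, s0, g):.2f} >= {target:.2f} °C); the anchor set "
                "is unsatisfiable with a non-negative cutting energy")
        hi = 1.0
        while f(hi) < 0.0:
            hi *= 2.0
            if hi > 1e3:
                raise CalibrationError(
                    "peak anchor unreachable even at an implausible cutting "
                    "energy (>1000 J/mm^3); check the anchor definition")
        u_star = float(brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12))
        p_residual = (peak(u_star, s0, g) / target - 1.0) ** 2
    else:
        us = np.linspace(1e-4, 20.0, 200001)
        obj = np.zeros_like(us)
        for s0, g, target in responses:
            peaks = np.max(s0[None, :] + us[:, None] * g[None, :], axis=1)
            obj += (peaks / target - 1.0) ** 2
        i = int(np.argmin(obj))
        u_star = float(us[i])
        p_residual = float(obj[i])

    return FeedCalibration(
        feed_compliance_mm_per_rev_n=compliance,
        specific_cutting_energy_j_mm3=u_star,
        residual=t_residual + p_residual,
        anchors={
            "time": [(a.feed_force_n, a.rotational_speed_rpm, a.time_s, a.depth_mm)
                     for a in time_anchors],
            "peak": [(a.scenario.name, a.probe_x_mm, a.probe_z_mm,
                      a.peak_temperature_c) for a in peak_anchors],
        },
    )


@lru_cache(maxsize=4)
def default_calibration(grid_spacing_mm: float = 0.05) -> FeedCalibration:
    """The default calibration used by every study (memoised per resolution)."""
    return calibrate_feed(grid_spacing_mm=grid_spacing_mm)
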