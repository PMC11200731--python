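"""Heat generation at the drill--bone interface.

Two mechanisms feed the interface heat budget:

* **Friction** between the rotating bit and the bone, with power
  ``q_f = 2*pi*R*n*mu*F`` (sliding speed at effective radius R times the
  Coulomb friction force), evaluated at the area-weighted mean radius of the
  current contact annulus.
* **Cutting** (plastic deformation of the chip), modelled as a specific
  cutting energy per removed volume: ``q_p = eta * u_c * MRR`` where MRR is
  the material removal rate.  The effective stress / plastic strain-rate
  product inside a full chip-formation solve is deliberately collapsed into
  the single empirical constant ``u_c`` (see :mod:`bonedrill.calibrate`).

A constant partition factor splits the total power between the tool (a
lumped sink — the drill is never meshed) and the bone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .materials import DrillSpec, Scenario


class CalibrationMissingError(RuntimeError):
    """A scenario was run without feed-model constants."""


@dataclass(frozen=True)
class FeedCalibration:
    """Empirical constants of the force-controlled feed model.

    feed_compliance_mm_per_rev_n
        Feed per revolution per newton of thrust; the penetration rate is
        ``v = compliance * F * n`` with n in rev/s.
    specific_cutting_energy_j_mm3
        Energy converted to heat per unit volume of removed bone.
    """

    feed_compliance_mm_per_rev_n: float
    specific_cutting_energy_j_mm3: float
    residual: float = 0.0
    anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.feed_compliance_mm_per_rev_n > 0:
            raise ValueError("feed_compliance_mm_per_rev_n must be strictly positive")
        if not self.specific_cutting_energy_j_mm3 > 0:
            raise ValueError("specific_cutting_energy_j_mm3 must be strictly positive")


@dataclass(frozen=True)
class HeatSourceState:
    """Instantaneous heat-source bookkeeping at one tip depth."""

    friction_power_w: float
    cutting_power_w: float
    flux_to_bone_w: float
    flux_to_drill_w: float
    contact_annulus_mm: tuple[float, float]
    tip_depth_mm: float

    @property
    def total_power_w(self) -> float:
        return self.friction_power_w + self.cutting_power_w


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def frictional_heat_rate(radius_m: float, speed_rev_s: float,
                         mu: float, normal_force_n: float) -> float:
    """Frictional power (W) at sliding radius ``radius_m``.

    ``2*pi*R*n`` is the sliding speed of the interface; multiplied by the
    Coulomb friction force ``mu*F`` it gives the dissipated power.
    """
    _require_nonnegative(radius_m=radius_m, speed_rev_s=speed_rev_s,
                         mu=mu, normal_force_n=normal_force_n)
    return 2.0 * math.pi * radius_m * speed_rev_s * mu * normal_force_n


def cutting_heat_rate(removal_rate_mm3_s: float, specific_cutting_energy_j_mm3: float,
                      eta: float) -> float:
    """Plastic-work heating power (W): eta * u_c * MRR."""
    _require_nonnegative(removal_rate_mm3_s=removal_rate_mm3_s,
                         specific_cutting_energy_j_mm3=specific_cutting_energy_j_mm3)
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta (inelastic heat fraction) must lie in [0, 1], got {eta}")
    return eta * specific_cutting_energy_j_mm3 * removal_rate_mm3_s


def partition_heat(total_w: float, eta1: float) -> tuple[float, float]:
    """Split ``total_w`` into (to_drill, to_bone).

    ``to_bone`` is computed as the exact complement ``total - to_drill``,
    so no power is created or lost by the split (the recomposed sum agrees
    with the input to one ulp).
    """
    if not 0.0 <= eta1 <= 1.0:
        raise ValueError(f"eta1 (heat partition factor) must lie in [0, 1], got {eta1}")
    to_drill = eta1 * total_w
    return to_drill, total_w - to_drill


def penetration_rate(scenario: "Scenario",
                     calib: Optional[FeedCalibration] = None) -> float:
    """Nominal axial penetration speed (mm/s) under force-controlled feed.

    Linear compliance law: feed per revolution proportional to the thrust,
    so ``v = c * F * n_rev``.  Strictly increasing in both force and speed.
    This is the fully engaged rate; the solver scales it instantaneously by
    the inverse engaged-area fraction (see :func:`tip_depth_schedule`), so
    a pilot-hole pass or a breaking-through tip advances faster at the same
    thrust while the volumetric removal rate stays ``v * pi R^2``.
    """
    calib = calib if calib is not None else scenario.calibration
    if calib is None:
        raise CalibrationMissingError(
            "scenario has no feed calibration; run bonedrill.calibrate."
            "calibrate_feed (or default_calibration) and attach the result")
    return (calib.feed_compliance_mm_per_rev_n
            * scenario.feed_force_n
            * scenario.rotational_speed_rpm / 60.0)


def tip_depth_schedule(scenario: "Scenario", target_depth_mm: float,
                       n_points: int = 4096):
    """Tip trajectory d(t) under engagement-scaled force-controlled feed.

    The bite per revolution is proportional to the thrust carried per unit
    of engaged cutting face: ``v(d) = v_nom * A_full / A_engaged(d)``.
    Integrating gives ``t(d) = V_removed(d) / (A_full * v_nom)`` in closed
    form, which this function tabulates and returns as
    ``(times_s, depths_mm, t_drill_s)`` for interpolation.  Entry and
    breakthrough (small engaged area) are traversed quickly; the time to
    complete a through-hole equals ``thickness_eff / v_nom`` where
    ``thickness_eff = V_total / A_full`` — for a direct through-hole this
    is exactly the cortical thickness, making the compliance calibration's
    time-to-depth law exact.
    """
    v_nom = penetration_rate(scenario)
    a_full = math.pi * scenario.drill.radius_mm ** 2
    depths = [i * target_depth_mm / (n_points - 1) for i in range(n_points)]
    times = [removed_volume_mm3(scenario.drill, scenario.bone.thickness_mm,
                                scenario.predrill_diameter_mm, d)
             / (a_full * v_nom) for d in depths]
    return times, depths, times[-1]


# ---------------------------------------------------------------------------
# Geometry of the advancing conical front.
# ---------------------------------------------------------------------------

def contact_annulus_mm(drill: "DrillSpec", thickness_mm: float,
                       predrill_mm: Optional[float],
                       tip_depth_mm: float) -> Optional[tuple[float, float]]:
    """Radial interval (inner, outer) of bone in contact with the tip cone.

    Returns ``None`` when the cone touches no uncut material (tip above the
    surface, spinning inside the pilot hole, or fully broken through).
    """
    if tip_depth_mm < 0:
        raise ValueError(f"tip_depth_mm must be non-negative, got {tip_depth_mm}")
    if tip_depth_mm == 0:
        return None
    tan_phi = math.tan(drill.tip_half_angle_rad)
    r_out = min(drill.radius_mm, tip_depth_mm * tan_phi)
    r_in = 0.0
    if tip_depth_mm > thickness_mm:
        r_in = (tip_depth_mm - thickness_mm) * tan_phi
    if predrill_mm is not None:
        r_in = max(r_in, 0.5 * predrill_mm)
    if r_in >= r_out:
        return None
    return (r_in, r_out)


def mean_contact_radius_mm(annulus: tuple[float, float]) -> float:
    """Area-weighted mean radius of an annulus: (2/3)(ro^3-ri^3)/(ro^2-ri^2)."""
    ri, ro = annulus
    return (2.0 / 3.0) * (ro ** 3 - ri ** 3) / (ro ** 2 - ri ** 2)


def removal_area_mm2(drill: "DrillSpec", thickness_mm: float,
                     predrill_mm: Optional[float], tip_depth_mm: float) -> float:
    """Cross-section (mm^2) of uncut material swept per unit tip advance.

    For a fully engaged drill with a pilot hole this is the annulus
    ``pi/4 (D^2 - dp^2)``; during entry the cone is only partially embedded
    and during breakthrough the remaining annulus shrinks to zero.
    """
    ann = contact_annulus_mm(drill, thickness_mm, predrill_mm, tip_depth_mm)
    if ann is None:
        return 0.0
    ri, ro = ann
    return math.pi * (ro ** 2 - ri ** 2)


def removal_rate(scenario: "Scenario", v_mm_s: float, tip_depth_mm: float) -> float:
    """Material removal rate (mm^3/s) at the given tip depth."""
    if v_mm_s < 0:
        raise ValueError(f"v_mm_s must be non-negative, got {v_mm_s}")
    if tip_depth_mm < 0:
        raise ValueError(f"tip_depth_mm must be non-negative, got {tip_depth_mm}")
    return v_mm_s * removal_area_mm2(
        scenario.drill, scenario.bone.thickness_mm,
        scenario.predrill_diameter_mm, tip_depth_mm)


def removed_volume_mm3(drill: "DrillSpec", thickness_mm: float,
                       predrill_mm: Optional[float], tip_depth_mm: float) -> float:
    """Closed-form volume of bone removed by the cone+cylinder at one depth.

    Counts only material the *current* drill removes, i.e. excludes any
    pre-existing pilot hole.  Used as the analytic oracle for the discrete
    mask and for the enthalpy audit.
    """
    if tip_depth_mm <= 0:
        return 0.0
    d = tip_depth_mm
    R = drill.radius_mm
    tan_phi = math.tan(drill.tip_half_angle_rad)
    h = drill.cone_height_mm
    rp = 0.5 * predrill_mm if predrill_mm is not None else 0.0
    t2 = tan_phi ** 2

    vol = 0.0
    # Cylindrical section: z in [0, min(d - h, thickness)], radius R.
    a = min(max(d - h, 0.0), thickness_mm)
    vol += math.pi * max(R ** 2 - rp ** 2, 0.0) * a
    # Conical section: z in [max(d-h, 0), min(d, thickness)], radius (d-z)tan(phi),
    # truncated where the cone radius falls inside the pilot hole.
    lo = max(d - h, 0.0)
    hi = min(d, thickness_mm)
    if rp > 0:
        hi = min(hi, d - rp / tan_phi)
    if hi > lo:
        vol += math.pi * (t2 * ((d - lo) ** 3 - (d - hi) ** 3) / 3.0
                          - rp ** 2 * (hi - lo))
    return vol


def heat_source_state(scenario: "Scenario", v_mm_s: float,
                      tip_depth_mm: float,
                      calib: Optional[FeedCalibration] = None) -> HeatSourceState:
    """Assemble the instantaneous heat-source state at one tip depth."""
    calib = calib if calib is not None else scenario.calibration
    if calib is None:
        raise CalibrationMissingError(
            "scenario has no feed calibration; run calibrate_feed first")
    ann = contact_annulus_mm(scenario.drill, scenario.bone.thickness_mm,
                             scenario.predrill_diameter_mm, tip_depth_mm)
    if ann is None:
        return HeatSourceState(0.0, 0.0, 0.0, 0.0, (0.0, 0.0), tip_depth_mm)
    rbar_m = mean_contact_radius_mm(ann) * 1e-3
    q_f = frictional_heat_rate(rbar_m, scenario.rotational_speed_rpm / 60.0,
                               scenario.friction_coefficient, scenario.feed_force_n)
    mrr = removal_rate(scenario, v_mm_s, tip_depth_mm)
    q_p = cutting_heat_rate(mrr, calib.specific_cutting_energy_j_mm3,
                            scenario.inelastic_heat_fraction)
    to_drill, to_bone = partition_heat(q_f + q_p, scenario.heat_partition_to_drill)
    return HeatSourceState(q_f, q_p, to_bone, to_drill, ann, tip_depth_mm)
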