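"""Material, tool, bone and scenario definitions for the drilling model.

All configuration-level quantities use the bench units that surgeons and
tool catalogues use (mm, rpm, N, °C, g/cm³).  Conversion to SI happens once,
at the solver boundary, never inside user-facing types: mixing unit systems
inside the heat-generation formulas is the classic way these models go wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, TYPE_CHECKING

import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .heat import FeedCalibration


class UnknownPresetError(KeyError):
    """Raised when a preset scenario id is not recognised."""


@dataclass(frozen=True)
class MaterialProps:
    """Thermal and mechanical constants of one material.

    The mechanical fields (moduli, strengths) and the two ductile-damage
    constants are carried as metadata so a scenario file is a complete
    record of the modelled materials; the thermal surrogate solver only
    consumes density, specific heat and thermal conductivity.
    """

    name: str
    density_g_cm3: float
    elastic_modulus_mpa: float
    poisson_ratio: float
    yield_stress_mpa: float
    ultimate_stress_mpa: float
    ultimate_strain: float
    specific_heat_j_kg_c: float
    thermal_conductivity_w_m_k: float
    damage_failure_strain: Optional[float] = None
    damage_plastic_displacement_mm: Optional[float] = None

    @property
    def density_kg_m3(self) -> float:
        return self.density_g_cm3 * 1000.0

    @property
    def volumetric_heat_capacity_j_m3_c(self) -> float:
        """rho * c_p, J/(m^3 °C)."""
        return self.density_kg_m3 * self.specific_heat_j_kg_c

    @property
    def thermal_diffusivity_m2_s(self) -> float:
        return self.thermal_conductivity_w_m_k / self.volumetric_heat_capacity_j_m3_c

    def violations(self, prefix: str = "material") -> list[str]:
        out = []
        positive = [
            "density_g_cm3", "elastic_modulus_mpa", "yield_stress_mpa",
            "ultimate_stress_mpa", "ultimate_strain", "specific_heat_j_kg_c",
            "thermal_conductivity_w_m_k",
        ]
        for f_ in positive:
            if not getattr(self, f_) > 0:
                out.append(f"{prefix}.{f_}: must be strictly positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            out.append(f"{prefix}.poisson_ratio: must lie in (0, 0.5)")
        return out


#: Cortical bone, treated as isotropic and homogeneous.
CORTICAL_BONE = MaterialProps(
    name="cortical bone",
    density_g_cm3=1.640,
    elastic_modulus_mpa=16_700.0,
    poisson_ratio=0.3,
    yield_stress_mpa=105.0,
    ultimate_stress_mpa=106.0,
    ultimate_strain=0.008,
    specific_heat_j_kg_c=1640.0,
    thermal_conductivity_w_m_k=0.452,
    damage_failure_strain=0.008,
    damage_plastic_displacement_mm=0.3,
)

#: 316L surgical stainless steel drill-bit stock.
DRILL_316L = MaterialProps(
    name="316L stainless steel",
    density_g_cm3=7.990,
    elastic_modulus_mpa=193_000.0,
    poisson_ratio=0.25,
    yield_stress_mpa=290.0,
    ultimate_stress_mpa=579.0,
    ultimate_strain=0.003,
    specific_heat_j_kg_c=500.0,
    thermal_conductivity_w_m_k=16.2,
)


@dataclass(frozen=True)
class DrillSpec:
    """Twist-drill geometry.

    The point angle is the included angle of the conical tip; the half-angle
    measured from the drill axis is ``point_angle/2``, so the cone's local
    radius grows as ``tan(point_angle/2)`` per unit of axial distance above
    the tip.  The helix angle is metadata in this thermal surrogate.
    """

    diameter_mm: float
    point_angle_deg: float = 108.0
    helix_angle_deg: float = 23.0
    material: MaterialProps = DRILL_316L

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    @property
    def tip_half_angle_rad(self) -> float:
        """Half of the point angle, measured from the drill axis."""
        return math.radians(0.5 * self.point_angle_deg)

    @property
    def cone_height_mm(self) -> float:
        """Axial height of the conical tip, R / tan(half angle)."""
        return self.radius_mm / math.tan(self.tip_half_angle_rad)

    def violations(self, prefix: str = "drill") -> list[str]:
        out = []
        if not self.diameter_mm > 0:
            out.append(f"{prefix}.diameter_mm: must be strictly positive")
        if not 0.0 < self.point_angle_deg < 180.0:
            out.append(f"{prefix}.point_angle_deg: must lie in (0, 180)")
        out.extend(self.material.violations(prefix=f"{prefix}.material"))
        return out


@dataclass(frozen=True)
class BoneSpec:
    """Cylindrical cortical-bone work piece.

    The domain is a disc of ``outer_diameter_mm`` and ``thickness_mm`` with
    the drilling axis through its centre; all external surfaces are
    adiabatic (no irrigation, no convective loss).
    """

    thickness_mm: float = 4.0
    outer_diameter_mm: float = 8.0
    material: MaterialProps = CORTICAL_BONE
    initial_temperature_c: float = 22.0

    @property
    def outer_radius_mm(self) -> float:
        return 0.5 * self.outer_diameter_mm

    def violations(self, prefix: str = "bone") -> list[str]:
        out = []
        if not self.thickness_mm > 0:
            out.append(f"{prefix}.thickness_mm: must be strictly positive")
        if not self.outer_diameter_mm > 0:
            out.append(f"{prefix}.outer_diameter_mm: must be strictly positive")
        out.extend(self.material.violations(prefix=f"{prefix}.material"))
        return out


@dataclass
class Scenario:
    """One complete drilling configuration.

    ``heat_partition_to_drill`` is the fraction of interface heat carried
    into the tool (a lumped sink); the remainder enters the bone.
    ``inelastic_heat_fraction`` scales the cutting (plastic-work) heat.
    ``calibration`` carries the two empirical constants of the force-
    controlled feed model; see :mod:`bonedrill.calibrate`.
    """

    drill: DrillSpec
    bone: BoneSpec = field(default_factory=BoneSpec)
    rotational_speed_rpm: float = 800.0
    feed_force_n: float = 20.0
    friction_coefficient: float = 0.3
    heat_partition_to_drill: float = 0.5
    inelastic_heat_fraction: float = 0.9
    #: Tip travel at which the sources switch off.  None means drill until
    #: breakthrough is complete (thickness + cone height), i.e. a finished
    #: through-hole; set a number to stop earlier (e.g. a blind hole).
    target_depth_mm: Optional[float] = None
    predrill_diameter_mm: Optional[float] = None
    calibration: Optional["FeedCalibration"] = None
    grid_spacing_mm: float = 0.05
    time_step_safety: float = 0.4
    post_drill_hold_s: float = 5.0
    max_time_s: float = 120.0
    name: str = ""

    def with_calibration(self, calibration: "FeedCalibration") -> "Scenario":
        return replace(self, calibration=calibration)

    @property
    def effective_target_depth_mm(self) -> float:
        """Tip travel at source switch-off; breakthrough-complete if unset."""
        if self.target_depth_mm is not None:
            return self.target_depth_mm
        return self.bone.thickness_mm + self.drill.cone_height_mm


def validate_scenario(s: Scenario) -> list[str]:
    """Return a list of invariant violations (empty iff the scenario is valid).

    This is a reporting operation: it never raises, each entry names the
    offending field and the rule it breaks.
    """
    out: list[str] = []
    out.extend(s.drill.violations())
    out.extend(s.bone.violations())
    if not s.rotational_speed_rpm > 0:
        out.append("rotational_speed_rpm: must be strictly positive")
    if not s.feed_force_n > 0:
        out.append("feed_force_n: must be strictly positive")
    if not s.friction_coefficient >= 0:
        out.append("friction_coefficient: must be non-negative")
    if not 0.0 <= s.heat_partition_to_drill <= 1.0:
        out.append("heat_partition_to_drill: must lie in [0, 1]")
    if not 0.0 <= s.inelastic_heat_fraction <= 1.0:
        out.append("inelastic_heat_fraction: must lie in [0, 1]")
    if s.target_depth_mm is not None and not s.target_depth_mm > 0:
        out.append("target_depth_mm: must be strictly positive")
    if s.predrill_diameter_mm is not None:
        if not s.predrill_diameter_mm > 0:
            out.append("predrill_diameter_mm: must be strictly positive")
        elif not s.predrill_diameter_mm < s.drill.diameter_mm:
            out.append(
                "predrill_diameter_mm: pilot hole must be smaller than the "
                f"drill diameter ({s.predrill_diameter_mm} >= {s.drill.diameter_mm})"
            )
    if not s.grid_spacing_mm > 0:
        out.append("grid_spacing_mm: must be strictly positive")
    if not 0.0 < s.time_step_safety <= 0.5:
        out.append("time_step_safety: must lie in (0, 0.5] for explicit stability")
    if not s.post_drill_hold_s >= 0:
        out.append("post_drill_hold_s: must be non-negative")
    return out


# ---------------------------------------------------------------------------
# Presets: the named configurations of the reported parameter studies.
# ---------------------------------------------------------------------------

_DRILL_35 = DrillSpec(diameter_mm=3.5)
_DRILL_45 = DrillSpec(diameter_mm=4.5)


def _presets() -> dict[str, Scenario]:
    bone_22 = BoneSpec(initial_temperature_c=22.0)
    bone_255 = BoneSpec(initial_temperature_c=25.5)
    p: dict[str, Scenario] = {
        # Validation scenarios: probe at x = 0.5 mm, z = 4 mm.
        "validation-fig3a": Scenario(
            drill=_DRILL_35, bone=bone_22, rotational_speed_rpm=1200.0,
            feed_force_n=20.0, name="validation-fig3a"),
        "validation-fig3b": Scenario(
            drill=_DRILL_45, bone=bone_255, rotational_speed_rpm=1200.0,
            feed_force_n=60.0, name="validation-fig3b"),
        # Predrill pair: 3.5 mm at 800 rpm, 20 N, with/without 2.5 mm pilot.
        "predrill-fig6-direct": Scenario(
            drill=_DRILL_35, bone=bone_22, rotational_speed_rpm=800.0,
            feed_force_n=20.0, name="predrill-fig6-direct"),
        "predrill-fig6-pilot": Scenario(
            drill=_DRILL_35, bone=bone_22, rotational_speed_rpm=800.0,
            feed_force_n=20.0, predrill_diameter_mm=2.5,
            name="predrill-fig6-pilot"),
    }
    # Feed-force study: 3.5 mm, 800 rpm, probe at x = 0.1 mm, z = 1 mm.
    for force in (10.0, 20.0, 40.0, 60.0):
        name = f"feedforce-fig5-{int(force)}"
        p[name] = Scenario(
            drill=_DRILL_35, bone=bone_22, rotational_speed_rpm=800.0,
            feed_force_n=force, name=name)
    # TAZ-vs-depth study; the feed force is not stated for these runs, the
    # presets use the mid-range 20 N used by every other single-force study.
    for dia, fig in ((_DRILL_35, "fig7a"), (_DRILL_45, "fig7b")):
        for rpm in (800.0, 2000.0):
            name = f"taz-{fig}-{int(rpm)}"
            p[name] = Scenario(
                drill=dia, bone=bone_22, rotational_speed_rpm=rpm,
                feed_force_n=20.0, name=name)
    # Alias: "predrill-fig6" means the two-stage (pilot) arm.
    p["predrill-fig6"] = replace(p["predrill-fig6-pilot"], name="predrill-fig6")
    return p


def preset_names() -> list[str]:
    return sorted(_presets().keys())


def preset_scenario(name: str, calibration: Optional["FeedCalibration"] = None) -> Scenario:
    """Build one of the named study configurations.

    Raises :class:`UnknownPresetError` listing the available ids if ``name``
    is not a documented preset.
    """
    table = _presets()
    if name not in table:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(table))}")
    s = table[name]
    if calibration is not None:
        s = s.with_calibration(calibration)
    return s


# ---------------------------------------------------------------------------
# YAML serialisation (one document per scenario; lengths in mm, temps in °C).
# ---------------------------------------------------------------------------

def scenario_to_dict(s: Scenario) -> dict:
    d = asdict(s)
    if s.calibration is not None:
        from .heat import FeedCalibration  # local import avoids cycle
        d["calibration"] = asdict(s.calibration)
    return d


def scenario_from_dict(d: dict) -> Scenario:
    from .heat import FeedCalibration

    d = dict(d)
    d["drill"] = DrillSpec(**{**d["drill"], "material": MaterialProps(**d["drill"]["material"])})
    d["bone"] = BoneSpec(**{**d["bone"], "material": MaterialProps(**d["bone"]["material"])})
    if d.get("calibration") is not None:
        d["calibration"] = FeedCalibration(**d["calibration"])
    return Scenario(**d)


def save_scenario(s: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(s), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
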