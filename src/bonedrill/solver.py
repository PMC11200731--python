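"""Axisymmetric transient conduction with a moving cutting front.

The cylindrical bone blank is discretised on a uniform (r, z) grid of
finite-volume cells (the azimuthal coordinate is eliminated by averaging the
rotating source over a revolution).  Conduction is integrated explicitly in
flux form, so enthalpy is conserved to round-off; all outer surfaces and the
hole wall behind the front are adiabatic.  The drill is represented purely
kinematically: cells whose centre falls inside the advancing tip cone are
excised together with their enthalpy (heat leaves with the chip), and the
bone share of the interface power is deposited on the cells currently
forming the conical front, weighted by local cone surface area.

That advective loss is what produces the clinically observed trends: at high
feed force or speed the front outruns its own thermal boundary layer
(thickness ~ alpha/v), so most interface heat is excised with the chips
before it can conduct into bone that stays behind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .materials import BoneSpec, DrillSpec, Scenario, validate_scenario
from .heat import (CalibrationMissingError, heat_source_state,
                   penetration_rate, removal_area_mm2, tip_depth_schedule)


class ScenarioError(ValueError):
    """A scenario failed invariant validation."""


class StabilityError(ValueError):
    """Requested explicit time step exceeds the diffusive stability limit."""


@dataclass
class Grid:
    """Uniform axisymmetric finite-volume grid.

    ``mask`` is True for bone cells; cells only transition bone -> removed.
    Axis 0 is z (0 at the entry surface), axis 1 is r (0 at the drill axis).
    """

    dr_m: float
    dz_m: float
    r_edges_m: np.ndarray          # (nr+1,)
    z_edges_m: np.ndarray          # (nz+1,)
    mask: np.ndarray               # (nz, nr) bool
    tip_depth_mm: float = 0.0

    def __post_init__(self):
        self.r_centers_m = 0.5 * (self.r_edges_m[:-1] + self.r_edges_m[1:])
        self.z_centers_m = 0.5 * (self.z_edges_m[:-1] + self.z_edges_m[1:])
        # Ring volume per radial index (identical for every z row).
        self.cell_volume_m3 = (np.pi * np.diff(self.r_edges_m ** 2) * self.dz_m)
        self.face_area_r_m2 = 2.0 * np.pi * self.r_edges_m[1:-1] * self.dz_m
        self.face_area_z_m2 = np.pi * np.diff(self.r_edges_m ** 2)

    @property
    def nr(self) -> int:
        return self.r_edges_m.size - 1

    @property
    def nz(self) -> int:
        return self.z_edges_m.size - 1

    @property
    def r_centers_mm(self) -> np.ndarray:
        return self.r_centers_m * 1e3

    @property
    def z_centers_mm(self) -> np.ndarray:
        return self.z_centers_m * 1e3

    def hole_radius_mm(self, z_mm: float, drill: DrillSpec) -> float:
        """Current hole-edge radius at depth ``z_mm`` for the given drill."""
        if z_mm > self.tip_depth_mm:
            return 0.0
        tan_phi = math.tan(drill.tip_half_angle_rad)
        return min(drill.radius_mm, (self.tip_depth_mm - z_mm) * tan_phi)

    def removed_volume_m3(self) -> float:
        return float(np.sum(np.broadcast_to(self.cell_volume_m3,
                                            self.mask.shape)[~self.mask]))


def build_grid(bone: BoneSpec, dr_mm: float, dz_mm: float,
               predrill_mm: Optional[float] = None) -> Grid:
    """Discretise the bone blank; all cells start as bone except a pilot hole.

    The spacings must tile the domain (radius and thickness) within rounding
    tolerance, and must not exceed it.
    """
    radius_mm = bone.outer_radius_mm
    thickness_mm = bone.thickness_mm
    for name, spacing, extent in (("dr_mm", dr_mm, radius_mm),
                                  ("dz_mm", dz_mm, thickness_mm)):
        if spacing <= 0:
            raise ValueError(f"{name} must be strictly positive")
        if spacing > extent:
            raise ValueError(f"{name}={spacing} exceeds the domain extent {extent} mm")
        n = extent / spacing
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ValueError(f"{name}={spacing} does not divide the domain extent {extent} mm")
    nr = round(radius_mm / dr_mm)
    nz = round(thickness_mm / dz_mm)
    r_edges = np.linspace(0.0, radius_mm * 1e-3, nr + 1)
    z_edges = np.linspace(0.0, thickness_mm * 1e-3, nz + 1)
    mask = np.ones((nz, nr), dtype=bool)
    grid = Grid(dr_m=dr_mm * 1e-3, dz_m=dz_mm * 1e-3,
                r_edges_m=r_edges, z_edges_m=z_edges, mask=mask)
    if predrill_mm is not None:
        grid.mask[:, grid.r_centers_mm < 0.5 * predrill_mm] = False
    return grid


def stable_time_step_s(grid: Grid, material) -> float:
    """Largest explicit time step: 1 / (2 alpha (1/dr^2 + 1/dz^2)).

    The cylindrical finite-volume coefficients reduce to exactly the
    Cartesian ones for uniform spacing (the face-area/volume ratios are
    2/dr and 2/dz for every ring, including the axis cell).
    """
    alpha = material.thermal_diffusivity_m2_s
    return 1.0 / (2.0 * alpha * (1.0 / grid.dr_m ** 2 + 1.0 / grid.dz_m ** 2))


def advance_front(grid: Grid, tip_depth_mm: float, drill: DrillSpec,
                  predrill_mm: Optional[float] = None,
                  ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Excise cells behind the advancing conical tip; locate the front.

    Returns ``(newly_removed, front)`` where ``newly_removed`` is a boolean
    (nz, nr) array of cells removed by this call and ``front`` is
    ``(iz, ir, weight)`` arrays of the bone cells on the cone surface with
    cone-surface-area weights (normalised to sum to 1) for flux deposition.
    Tip depth must be non-decreasing across calls: there is no un-drilling.
    """
    if tip_depth_mm < grid.tip_depth_mm - 1e-12:
        raise ValueError(
            f"tip depth must be non-decreasing (was {grid.tip_depth_mm} mm, "
            f"got {tip_depth_mm} mm): material cannot be un-removed")
    tan_phi = math.tan(drill.tip_half_angle_rad)
    R = drill.radius_mm
    rp = 0.5 * predrill_mm if predrill_mm is not None else 0.0
    z_mm = grid.z_centers_mm
    r_mm = grid.r_centers_mm

    # Hole radius at each row for the new tip position.
    rho = np.minimum(R, (tip_depth_mm - z_mm) * tan_phi)
    rho[z_mm > tip_depth_mm] = 0.0
    inside = r_mm[None, :] < rho[:, None]
    newly = inside & grid.mask
    grid.mask[newly] = False
    grid.tip_depth_mm = max(grid.tip_depth_mm, tip_depth_mm)

    # Front rows: cone surface at radius rho(z) within (pilot, R).
    sel = (rho > rp + 1e-12) & (rho < R - 1e-12) & (z_mm <= tip_depth_mm)
    iz = np.nonzero(sel)[0]
    if iz.size == 0:
        empty = np.zeros(0, dtype=int)
        return newly, (empty, empty, np.zeros(0))
    # First bone cell at or beyond the cone surface in each selected row.
    dr_mm_ = grid.dr_m * 1e3
    ir = np.ceil(rho[iz] / dr_mm_ - 0.5).astype(int)
    ir = np.clip(ir, 0, grid.nr - 1)
    keep = grid.mask[iz, ir]
    iz, ir = iz[keep], ir[keep]
    if iz.size == 0:
        empty = np.zeros(0, dtype=int)
        return newly, (empty, empty, np.zeros(0))
    # Local lateral cone area per row is 2*pi*rho*dz/cos(phi): weight by rho.
    w = rho[iz]
    w = w / w.sum()
    return newly, (iz, ir, w)


def conduction_step(T: np.ndarray, grid: Grid, conductivity_w_m_k: float,
                    volumetric_heat_capacity: float, dt_s: float,
                    power_w: float = 0.0,
                    deposit: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
                    _ctx: Optional[dict] = None) -> np.ndarray:
    """One explicit finite-volume update; returns the new temperature field.

    ``deposit`` is an ``(iz, ir, weight)`` triple describing where the
    source power enters (weights must sum to 1).  Faces touching a removed
    cell or the domain boundary carry no flux (adiabatic).  With zero power
    and a uniform field the field is returned unchanged to round-off; the
    enthalpy added over the step equals ``power_w * dt_s`` exactly.
    """
    limit = stable_time_step_s(grid, _Mat(conductivity_w_m_k, volumetric_heat_capacity))
    if dt_s > limit * (1.0 + 1e-9):
        raise StabilityError(
            f"dt={dt_s:.3e} s exceeds the explicit stability limit {limit:.3e} s")
    if _ctx is None:
        _ctx = {}
    if _ctx.get("mask_version") != id(grid.mask) or _ctx.get("mask_sum") != int(grid.mask.sum()):
        _ctx["both_r"] = grid.mask[:, 1:] & grid.mask[:, :-1]
        _ctx["both_z"] = grid.mask[1:, :] & grid.mask[:-1, :]
        _ctx["mask_version"] = id(grid.mask)
        _ctx["mask_sum"] = int(grid.mask.sum())
    k = conductivity_w_m_k
    cond_r = k * grid.face_area_r_m2 / grid.dr_m       # (nr-1,)
    cond_z = k * grid.face_area_z_m2 / grid.dz_m       # (nr,)

    fr = cond_r * (T[:, 1:] - T[:, :-1]) * _ctx["both_r"]
    fz = cond_z * (T[1:, :] - T[:-1, :]) * _ctx["both_z"]
    dU = np.zeros_like(T)
    dU[:, :-1] += fr
    dU[:, 1:] -= fr
    dU[:-1, :] += fz
    dU[1:, :] -= fz
    if power_w and deposit is not None and deposit[0].size:
        iz, ir, w = deposit
        np.add.at(dU, (iz, ir), power_w * w)
    return T + dt_s * dU / (volumetric_heat_capacity * grid.cell_volume_m3)


class _Mat:
    """Minimal duck-typed material for stable_time_step_s."""

    def __init__(self, k, rhoc):
        self.thermal_diffusivity_m2_s = k / rhoc


@dataclass
class FieldHistory:
    """Time-stamped axisymmetric temperature fields plus derived series.

    ``running_max`` is the per-cell maximum temperature over the whole
    history (frozen at excision for removed cells); it is the field the
    TAZ analysis thresholds.  Probe series are stored at full time-step
    resolution for the points requested at simulation time.
    """

    grid: Grid
    times_s: np.ndarray                        # snapshot times
    fields_c: list                             # snapshot temperature fields
    masks: list                                # snapshot masks
    running_max_c: np.ndarray
    probe_points_mm: list                      # [(x_offset, depth), ...]
    probe_times_s: np.ndarray
    probe_series_c: np.ndarray                 # (nstep, nprobe)
    hole_edge_radius_mm: float
    initial_temperature_c: float
    drilling_time_s: float
    energy_j: dict = field(default_factory=dict)
    scenario: Optional[Scenario] = None

    def __post_init__(self):
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    def probe(self, x_offset_mm: float, depth_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Full-resolution series for a probe recorded during the run."""
        for i, (x, z) in enumerate(self.probe_points_mm):
            if abs(x - x_offset_mm) < 1e-9 and abs(z - depth_mm) < 1e-9:
                return self.probe_times_s, self.probe_series_c[:, i]
        raise KeyError(
            f"probe ({x_offset_mm}, {depth_mm}) mm was not recorded; "
            f"available probes: {self.probe_points_mm}")

    def probe_peak(self, x_offset_mm: float, depth_mm: float) -> tuple[float, float]:
        """(peak temperature °C, time of peak s) of a recorded probe."""
        t, series = self.probe(x_offset_mm, depth_mm)
        i = int(np.argmax(series))
        return float(series[i]), float(t[i])


def interp_field(grid: Grid, field_c: np.ndarray, r_mm: float, z_mm: float) -> float:
    """Bilinear interpolation at (r, z) in mm, clamped to cell-centre range.

    Positions must lie inside the physical domain; the half-cell margin
    between the outermost centres and the domain edges is clamped.
    """
    r_max = grid.r_edges_m[-1] * 1e3
    z_max = grid.z_edges_m[-1] * 1e3
    if not (0.0 <= r_mm <= r_max + 1e-9) or not (0.0 <= z_mm <= z_max + 1e-9):
        raise ValueError(
            f"probe (r={r_mm} mm, z={z_mm} mm) lies outside the domain "
            f"(r <= {r_max} mm, z <= {z_max} mm)")
    w_r, i_r = _axis_weights(grid.r_centers_mm, r_mm)
    w_z, i_z = _axis_weights(grid.z_centers_mm, z_mm)
    block = field_c[np.ix_(i_z, i_r)]
    return float(w_z @ block @ w_r)


def _axis_weights(centers: np.ndarray, x: float) -> tuple[np.ndarray, np.ndarray]:
    x = min(max(x, centers[0]), centers[-1])
    j = int(np.searchsorted(centers, x))
    if j == 0:
        return np.array([1.0]), np.array([0])
    f = (x - centers[j - 1]) / (centers[j] - centers[j - 1])
    return np.array([1.0 - f, f]), np.array([j - 1, j])


def simulate(scenario: Scenario,
             probe_points_mm: Optional[Sequence[tuple[float, float]]] = None,
             snapshot_dt_s: float = 0.1) -> FieldHistory:
    """Run one complete drilling simulation.

    The time loop couples the force-controlled penetration rate, kinematic
    front advance, interface heat generation and partition, and the explicit
    conduction update; sources switch off when the tip reaches the target
    depth and conduction continues through a post-drilling hold.  Probe
    offsets are measured radially from the final hole edge (r = D/2 + x).
    """
    violations = validate_scenario(scenario)
    if violations:
        raise ScenarioError("invalid scenario: " + "; ".join(violations))
    if scenario.calibration is None:
        raise CalibrationMissingError(
            "scenario has no feed calibration; build one with "
            "bonedrill.calibrate.default_calibration() or calibrate_feed()")

    mat = scenario.bone.material
    k = mat.thermal_conductivity_w_m_k
    rhoc = mat.volumetric_heat_capacity_j_m3_c
    T0 = scenario.bone.initial_temperature_c

    grid = build_grid(scenario.bone, scenario.grid_spacing_mm,
                      scenario.grid_spacing_mm, scenario.predrill_diameter_mm)
    dt = scenario.time_step_safety * min(grid.dr_m, grid.dz_m) ** 2 / (
        2.0 * mat.thermal_diffusivity_m2_s)

    v_nom = penetration_rate(scenario)                   # mm/s, fully engaged
    target_mm = scenario.effective_target_depth_mm
    t_sched, d_sched, t_drill = tip_depth_schedule(scenario, target_mm)
    a_full_mm2 = math.pi * scenario.drill.radius_mm ** 2
    t_end = min(t_drill + scenario.post_drill_hold_s, scenario.max_time_s)
    n_steps = int(math.ceil(t_end / dt))

    if probe_points_mm is None:
        probe_points_mm = [(0.1, 1.0), (0.5, 4.0)]
    probe_points_mm = list(probe_points_mm)
    hole_edge = scenario.drill.radius_mm
    probe_w = []
    for x, z in probe_points_mm:
        wr, ir = _axis_weights(grid.r_centers_mm, hole_edge + x)
        wz, iz = _axis_weights(grid.z_centers_mm, z)
        if hole_edge + x > grid.r_edges_m[-1] * 1e3 + 1e-9:
            raise ValueError(f"probe offset {x} mm places the probe outside the domain")
        probe_w.append((wr, ir, wz, iz))

    T = np.full((grid.nz, grid.nr), T0, dtype=float)
    running_max = T.copy()
    cell_vol = np.broadcast_to(grid.cell_volume_m3, T.shape)

    probe_times = np.empty(n_steps + 1)
    probe_series = np.empty((n_steps + 1, len(probe_points_mm)))
    probe_times[0] = 0.0
    probe_series[0, :] = T0

    snap_times = [0.0]
    snap_fields = [T.copy()]
    snap_masks = [grid.mask.copy()]
    next_snap = snapshot_dt_s

    e_in = 0.0
    e_removed = 0.0
    ctx: dict = {}

    for n in range(n_steps):
        t = n * dt
        power = 0.0
        deposit = None
        if t < t_drill:
            tip = min(float(np.interp(t, t_sched, d_sched)), target_mm)
            newly, deposit = advance_front(grid, tip, scenario.drill,
                                           scenario.predrill_diameter_mm)
            if newly.any():
                e_removed += float(np.sum((T[newly] - T0) * rhoc * cell_vol[newly]))
                T[newly] = T0
            a_eng = removal_area_mm2(scenario.drill, scenario.bone.thickness_mm,
                                     scenario.predrill_diameter_mm, tip)
            v_inst = v_nom * a_full_mm2 / a_eng if a_eng > 0 else 0.0
            src = heat_source_state(scenario, v_inst, tip)
            if deposit[0].size:
                power = src.flux_to_bone_w
        T = conduction_step(T, grid, k, rhoc, dt, power, deposit, _ctx=ctx)
        e_in += power * dt
        np.maximum(running_max, T, out=running_max, where=grid.mask)
        probe_times[n + 1] = t + dt
        for j, (wr, ir, wz, iz) in enumerate(probe_w):
            probe_series[n + 1, j] = wz @ T[np.ix_(iz, ir)] @ wr
        if t + dt >= next_snap - 1e-12 or n == n_steps - 1:
            snap_times.append(t + dt)
            snap_fields.append(T.copy())
            snap_masks.append(grid.mask.copy())
            next_snap += snapshot_dt_s
        if n % 200 == 0 and not np.all(np.isfinite(T)):
            raise FloatingPointError(
                f"non-finite temperature at t={t:.4f} s (step {n}); "
                "diagnostic snapshot retained in history")

    e_stored = float(np.sum((T[grid.mask] - T0) * rhoc * cell_vol[grid.mask]))
    return FieldHistory(
        grid=grid,
        times_s=np.asarray(snap_times),
        fields_c=snap_fields,
        masks=snap_masks,
        running_max_c=running_max,
        probe_points_mm=probe_points_mm,
        probe_times_s=probe_times,
        probe_series_c=probe_series,
        hole_edge_radius_mm=hole_edge,
        initial_temperature_c=T0,
        drilling_time_s=t_drill,
        energy_j={"absorbed": e_in, "removed": e_removed, "stored": e_stored},
        scenario=scenario,
    )
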