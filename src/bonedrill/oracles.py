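"""Analytic conduction solutions and synthetic fixtures.

Everything here is implemented directly from closed forms, independent of
the finite-volume solver, so the ``verify`` suite genuinely cross-checks
the discretisation rather than re-running it:

* semi-infinite solid under constant surface heat flux (the classic
  erfc/ierfc solution),
* instantaneous ring source in an infinite medium (axisymmetric heat
  kernel with a Bessel ``I0`` azimuthal integral),
* synthetic field histories with closed-form running maxima, used to test
  the TAZ analysis without running the solver at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import erfc, i0e

from .materials import BoneSpec, MaterialProps, CORTICAL_BONE


@dataclass(frozen=True)
class FixtureCase:
    """One verification case: a solver run compared with a closed form."""

    name: str
    tolerance: float           # relative
    runner: Callable[[float], tuple[float, float]]  # grid_mm -> (err, tol)

    def run(self, grid_mm: float = 0.05) -> dict:
        err, tol = self.runner(grid_mm)
        return {"case": self.name, "max_rel_error": err,
                "tolerance": tol, "passed": err <= tol}


def halfspace_constant_flux(q_w_m2: float, material: MaterialProps,
                            t_s: float, depth_m: float = 0.0) -> float:
    """Temperature rise (°C) in a half-space under constant surface flux.

    dT = (2q/k) sqrt(alpha t / pi) exp(-d^2/(4 alpha t))
         - (q d / k) erfc(d / (2 sqrt(alpha t)))
    """
    if t_s <= 0:
        raise ValueError(f"t_s must be strictly positive, got {t_s}")
    if depth_m < 0:
        raise ValueError(f"depth_m must be non-negative, got {depth_m}")
    k = material.thermal_conductivity_w_m_k
    alpha = material.thermal_diffusivity_m2_s
    s = math.sqrt(alpha * t_s)
    return (2.0 * q_w_m2 / k * s / math.sqrt(math.pi)
            * math.exp(-depth_m ** 2 / (4.0 * alpha * t_s))
            - q_w_m2 * depth_m / k * float(erfc(depth_m / (2.0 * s))))


def halfspace_flux_quadrature(q_w_m2: float, material: MaterialProps,
                              t_s: float, depth_m: float = 0.0,
                              n: int = 20000) -> float:
    """Same rise by direct time quadrature of the 1-D surface-source kernel.

    dT(d, t) = (q / rho c) * int_0^t exp(-d^2/(4 alpha tau)) / sqrt(pi alpha tau) dtau,
    evaluated on a square-root-stretched grid to tame the integrable
    endpoint singularity.  Used only as an independent check of the closed
    form above.
    """
    if t_s <= 0:
        raise ValueError("t_s must be strictly positive")
    alpha = material.thermal_diffusivity_m2_s
    rhoc = material.volumetric_heat_capacity_j_m3_c
    u = np.linspace(0.0, math.sqrt(t_s), n + 1)[1:]   # tau = u^2, dtau = 2u du
    tau = u ** 2
    kern = np.exp(-depth_m ** 2 / (4.0 * alpha * tau)) / np.sqrt(math.pi * alpha * tau)
    return float(q_w_m2 / rhoc * np.trapezoid(kern * 2.0 * u, u))


def instantaneous_ring_source(energy_j: float, material: MaterialProps,
                              r0_m: float, z0_m: float, t_s: float,
                              r_m: float, z_m: float) -> float:
    """Temperature rise of an instantaneous ring source in an infinite medium.

    dT = E / (rho c (4 pi alpha t)^{3/2})
         * exp(-((r - r0)^2 + (z - z0)^2) / (4 alpha t)) * i0e(r r0 / (2 alpha t))

    written with the exponentially scaled Bessel function for numerical
    stability at large arguments.
    """
    if t_s <= 0:
        raise ValueError(f"t_s must be strictly positive, got {t_s}")
    alpha = material.thermal_diffusivity_m2_s
    rhoc = material.volumetric_heat_capacity_j_m3_c
    four_at = 4.0 * alpha * t_s
    pref = energy_j / (rhoc * (math.pi * four_at) ** 1.5)
    arg = (r_m - r0_m) ** 2 + (z_m - z0_m) ** 2
    return float(pref * math.exp(-arg / four_at) * i0e(2.0 * r_m * r0_m / four_at))


def ring_source_enthalpy_j(energy_j: float, material: MaterialProps,
                           r0_m: float, z0_m: float, t_s: float,
                           r_max_m: float = 0.02, z_half_m: float = 0.02,
                           n: int = 400) -> float:
    """Numerically integrate rho c dT over a large cylinder (checks ~ E)."""
    r = np.linspace(0, r_max_m, n + 1)[1:] - 0.5 * r_max_m / n
    z = np.linspace(z0_m - z_half_m, z0_m + z_half_m, n)
    rr, zz = np.meshgrid(r, z, indexing="ij")
    alpha = material.thermal_diffusivity_m2_s
    rhoc = material.volumetric_heat_capacity_j_m3_c
    four_at = 4.0 * alpha * t_s
    pref = energy_j / (rhoc * (math.pi * four_at) ** 1.5)
    dT = pref * np.exp(-((rr - r0_m) ** 2 + (zz - z0_m) ** 2) / four_at) \
        * i0e(2.0 * rr * r0_m / four_at)
    dv = 2.0 * np.pi * rr * (r_max_m / n) * (z[1] - z[0])
    return float(np.sum(rhoc * dT * dv))


# ---------------------------------------------------------------------------
# Synthetic histories with closed-form analysis results.
# ---------------------------------------------------------------------------

def make_synthetic_history(spec: dict):
    """Build a FieldHistory whose analysis outputs have closed-form values.

    ``spec`` keys:

    kind
        ``"gaussian"``: Tmax(x, z) = T0 + A(z) exp(-x^2 / (2 sigma^2));
        ``"exponential"``: Tmax(x, z) = T0 + A(z) exp(-x / lam);
        ``"constant"``: Tmax = T0 everywhere.
    hole_radius_mm, baseline_c, amplitude_c, amplitude_slope_c_per_mm,
    sigma_mm / lambda_mm, grid_spacing_mm
        geometry and profile parameters (x is the offset beyond the hole
        edge; the amplitude may grow linearly with depth).
    """
    from .solver import FieldHistory, build_grid   # deferred import

    known = {"kind", "hole_radius_mm", "baseline_c", "amplitude_c",
             "amplitude_slope_c_per_mm", "sigma_mm", "lambda_mm",
             "grid_spacing_mm"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown synthetic-history keys: {sorted(unknown)}")
    kind = spec.get("kind")
    if kind not in ("gaussian", "exponential", "constant"):
        raise ValueError(f"kind must be gaussian|exponential|constant, got {kind!r}")

    h_mm = float(spec.get("grid_spacing_mm", 0.05))
    hole_r = float(spec.get("hole_radius_mm", 1.75))
    T0 = float(spec.get("baseline_c", 22.0))
    a0 = float(spec.get("amplitude_c", 0.0))
    a1 = float(spec.get("amplitude_slope_c_per_mm", 0.0))

    grid = build_grid(BoneSpec(), h_mm, h_mm, predrill_mm=2.0 * hole_r)
    r = grid.r_centers_mm
    z = grid.z_centers_mm
    x = np.maximum(r[None, :] - hole_r, 0.0)
    amp = a0 + a1 * z[:, None]
    if kind == "gaussian":
        sigma = float(spec.get("sigma_mm", 0.3))
        field = T0 + amp * np.exp(-x ** 2 / (2.0 * sigma ** 2))
    elif kind == "exponential":
        lam = float(spec.get("lambda_mm", 0.3))
        field = T0 + amp * np.exp(-x / lam)
    else:
        field = np.full((grid.nz, grid.nr), T0)
    field = np.asarray(field, dtype=float)

    return FieldHistory(
        grid=grid,
        times_s=np.array([0.0, 1.0]),
        fields_c=[field.copy(), field.copy()],
        masks=[grid.mask.copy(), grid.mask.copy()],
        running_max_c=field,
        probe_points_mm=[],
        probe_times_s=np.array([0.0]),
        probe_series_c=np.zeros((1, 0)),
        hole_edge_radius_mm=hole_r,
        initial_temperature_c=T0,
        drilling_time_s=0.0,
    )


# ---------------------------------------------------------------------------
# The verify suite: solver vs closed forms on fixture grids.
# ---------------------------------------------------------------------------

def _run_halfspace_case(grid_mm: float) -> tuple[float, float]:
    """Uniform flux on the top face vs the 1-D half-space closed form.

    Checked well before the thermal front reaches the bottom boundary
    (penetration depth ~ sqrt(alpha t) << thickness).
    """
    from .solver import Grid, build_grid, conduction_step, stable_time_step_s

    mat = CORTICAL_BONE
    bone = BoneSpec()
    grid = build_grid(bone, grid_mm, grid_mm)
    q = 1.0e4                                    # W/m^2
    area = math.pi * (grid.r_edges_m[-1]) ** 2
    power = q * area
    iz = np.zeros(grid.nr, dtype=int)
    ir = np.arange(grid.nr)
    w = grid.face_area_z_m2 / area
    dt = 0.8 * stable_time_step_s(grid, mat)
    t_check = 2.0
    n = int(round(t_check / dt))
    T = np.zeros((grid.nz, grid.nr))
    ctx: dict = {}
    for _ in range(n):
        T = conduction_step(T, grid, mat.thermal_conductivity_w_m_k,
                            mat.volumetric_heat_capacity_j_m3_c, dt,
                            power, (iz, ir, w), _ctx=ctx)
    t_end = n * dt
    errs = []
    for j in range(0, 12, 3):                    # surface and shallow cells
        exact = halfspace_constant_flux(q, mat, t_end, grid.z_centers_m[j])
        errs.append(abs(T[j, grid.nr // 2] - exact) / exact)
    return max(errs), 0.03


def _run_ring_case(grid_mm: float) -> tuple[float, float]:
    """Instantaneous hot ring: enthalpy conservation + kernel comparison."""
    from .solver import build_grid, conduction_step, stable_time_step_s

    mat = CORTICAL_BONE
    bone = BoneSpec()
    grid = build_grid(bone, grid_mm, grid_mm)
    rhoc = mat.volumetric_heat_capacity_j_m3_c
    energy = 0.5                                 # J
    r0, z0 = 1.0e-3, 2.0e-3
    i_r = int(np.argmin(np.abs(grid.r_centers_m - r0)))
    i_z = int(np.argmin(np.abs(grid.z_centers_m - z0)))
    T = np.zeros((grid.nz, grid.nr))
    T[i_z, i_r] = energy / (rhoc * grid.cell_volume_m3[i_r])
    vol = np.broadcast_to(grid.cell_volume_m3, T.shape)
    dt = 0.8 * stable_time_step_s(grid, mat)
    t_check = 0.25
    ctx: dict = {}
    for _ in range(int(round(t_check / dt))):
        T = conduction_step(T, grid, mat.thermal_conductivity_w_m_k, rhoc, dt,
                            _ctx=ctx)
    t_end = round(t_check / dt) * dt
    enthalpy = float(np.sum(rhoc * T * vol))
    enthalpy_err = abs(enthalpy - energy) / energy
    # Field comparison at a few off-source points (infinite-medium kernel;
    # the finite adiabatic boundaries are still far at sqrt(4 alpha t)).
    errs = [enthalpy_err]
    for dr_, dz_ in ((0.3e-3, 0.0), (0.0, 0.4e-3), (-0.4e-3, 0.2e-3)):
        exact = instantaneous_ring_source(energy, mat, grid.r_centers_m[i_r],
                                          grid.z_centers_m[i_z], t_end,
                                          grid.r_centers_m[i_r] + dr_,
                                          grid.z_centers_m[i_z] + dz_)
        got = T[i_z + int(round(dz_ / grid.dz_m)),
                i_r + int(round(dr_ / grid.dr_m))]
        errs.append(abs(got - exact) / exact)
    return max(errs), 0.08


def _run_enthalpy_only_case(grid_mm: float) -> tuple[float, float]:
    err, _ = _run_ring_case(grid_mm)
    return err, 0.005


def fixture_cases() -> list[FixtureCase]:
    return [
        FixtureCase("halfspace-constant-flux", 0.03, _run_halfspace_case),
        FixtureCase("ring-source-kernel", 0.08, _run_ring_case),
    ]


def verify_suite(grid_mm: float = 0.05) -> pd.DataFrame:
    """Run every fixture case; returns (case, max rel. error, tolerance, pass)."""
    rows = [case.run(grid_mm) for case in fixture_cases()]
    # Ring enthalpy alone, at the tight conservation tolerance.
    from .solver import build_grid  # noqa: F401  (import parity with cases)
    err, tol = _ring_enthalpy_error(grid_mm)
    rows.append({"case": "ring-source-enthalpy", "max_rel_error": err,
                 "tolerance": tol, "passed": err <= tol})
    return pd.DataFrame(rows)


def _ring_enthalpy_error(grid_mm: float) -> tuple[float, float]:
    from .solver import build_grid, conduction_step, stable_time_step_s

    mat = CORTICAL_BONE
    grid = build_grid(BoneSpec(), grid_mm, grid_mm)
    rhoc = mat.volumetric_heat_capacity_j_m3_c
    energy = 0.5
    i_r = int(np.argmin(np.abs(grid.r_centers_m - 1.0e-3)))
    i_z = int(np.argmin(np.abs(grid.z_centers_m - 2.0e-3)))
    T = np.zeros((grid.nz, grid.nr))
    T[i_z, i_r] = energy / (rhoc * grid.cell_volume_m3[i_r])
    vol = np.broadcast_to(grid.cell_volume_m3, T.shape)
    dt = 0.8 * stable_time_step_s(grid, mat)
    ctx: dict = {}
    for _ in range(int(round(1.0 / dt))):
        T = conduction_step(T, grid, mat.thermal_conductivity_w_m_k, rhoc, dt,
                            _ctx=ctx)
    return abs(float(np.sum(rhoc * T * vol)) - energy) / energy, 0.005
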