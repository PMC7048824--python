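"""Quasi-1D laminar airflow through a bilateral duct geometry.

Steady, incompressible, laminar flow under the standard restful-breathing
boundary conditions: 0 Pa relative static pressure at both nostrils and a
prescribed total flow rate (default 200 ml/s, i.e. a 6 l respiratory minute
volume under equal-phase quasi-steady breathing) at the shared pharynx.

The axial model is the exact fully developed elliptical-duct law

    dp/dx = 4 μ Q (a² + b²) / (π a³ b³)

(reducing to Poiseuille 8μQ/(πr⁴) for a = b = r), integrated by the
trapezoidal rule over the centerline stations, plus optional
direction-dependent Borda–Carnot minor losses  Δp = K·ρ·u²/2 with
K = (1 − A_small/A_large)²  at each station transition that expands in the
flow direction.  The minor losses are the (sole, deliberately minimal)
mechanism that breaks inspiration/expiration symmetry; without them the
model is linear (Stokes regime) and exactly reversible.

Wall shear stress comes from the exact axial force balance of fully
developed flow,  τ = |dp/ds|_visc · A / P,  evaluated per station; minor
losses model separated flow whose momentum does not load the wall as
developed shear and are excluded from τ.

Units: SI internally; the API takes flow in ml/s and reports pressures in
Pa, resistances in Pa·s/ml and velocities in m/s, mirroring clinical usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .geometry import DuctGeometry, SideProfile, SIDE_NAMES

logger = logging.getLogger(__name__)

MM = 1e-3  # mm -> m
MM2 = 1e-6  # mm² -> m²
MLS = 1e-6  # ml/s -> m³/s
SPEED_OF_SOUND_MS = 340.0

INSPIRATION = "inspiration"
EXPIRATION = "expiration"


@dataclass(frozen=True)
class FluidProperties:
    """Respired air at body conditions (defaults: ρ=1.18 kg/m³, μ=18.6 μPa·s)."""

    density: float = 1.18  # kg/m³
    dynamic_viscosity: float = 1.86e-5  # Pa·s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be strictly positive")


@dataclass(frozen=True)
class BreathingPhase:
    """One quasi-steady breathing phase at a fixed total (bilateral) flow."""

    label: str = INSPIRATION
    total_flow_mls: float = 200.0

    def __post_init__(self):
        if self.label not in (INSPIRATION, EXPIRATION):
            raise ValueError(f"unknown phase label: {self.label!r}")
        if self.total_flow_mls <= 0:
            raise ValueError("total flow must be positive")


def quasi_steady_flow_mls(
    minute_volume_l: float = 6.0, phase_fraction: float = 0.5
) -> float:
    """Representative steady phase flow rate for a respiratory minute volume.

    With equal-duration inspiration and expiration (phase_fraction = 0.5), a
    6 l/min minute volume moves 6000 ml through the nose in the 30 s spent
    in each phase: 200 ml/s.
    """
    if minute_volume_l <= 0 or not (0 < phase_fraction <= 1):
        raise ValueError("minute volume and phase fraction must be positive")
    return minute_volume_l * 1000.0 / (60.0 * phase_fraction)


@dataclass
class FlowSolution:
    """Flow through one bilateral geometry for one breathing phase."""

    phase: BreathingPhase
    q_left_mls: float
    q_right_mls: float
    dp_pa: float  # common nostril-to-pharynx pressure drop magnitude
    station_pressures_pa: Dict[str, np.ndarray]  # per side, indexed by station
    station_velocity_ms: Dict[str, np.ndarray]  # u(s) = Q/A per side
    wall_pressure_pa: Optional[np.ndarray] = None  # per vertex
    wall_shear_stress_pa: Optional[np.ndarray] = None  # per vertex
    mach_max: float = field(default=0.0)

    @property
    def airflow_partitioning_pct(self) -> float:
        """Left share of the bilateral airflow, percent."""
        return 100.0 * self.q_left_mls / (self.q_left_mls + self.q_right_mls)


def _side_profile(g: DuctGeometry, side: str) -> SideProfile:
    if side not in SIDE_NAMES or side == "shared":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if side not in g.profiles:
        raise ValueError(
            f"geometry has no '{side}' profile; compute or attach profiles first"
        )
    return g.profiles[side]


def _pressure_run(
    prof: SideProfile,
    q_mls: float,
    fluid: FluidProperties,
    direction: str,
    losses: bool,
    contraction_coefficient: float = 0.0,
) -> Tuple[float, np.ndarray]:
    """Total drop (Pa) and station pressures (Pa, nostril = 0) for one side."""
    a = prof.semi_axis_a_mm * MM
    b = prof.semi_axis_b_mm * MM
    area = prof.area_mm2 * MM2
    ell = prof.arclength_mm * MM
    if np.any(area <= 0):
        raise ValueError("non-positive cross-sectional area")
    q = q_mls * MLS
    if q < 0:
        raise ValueError("flow rate must be non-negative")

    mu = fluid.dynamic_viscosity
    grad = 4.0 * mu * q * (a**2 + b**2) / (np.pi * a**3 * b**3)  # Pa/m, ≥ 0
    # cumulative viscous drop from the nostril (station 0) to each station
    seg = 0.5 * (grad[1:] + grad[:-1]) * np.diff(ell)
    visc_cum = np.concatenate([[0.0], np.cumsum(seg)])

    n = area.size
    loss_cum = np.zeros(n)  # minor-loss drop accumulated from the nostril
    if losses and q > 0:
        rho = fluid.density
        if direction == INSPIRATION:
            order = range(n - 1)  # transitions i -> i+1 in flow direction
        else:
            order = range(n - 1, 0, -1)  # i -> i-1
        loss_at = np.zeros(n)  # loss assigned to the downstream-station slot
        for i in order:
            jnxt = i + 1 if direction == INSPIRATION else i - 1
            a_up, a_dn = area[i], area[jnxt]
            if a_dn > a_up:  # expansion in flow direction
                k_loss = (1.0 - a_up / a_dn) ** 2
                loss_at[max(i, jnxt)] += k_loss * rho * (q / a_up) ** 2 / 2.0
            elif contraction_coefficient > 0 and a_dn < a_up:
                loss_at[max(i, jnxt)] += (
                    contraction_coefficient * rho * (q / a_dn) ** 2 / 2.0
                )
        loss_cum = np.cumsum(loss_at)

    drop_from_nostril = visc_cum + loss_cum  # pressure lost between nostril and s
    total = float(drop_from_nostril[-1])
    if direction == INSPIRATION:
        p = -drop_from_nostril  # flow nostril -> pharynx, p decreases
    else:
        p = drop_from_nostril  # flow pharynx -> nostril, pharynx is upstream
    return total, p


def lateral_pressure_drop(
    g: DuctGeometry,
    side: str,
    q_mls: float,
    fluid: FluidProperties = FluidProperties(),
    direction: str = INSPIRATION,
    losses: bool = False,
    contraction_coefficient: float = 0.0,
) -> Tuple[float, np.ndarray]:
    """Nostril-to-pharynx pressure drop (Pa) of one side at flow ``q_mls``,
    plus station pressures referenced to 0 Pa at the nostril.

    Returns (0.0, zeros) for zero flow.
    """
    prof = _side_profile(g, side)
    if q_mls == 0:
        return 0.0, np.zeros(prof.n_stations)
    return _pressure_run(prof, q_mls, fluid, direction, losses, contraction_coefficient)


def lateral_resistance(
    g: DuctGeometry,
    side: str,
    q_mls: float,
    fluid: FluidProperties = FluidProperties(),
    direction: str = INSPIRATION,
    losses: bool = False,
    contraction_coefficient: float = 0.0,
) -> float:
    """Lateral nasal resistance R = Δp / Q in Pa·s/ml."""
    if q_mls <= 0:
        raise ValueError("resistance needs a positive flow rate")
    dp, _ = lateral_pressure_drop(
        g, side, q_mls, fluid, direction, losses, contraction_coefficient
    )
    return dp / q_mls


def total_resistance(r_left: float, r_right: float) -> float:
    """Parallel combination R_total = R_left·R_right / (R_left + R_right)."""
    if r_left <= 0 or r_right <= 0:
        raise ValueError("lateral resistances must be positive")
    return r_left * r_right / (r_left + r_right)


def solve_bilateral_partition(
    g: DuctGeometry,
    phase: BreathingPhase,
    fluid: FluidProperties = FluidProperties(),
    losses: bool = False,
    contraction_coefficient: float = 0.0,
    tol_pa: float = 1e-9,
    max_iter: int = 200,
    with_wall_fields: bool = True,
) -> FlowSolution:
    """Partition the total flow over the two sides by pressure matching.

    Both nostrils sit at 0 Pa and the sides meet at a common pharynx
    pressure, so the left flow solves Δp_left(Q) = Δp_right(V̇ − Q).  Δp is
    strictly increasing in Q, hence bisection on Q_left ∈ (0, V̇) converges;
    the symmetric first midpoint V̇/2 makes mirror-symmetric geometries
    resolve to an exact 50/50 partition.  With losses off the solution
    coincides with the two-resistor current divider
    Q_left = V̇·R_right/(R_left+R_right).
    """
    vdot = phase.total_flow_mls
    direction = phase.label

    def mismatch(q_left: float) -> Tuple[float, np.ndarray, np.ndarray]:
        dl, pl = lateral_pressure_drop(
            g, "left", q_left, fluid, direction, losses, contraction_coefficient
        )
        dr, pr = lateral_pressure_drop(
            g, "right", vdot - q_left, fluid, direction, losses, contraction_coefficient
        )
        return dl - dr, pl, pr

    eps = vdot * 1e-12
    lo, hi = eps, vdot - eps
    q = 0.5 * (lo + hi)
    for _ in range(max_iter):
        f, pl, pr = mismatch(q)
        if abs(f) <= tol_pa:
            break
        if f > 0:  # left drop too large -> shift flow to the right
            hi = q
        else:
            lo = q
        q = 0.5 * (lo + hi)
    else:
        f, pl, pr = mismatch(q)
        if abs(f) > tol_pa:
            raise RuntimeError(
                f"bilateral partition did not converge: |Δp mismatch| = {abs(f):.3e} Pa"
            )

    dl, _ = lateral_pressure_drop(
        g, "left", q, fluid, direction, losses, contraction_coefficient
    )
    sol = FlowSolution(
        phase=phase,
        q_left_mls=q,
        q_right_mls=vdot - q,
        dp_pa=dl,
        station_pressures_pa={"left": pl, "right": pr},
        station_velocity_ms={
            "left": q * MLS / (g.profiles["left"].area_mm2 * MM2),
            "right": (vdot - q) * MLS / (g.profiles["right"].area_mm2 * MM2),
        },
    )
    u_max = max(sol.station_velocity_ms["left"].max(), sol.station_velocity_ms["right"].max())
    sol.mach_max = u_max / SPEED_OF_SOUND_MS
    logger.info(
        "[flow] %s V=%.1f ml/s AP=%.2f%% dp=%.3f Pa Mach_max=%.4f%s",
        phase.label, vdot, sol.airflow_partitioning_pct, sol.dp_pa, sol.mach_max,
        "" if sol.mach_max < 0.01 else " (WARNING: Mach >= 0.01)",
    )
    if with_wall_fields:
        sol.wall_pressure_pa, sol.wall_shear_stress_pa = wall_fields(g, sol, fluid)
    return sol


def wall_fields(
    g: DuctGeometry, sol: FlowSolution, fluid: FluidProperties = FluidProperties()
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-vertex wall static pressure (Pa) and wall shear stress (Pa).

    Every vertex of a station ring takes that station's pressure and the
    force-balance shear  τ = |dp/ds|_visc·A/P.  Shared pharynx-tube
    vertices carry the common pharynx pressure and a τ computed from the
    total flow through the pharynx section.
    """
    if not g.has_structure:
        raise ValueError("wall fields require ring/station structure")
    mu = fluid.dynamic_viscosity
    pressure = np.zeros(g.n_vertices)
    tau = np.zeros(g.n_vertices)

    def visc_tau(prof: SideProfile, q_mls: float) -> np.ndarray:
        a = prof.semi_axis_a_mm * MM
        b = prof.semi_axis_b_mm * MM
        grad = 4.0 * mu * (q_mls * MLS) * (a**2 + b**2) / (np.pi * a**3 * b**3)
        return grad * (prof.area_mm2 * MM2) / (prof.perimeter_mm * MM)

    q_of_side = {"left": sol.q_left_mls, "right": sol.q_right_mls}
    for side in ("left", "right"):
        prof = g.profiles[side]
        mask = g.side_of_vertex == SIDE_NAMES[side]
        st = g.station_of_vertex[mask]
        pressure[mask] = sol.station_pressures_pa[side][st]
        tau[mask] = visc_tau(prof, q_of_side[side])[st]

    if "shared" in g.profiles:
        mask = g.side_of_vertex == SIDE_NAMES["shared"]
        if np.any(mask):
            p_phx = 0.5 * (
                sol.station_pressures_pa["left"][-1]
                + sol.station_pressures_pa["right"][-1]
            )
            pressure[mask] = p_phx
            prof = g.profiles["shared"]
            vdot = sol.q_left_mls + sol.q_right_mls
            tau[mask] = visc_tau(prof, vdot)[g.station_of_vertex[mask]]
    return pressure, tau


def simulate_phases(
    g: DuctGeometry,
    fluid: FluidProperties = FluidProperties(),
    total_flow_mls: float = 200.0,
    losses: bool = True,
    contraction_coefficient: float = 0.0,
) -> Tuple[FlowSolution, FlowSolution]:
    """Quasi-steady restful inspiration and expiration at the same flow rate."""
    insp = solve_bilateral_partition(
        g, BreathingPhase(INSPIRATION, total_flow_mls), fluid, losses,
        contraction_coefficient,
    )
    exp = solve_bilateral_partition(
        g, BreathingPhase(EXPIRATION, total_flow_mls), fluid, losses,
        contraction_coefficient,
    )
    return insp, exp
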