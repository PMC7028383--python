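"""Pennes bio-heat solver driven by the Monte Carlo absorption field.

The temperature of perfused brain tissue under laser illumination obeys

    ρc ∂T/∂t = k ∇²T + ρ_b c_b w_b (T_A − T) + Sh(r) + q_m

with conduction, a blood-perfusion sink toward the arterial temperature T_A,
the optical heat source Sh from light transport, and metabolic heat q_m.  The
solver discretises the equation on the axisymmetric (z, r) voxel grid of the
:class:`~mpcalcium.mc_transport.AbsorptionGrid`, solving the steady state as a
sparse linear system and the transient with implicit time stepping.

Boundary conditions: the tissue surface under the cranial window is held at a
configurable sub-body temperature (default 30 °C) representing heat loss
through the window; the surface outside the window (under the skull) is
insulated; the distant lateral and deep bounds are held at T_A.  The window
temperature is the one genuinely free calibration parameter of the model —
absolute maximum temperatures depend on it, power slopes essentially do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mc_transport import AbsorptionGrid

__all__ = [
    "ThermalParams",
    "BoundaryConditions",
    "TemperatureField",
    "PowerSweepResult",
    "solve",
    "max_temperature",
    "power_sweep",
    "scan_fluctuation",
    "water_absorption_correction",
    "WATER_MUA_PER_MM",
    "DEFAULT_WATER_PATH_MM",
]


@dataclass(frozen=True)
class ThermalParams:
    """Thermal properties of perfused gray matter (mW/mm/°C unit system)."""

    rho_g_mm3: float = 1.04e-3      # tissue density, g/mm³
    c_mj_gc: float = 3.65e3         # tissue specific heat, mJ/(g·°C)
    k_mw_mmc: float = 0.527         # conductivity, mW/(mm·°C)
    rho_b_g_mm3: float = 1.06e-3    # blood density, g/mm³
    c_b_mj_gc: float = 3.6e3        # blood specific heat, mJ/(g·°C)
    w_b_per_s: float = 8.5e-3       # perfusion rate, 1/s
    q_m_mw_mm3: float = 9.5e-3      # metabolic heat, mW/mm³
    t_a_c: float = 36.7             # arterial temperature, °C

    def __post_init__(self) -> None:
        for name in (
            "rho_g_mm3", "c_mj_gc", "k_mw_mmc", "rho_b_g_mm3",
            "c_b_mj_gc", "w_b_per_s", "q_m_mw_mm3", "t_a_c",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def perfusion_mw_mm3c(self) -> float:
        """Perfusion sink coefficient ρ_b·c_b·w_b, mW/(mm³·°C)."""
        return self.rho_b_g_mm3 * self.c_b_mj_gc * self.w_b_per_s

    @property
    def equilibrium_temp_c(self) -> float:
        """Perfusion-balance temperature T_A + q_m/(ρ_b c_b w_b) ≈ 37.0 °C."""
        return self.t_a_c + self.q_m_mw_mm3 / self.perfusion_mw_mm3c


@dataclass(frozen=True)
class BoundaryConditions:
    """Boundary setup for the axisymmetric solve."""

    window_temp_c: float = 30.0
    window_radius_mm: float = 2.5
    far_temp_c: float | None = None  # defaults to T_A
    insulated: bool = False          # all-Neumann (for closed-form checks)


@dataclass
class TemperatureField:
    """Temperature map T(z, r) in °C on the solver grid."""

    values: np.ndarray
    r_mm: np.ndarray = field(repr=False)
    z_mm: np.ndarray = field(repr=False)
    time_s: float = math.inf

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite temperatures")


# --- immersion-water absorption -------------------------------------------
# Above 1200 nm tissue absorption is water-dominated and the gray-matter μa is
# 75% of the (spectrum-weighted) water value, so water μa = tissue μa / 0.75.
# At 920 nm tissue absorption is NOT water-dominated; pure-water absorption is
# ~0.0056/mm there (literature value), giving a <2% correction over 2 mm.
WATER_MUA_PER_MM: dict[int, float] = {
    920: 0.0056,
    1280: 0.078 / 0.75,
    1320: 0.12 / 0.75,
}

#: Water column for a 2-mm-working-distance objective focused 1 mm deep; gives
#: after-objective → surface transmission ≈ 0.85 at 1320 nm (80 → 68 mW).
DEFAULT_WATER_PATH_MM = math.log(80.0 / 68.0) / WATER_MUA_PER_MM[1320]


def water_absorption_correction(
    p_after_objective_mw: float,
    water_path_mm: float = DEFAULT_WATER_PATH_MM,
    wavelength_nm: float = 1320.0,
) -> float:
    """Average power at the brain surface after immersion-water absorption."""
    if water_path_mm < 0:
        raise ValueError("water_path_mm must be >= 0")
    mua = WATER_MUA_PER_MM[int(round(wavelength_nm))]
    return p_after_objective_mw * math.exp(-mua * water_path_mm)


def scan_fluctuation(cooling_rate_c_per_s: float, frame_rate_hz: float) -> float:
    """Peak-to-peak temperature ripple due to frame-by-frame revisits.

    Between two visits of the beam a point cools for one frame period, so the
    ripple is cooling_rate / frame_rate.  0.1 °C/s at 2 Hz gives 0.05 °C —
    negligible, which is why scanning can be modelled as continuous
    illumination.
    """
    if cooling_rate_c_per_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("inputs must be positive")
    return cooling_rate_c_per_s / frame_rate_hz


def _assemble(
    source: AbsorptionGrid,
    power_surface_mw: float,
    thermal: ThermalParams,
    bc: BoundaryConditions,
) -> tuple[sp.csc_matrix, np.ndarray, np.ndarray, np.ndarray]:
    """Build the steady-state system A·T = b on the voxel-corner node grid."""
    r = source.r_edges_mm
    z = source.z_edges_mm
    nr, nz = r.size, z.size
    dr = float(r[1] - r[0])
    dz = float(z[1] - z[0])
    k = thermal.k_mw_mmc
    perf = thermal.perfusion_mw_mm3c
    t_far = bc.far_temp_c if bc.far_temp_c is not None else thermal.t_a_c

    # Node source: volume-weighted average of the (up to) four cells that
    # overlap each node's control volume, so a deposit concentrated in one
    # cell keeps its integrated power on the node grid.
    sh_cells = source.values * power_surface_mw
    ncz, ncr = sh_cells.shape
    sh = np.zeros((nz, nr))
    wz = np.zeros((nz, 2))  # weight of (upper cell i-1, lower cell i)
    wz[:, 0] = 0.5
    wz[:, 1] = 0.5
    wz[0] = (0.0, 1.0)
    wz[-1] = (1.0, 0.0)
    for j in range(nr):
        rj = r[j]
        if j == 0:
            w_in, w_out = 0.0, 1.0
        elif j == nr - 1:
            w_in, w_out = 1.0, 0.0
        else:
            v_in = rj**2 - (rj - dr / 2.0) ** 2
            v_out = (rj + dr / 2.0) ** 2 - rj**2
            w_in = v_in / (v_in + v_out)
            w_out = 1.0 - w_in
        j_in = min(max(j - 1, 0), ncr - 1)
        j_out = min(j, ncr - 1)
        col = np.zeros(nz)
        for i in range(nz):
            i_up = min(max(i - 1, 0), ncz - 1)
            i_dn = min(i, ncz - 1)
            col[i] = (
                wz[i, 0] * (w_in * sh_cells[i_up, j_in] + w_out * sh_cells[i_up, j_out])
                + wz[i, 1] * (w_in * sh_cells[i_dn, j_in] + w_out * sh_cells[i_dn, j_out])
            )
        sh[:, j] = col

    n = nz * nr
    idx = np.arange(n).reshape(nz, nr)
    b = -(sh + thermal.q_m_mw_mm3) - perf * thermal.t_a_c
    b = b.ravel().astype(float)

    dirichlet = np.zeros((nz, nr), dtype=bool)
    dval = np.zeros((nz, nr))
    if not bc.insulated:
        top_window = r <= bc.window_radius_mm + 1e-12
        dirichlet[0, top_window] = True
        dval[0, top_window] = bc.window_temp_c
        dirichlet[-1, :] = True
        dval[-1, :] = t_far
        dirichlet[:, -1] = True
        dval[:, -1] = t_far

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i0: int, j0: int, i1: int, j1: int, coeff: float) -> None:
        rows.append(idx[i0, j0])
        cols.append(idx[i1, j1])
        vals.append(coeff)

    inv_dr2 = k / dr**2
    inv_dz2 = k / dz**2
    for i in range(nz):
        for j in range(nr):
            if dirichlet[i, j]:
                continue
            c = -perf
            # radial operator (1/r) d/dr (r dT/dr); symmetry at the axis
            if j == 0:
                if dirichlet[i, 1]:
                    b[idx[i, j]] -= 4.0 * inv_dr2 * dval[i, 1]
                else:
                    add(i, j, i, 1, 4.0 * inv_dr2)
                c -= 4.0 * inv_dr2
            elif j == nr - 1:
                # only reachable in all-insulated mode; mirror boundary
                add(i, j, i, j - 1, 2.0 * inv_dr2)
                c -= 2.0 * inv_dr2
            else:
                wp = inv_dr2 * (1.0 + dr / (2.0 * r[j]))
                wm = inv_dr2 * (1.0 - dr / (2.0 * r[j]))
                if dirichlet[i, j + 1]:
                    b[idx[i, j]] -= wp * dval[i, j + 1]
                else:
                    add(i, j, i, j + 1, wp)
                if dirichlet[i, j - 1]:
                    b[idx[i, j]] -= wm * dval[i, j - 1]
                else:
                    add(i, j, i, j - 1, wm)
                c -= wp + wm
            # axial operator with insulated (mirror) top/bottom where Neumann
            if i == 0:
                if dirichlet[1, j]:
                    b[idx[i, j]] -= 2.0 * inv_dz2 * dval[1, j]
                else:
                    add(i, j, 1, j, 2.0 * inv_dz2)
                c -= 2.0 * inv_dz2
            elif i == nz - 1:
                if dirichlet[nz - 2, j]:
                    b[idx[i, j]] -= 2.0 * inv_dz2 * dval[nz - 2, j]
                else:
                    add(i, j, nz - 2, j, 2.0 * inv_dz2)
                c -= 2.0 * inv_dz2
            else:
                for i2 in (i - 1, i + 1):
                    if dirichlet[i2, j]:
                        b[idx[i, j]] -= inv_dz2 * dval[i2, j]
                    else:
                        add(i, j, i2, j, inv_dz2)
                c -= 2.0 * inv_dz2
            add(i, j, i, j, c)

    di, dj = np.nonzero(dirichlet)
    for i, j in zip(di, dj):
        add(i, j, i, j, 1.0)
        b[idx[i, j]] = dval[i, j]

    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return a, b, r, z


def solve(
    source: AbsorptionGrid,
    power_surface_mw: float,
    thermal: ThermalParams | None = None,
    bc: BoundaryConditions | None = None,
    mode: str = "steady",
    time_s: float = 60.0,
    dt_s: float = 1.0,
) -> TemperatureField:
    """Solve the bio-heat equation on the absorption grid.

    ``power_surface_mw`` scales the normalised absorption field to the actual
    power entering the tissue.  ``mode="steady"`` solves the linear steady
    state directly; ``mode="transient"`` runs implicit Euler (unconditionally
    stable, no CFL restriction) from a uniform body-temperature initial
    condition up to ``time_s``.
    """
    thermal = thermal or ThermalParams()
    bc = bc or BoundaryConditions()
    if power_surface_mw < 0:
        raise ValueError("power must be >= 0")
    a, b, r, z = _assemble(source, power_surface_mw, thermal, bc)
    n = b.size
    if mode == "steady":
        t = splu(a).solve(b)
        if not np.all(np.isfinite(t)):
            raise RuntimeError("steady-state solve did not converge")
        return TemperatureField(t.reshape(z.size, r.size), r_mm=r, z_mm=z)
    if mode == "transient":
        rhoc = thermal.rho_g_mm3 * thermal.c_mj_gc  # mJ/(mm³·°C)
        # Dirichlet rows are identity in `a`; give them zero heat capacity so
        # they stay pinned at the boundary value during stepping.
        cap = np.full(n, rhoc / dt_s)
        rowsum = np.asarray(np.abs(a).sum(axis=1)).ravel()
        cap[np.isclose(a.diagonal(), 1.0) & np.isclose(rowsum, 1.0)] = 0.0
        m = sp.diags(cap, format="csc")
        lu = splu((m - a).tocsc())
        t = np.full(n, thermal.t_a_c)
        nsteps = max(1, int(round(time_s / dt_s)))
        for _ in range(nsteps):
            t = lu.solve(m @ t - b)
        return TemperatureField(t.reshape(z.size, r.size), r_mm=r, z_mm=z, time_s=time_s)
    raise ValueError("mode must be 'steady' or 'transient'")


def max_temperature(
    t: TemperatureField, radius_um: float = 120.0, height_um: float = 210.0
) -> float:
    """Hottest-volume-averaged maximum temperature (°C).

    Averages T over a cylinder of ~120 μm radius × 210 μm height (≈10⁷ μm³)
    centred on the temperature maximum — a metric robust to single-voxel
    peaks.  The cylinder is clipped at the grid top/bottom if necessary.
    """
    vals = t.values
    r_mm = t.r_mm
    z_mm = t.z_mm
    rad = radius_um * 1e-3
    hh = 0.5 * height_um * 1e-3
    if rad > r_mm[-1] or 2 * hh > (z_mm[-1] - z_mm[0]):
        raise ValueError("averaging region exceeds the solver grid")
    # the heat source is axisymmetric around the scan centre, so the hottest
    # volume is the on-axis cylinder; centre it on the axial maximum, shifted
    # inward if the cylinder would stick out of the grid
    iz0 = int(np.argmax(vals[:, 0]))
    zc = float(np.clip(z_mm[iz0], z_mm[0] + hh, z_mm[-1] - hh))
    rmask = r_mm <= rad + 1e-12
    zmask = np.abs(z_mm - zc) <= hh + 1e-12
    dr = float(r_mm[1] - r_mm[0])
    # annular shell weight around each radial node
    r_w = np.where(r_mm > 0, 2.0 * np.pi * r_mm * dr, np.pi * (dr / 2.0) ** 2)
    w = np.outer(zmask.astype(float), rmask * r_w)
    return float((vals * w).sum() / w.sum())


@dataclass
class PowerSweepResult:
    """Tmax vs power table with linearised slope and threshold crossings."""

    powers_mw: np.ndarray
    tmax_c: np.ndarray
    slope_c_per_50mw: float
    p_cross_37c_mw: float | None
    p_cross_41c_mw: float | None


def power_sweep(
    source: AbsorptionGrid,
    powers_mw: list[float],
    wavelength_nm: float = 1320.0,
    thermal: ThermalParams | None = None,
    bc: BoundaryConditions | None = None,
    water_path_mm: float = DEFAULT_WATER_PATH_MM,
    power_reference: str = "after-objective",
) -> PowerSweepResult:
    """Steady-state maximum temperature versus average power.

    Powers are stated after the objective by default and converted to surface
    powers through the immersion-water correction.  The PDE is linear in the
    source, so the sweep needs only two solves (zero and unit power); the
    hottest-volume metric is still evaluated per power because the hot spot
    moves once the optical source dominates the window cooling.
    """
    if not powers_mw:
        raise ValueError("empty power list")
    thermal = thermal or ThermalParams()
    bc = bc or BoundaryConditions()
    base = solve(source, 0.0, thermal, bc)
    unit_p = 100.0
    if power_reference == "after-objective":
        unit_surface = water_absorption_correction(unit_p, water_path_mm, wavelength_nm)
    else:
        unit_surface = unit_p
    hot = solve(source, unit_surface, thermal, bc)
    dT = (hot.values - base.values) / unit_p  # °C per mW of stated power
    powers = np.asarray(sorted(powers_mw), dtype=float)
    tmax = np.array(
        [
            max_temperature(
                TemperatureField(base.values + p * dT, r_mm=base.r_mm, z_mm=base.z_mm)
            )
            for p in powers
        ]
    )
    if powers.size >= 2:
        slope = 50.0 * (tmax[-1] - tmax[0]) / (powers[-1] - powers[0])
    else:
        slope = math.nan

    def crossing(level: float) -> float | None:
        above = tmax >= level
        if above.all():
            return float(powers[0])
        if not above.any():
            if slope and not math.isnan(slope) and slope > 0:
                p = powers[-1] + (level - tmax[-1]) * 50.0 / slope
                return float(p)
            return None
        i = int(np.argmax(above))
        p0, p1 = powers[i - 1], powers[i]
        t0, t1 = tmax[i - 1], tmax[i]
        return float(p0 + (level - t0) * (p1 - p0) / (t1 - t0))

    return PowerSweepResult(
        powers_mw=powers,
        tmax_c=tmax,
        slope_c_per_50mw=float(slope),
        p_cross_37c_mw=crossing(37.0),
        p_cross_41c_mw=crossing(41.0),
    )
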