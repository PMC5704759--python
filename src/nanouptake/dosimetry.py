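"""Nanoparticle dosimetry: mass-to-number conversion and deposited dose.

Converts administered mass concentrations of polydisperse core--shell
nanoparticles into particle numbers, and computes the time course of the
*delivered* dose -- the fraction of suspended particles that has reached
the cell monolayer at the bottom of a culture well by diffusion (and,
optionally, sedimentation).

The particle population is described by normal distributions of the core
radius ``r_c`` and the hydrodynamic radius ``R``.  The mean particle mass
follows from the third raw moments of those distributions,

    E[r^3] = mu^3 + 3*mu*sigma^2        (untruncated normal),

so the number of particles administered at mass concentration ``C`` in
volume ``V`` is ``n = C*V / <m>`` with

    <m> = rho_core * (4pi/3) * E[r_c^3]
        + rho_shell * (4pi/3) * (E[R^3] - E[r_c^3]).

Transport in the medium column is modelled as one-dimensional
advection--diffusion over the column height ``h`` with a perfectly
absorbing bottom (particles adhere on arrival) and a reflecting top; the
cumulative bottom flux, as a fraction of the administered amount, is the
delivered dose.  The diffusion coefficient comes from Stokes--Einstein at
the mean hydrodynamic diameter, the settling velocity from Stokes drag on
the effective core--shell sphere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "SizeDistribution",
    "ParticleSpecies",
    "ExposureSetup",
    "DepositionCurve",
    "third_raw_moment",
    "mean_particle_mass",
    "particle_number",
    "core_mass_to_number",
    "diffusion_coefficient",
    "sedimentation_velocity",
    "deposited_fraction",
]

BOLTZMANN_J_PER_K = 1.380649e-23
GRAVITY_M_PER_S2 = 9.80665
NM3_TO_CM3 = 1e-21

# Relative spread above which the untruncated normal-moment formula starts
# to carry non-negligible weight at negative radii.
_POLYDISPERSITY_WARN_RATIO = 0.5

# Relative growth of the adaptive Crank--Nicolson time step (dt <= growth*t).
_DT_GROWTH = 0.02


class DosimetryError(ValueError):
    """Invalid particle, medium or geometry parameters."""


class GeometryError(DosimetryError):
    """Inconsistent core/shell geometry or non-positive column height."""


@dataclass(frozen=True)
class SizeDistribution:
    """Normal distribution of a particle radius, in nm.

    The moment formula is that of the *untruncated* normal; for large
    ``sd/mean`` the negative-radius tail is no longer negligible and a
    warning is emitted.
    """

    mean: float  # nm
    sd: float = 0.0  # nm

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise DosimetryError(f"radius mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise DosimetryError(f"radius sd must be >= 0, got {self.sd}")
        if self.sd > _POLYDISPERSITY_WARN_RATIO * self.mean:
            warnings.warn(
                f"sd/mean = {self.sd / self.mean:.2f} > {_POLYDISPERSITY_WARN_RATIO}: "
                "untruncated normal moments put weight on negative radii",
                stacklevel=3,
            )

    @classmethod
    def from_diameter(cls, mean_nm: float, sd_nm: float = 0.0) -> "SizeDistribution":
        """Build a radius distribution from diameter statistics (d/2)."""
        return cls(mean=mean_nm / 2.0, sd=sd_nm / 2.0)


@dataclass(frozen=True)
class ParticleSpecies:
    """A polydisperse core--shell nanoparticle preparation.

    Parameters
    ----------
    core_density, shell_density:
        Mass densities in g/cm^3 of the inorganic core and the polymer
        shell. A shell density of 0 describes a bare core.
    core_radius, hydrodynamic_radius:
        Radius distributions in nm; the hydrodynamic radius includes the
        shell/solvation layer and sets the diffusion coefficient.
    mass_concentration:
        Administered concentration in ug/mL.
    channel:
        Fluorescence-channel label associated with this species.
    """

    name: str
    core_density: float  # g/cm^3
    core_radius: SizeDistribution
    hydrodynamic_radius: SizeDistribution
    mass_concentration: float = 0.0  # ug/mL
    shell_density: float = 1.0  # g/cm^3
    channel: str = ""

    def __post_init__(self) -> None:
        if not self.core_density > 0:
            raise DosimetryError("core density must be > 0")
        if self.shell_density < 0:
            raise DosimetryError("shell density must be >= 0")
        if self.mass_concentration < 0:
            raise DosimetryError("mass concentration must be >= 0")
        if self.hydrodynamic_radius.mean < self.core_radius.mean:
            raise GeometryError(
                "hydrodynamic radius mean smaller than core radius mean "
                f"({self.hydrodynamic_radius.mean} < {self.core_radius.mean} nm)"
            )


@dataclass(frozen=True)
class ExposureSetup:
    """Well geometry and medium physics for the transport problem."""

    well_area: float = 1.7  # cm^2
    medium_volume: float = 0.4  # mL
    temperature: float = 310.0  # K
    viscosity: float = 6.9e-4  # Pa s
    medium_density: float = 1.00  # g/cm^3

    def __post_init__(self) -> None:
        for name in ("well_area", "medium_volume", "temperature", "viscosity", "medium_density"):
            if not getattr(self, name) > 0:
                raise DosimetryError(f"{name} must be > 0")

    @property
    def column_height_mm(self) -> float:
        """Medium column height h = V/A in mm."""
        return self.medium_volume / self.well_area * 10.0

    @property
    def column_height_m(self) -> float:
        return self.column_height_mm * 1e-3


@dataclass
class DepositionCurve:
    """Cumulative delivered-dose fraction on a time grid."""

    times: np.ndarray  # s
    deposited_fraction: np.ndarray  # dimensionless, in [0, 1]
    species: str = ""
    column_height_mm: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.deposited_fraction = np.asarray(self.deposited_fraction, dtype=float)

    @property
    def suspended_fraction(self) -> np.ndarray:
        return 1.0 - self.deposited_fraction

    def at(self, t: float) -> float:
        """Deposited fraction at time ``t`` (linear interpolation)."""
        return float(np.interp(t, self.times, self.deposited_fraction))


def third_raw_moment(dist: SizeDistribution) -> float:
    """E[r^3] of a normal radius distribution, in nm^3.

    For N(mu, sigma): E[r^3] = mu^3 + 3*mu*sigma^2 (untruncated).
    """
    mu, sigma = dist.mean, dist.sd
    return mu**3 + 3.0 * mu * sigma**2


def mean_particle_mass(species: ParticleSpecies) -> float:
    """Mean single-particle mass in grams, core plus shell."""
    core_m3 = third_raw_moment(species.core_radius)
    hydro_m3 = third_raw_moment(species.hydrodynamic_radius)
    if hydro_m3 < core_m3:
        raise GeometryError(
            "mean hydrodynamic volume smaller than mean core volume "
            f"(E[R^3]={hydro_m3:.4g} < E[r_c^3]={core_m3:.4g} nm^3)"
        )
    vol = 4.0 * math.pi / 3.0
    core_mass = species.core_density * vol * core_m3 * NM3_TO_CM3
    shell_mass = species.shell_density * vol * (hydro_m3 - core_m3) * NM3_TO_CM3
    return core_mass + shell_mass


def particle_number(species: ParticleSpecies, setup: ExposureSetup) -> float:
    """Number of particles administered: n = C*V / <m> (not rounded)."""
    m = mean_particle_mass(species)
    if m == 0:
        raise ZeroDivisionError("mean particle mass is zero")
    total_mass_g = species.mass_concentration * 1e-6 * setup.medium_volume
    return total_mass_g / m


def core_mass_to_number(elemental_mass: float, species: ParticleSpecies) -> float:
    """Particle count from an elemental (core-only) mass in grams.

    Element-specific assays see only the inorganic core, so the conversion
    divides by the mean *core* mass alone.
    """
    if elemental_mass < 0:
        raise DosimetryError(f"elemental mass must be >= 0, got {elemental_mass}")
    core_mass = (
        species.core_density
        * (4.0 * math.pi / 3.0)
        * third_raw_moment(species.core_radius)
        * NM3_TO_CM3
    )
    return elemental_mass / core_mass


def diffusion_coefficient(species: ParticleSpecies, setup: ExposureSetup) -> float:
    """Stokes--Einstein diffusion coefficient (m^2/s) at the mean d_h."""
    d_h = 2.0 * species.hydrodynamic_radius.mean * 1e-9  # m
    return BOLTZMANN_J_PER_K * setup.temperature / (3.0 * math.pi * setup.viscosity * d_h)


def effective_density(species: ParticleSpecies) -> float:
    """Volume-averaged density of the core--shell sphere, g/cm^3."""
    core_m3 = third_raw_moment(species.core_radius)
    hydro_m3 = third_raw_moment(species.hydrodynamic_radius)
    return (species.core_density * core_m3 + species.shell_density * (hydro_m3 - core_m3)) / hydro_m3


def sedimentation_velocity(species: ParticleSpecies, setup: ExposureSetup) -> float:
    """Stokes settling velocity (m/s) of the effective core--shell sphere.

    Negative for buoyant particles (effective density below the medium's).
    """
    d_h = 2.0 * species.hydrodynamic_radius.mean * 1e-9  # m
    delta_rho = (effective_density(species) - setup.medium_density) * 1e3  # kg/m^3
    return GRAVITY_M_PER_S2 * d_h**2 * delta_rho / (18.0 * setup.viscosity)


def _size_quadrature(dist: SizeDistribution, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss--Hermite nodes/weights of the normal radius distribution."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_bins)
    radii = dist.mean + dist.sd * nodes
    w = weights / weights.sum()
    keep = radii > 0
    return radii[keep], w[keep] / w[keep].sum()


def _solve_deposition(
    D: float,
    v: float,
    h: float,
    times: np.ndarray,
    n_nodes: int,
    cfl: float,
) -> np.ndarray:
    """Crank--Nicolson finite-volume solve of one transport class.

    dc/dt = D d2c/dx2 + v dc/dx on x in [0, h] (x=0 is the cell layer),
    c(x,0)=1, absorbing wall at x=0, zero flux at x=h; v >= 0 is the
    downward settling speed, discretised upwind.  Returns the cumulative
    deposited fraction at each requested time, obtained by trapezoidal
    integration of the wall flux (which, in this flux-form scheme, equals
    the loss of suspended mass to machine precision).
    """
    dx = h / n_nodes
    dt_diff = cfl * dx * dx / D if D > 0 else np.inf
    dt_adv = cfl * dx / v if v > 0 else np.inf
    dt0 = min(dt_diff, dt_adv)
    if not np.isfinite(dt0):
        raise DosimetryError("both D and v are zero: no transport")
    t_end = float(times[-1])

    # Downward flux at interior face i (between cells i-1 below and i above):
    #   J_i = D*(c_i - c_{i-1})/dx + v*c_i          (upwind from above)
    # wall face: J_0 = (2D/dx + v)*c_0, top face: J_N = 0.
    # dc_i/dt = (J_{i+1} - J_i)/dx  => tridiagonal operator A.
    lower = np.full(n_nodes, D / dx**2)  # coefficient of c_{i-1}
    upper = np.full(n_nodes, D / dx**2 + v / dx)  # coefficient of c_{i+1}
    main = np.full(n_nodes, -2.0 * D / dx**2 - v / dx)
    # cell 0: dc0/dt = (J_1 - J_0)/dx with wall flux J_0 = (2D/dx + v) c_0;
    # J_1 contributes -D/dx^2 to the c_0 coefficient (its advective part
    # rides on c_1, which sits in `upper`).
    main[0] = -D / dx**2 - (2.0 * D / dx**2 + v / dx)
    # cell N-1: J_N = 0 => dc/dt = -J_{N-1}/dx
    main[-1] = -(D / dx**2 + v / dx)
    upper[-1] = 0.0

    def lhs_banded(half: float) -> np.ndarray:
        ab = np.zeros((3, n_nodes))
        ab[0, 1:] = -half * upper[:-1]
        ab[1, :] = 1.0 - half * main
        ab[2, :-1] = -half * lower[1:]
        return ab

    c = np.ones(n_nodes)
    wall_coeff = 2.0 * D / dx + v  # J_0 = wall_coeff * c_0

    out = np.zeros(len(times))
    deposited = 0.0  # integral of wall flux, units of c0*length
    t = 0.0
    ti = 0
    total = h  # initial mass per unit area at c0 = 1
    while ti < len(times) and times[ti] <= 0.0:
        out[ti] = 0.0
        ti += 1

    # Adaptive step: start at the CFL-like cap, then grow with elapsed
    # time (dt <= _DT_GROWTH * t).  Crank--Nicolson is A-stable, so the
    # cap is an accuracy device for the steep early transient only; the
    # advective cap stays hard to keep the upwind front sharp.
    rhs = np.empty(n_nodes)
    dt = -1.0
    ab_lhs = None
    while t < t_end - 1e-9 * dt0:
        dt_new = min(max(dt_diff, _DT_GROWTH * t), dt_adv, t_end - t)
        if ab_lhs is None or abs(dt_new - dt) > 1e-12 * dt_new:
            dt = dt_new
            half = dt / 2.0
            ab_lhs = lhs_banded(half)
        # rhs = (I + dt/2 A) c
        rhs[:] = (1.0 + half * main) * c
        rhs[:-1] += half * upper[:-1] * c[1:]
        rhs[1:] += half * lower[1:] * c[:-1]
        c_new = solve_banded((1, 1), ab_lhs, rhs)
        flux_avg = wall_coeff * 0.5 * (c[0] + c_new[0])
        dep_prev = deposited
        deposited += flux_avg * dt
        t_prev, t = t, t + dt
        c = c_new
        while ti < len(times) and times[ti] <= t + 1e-9 * dt:
            # linear interpolation of the cumulative deposit inside the step
            w = (times[ti] - t_prev) / dt
            out[ti] = (dep_prev + w * (deposited - dep_prev)) / total
            ti += 1
    while ti < len(times):  # guard against roundoff at t_end
        out[ti] = deposited / total
        ti += 1
    return np.clip(out, 0.0, 1.0)


def deposited_fraction(
    species: ParticleSpecies,
    setup: ExposureSetup,
    times,
    *,
    include_sedimentation: bool = False,
    n_nodes: int = 400,
    cfl: float = 0.5,
    n_size_bins: int = 1,
) -> DepositionCurve:
    """Fraction of the administered dose delivered to the cell layer.

    Parameters
    ----------
    times:
        Sorted, non-negative times in seconds.
    include_sedimentation:
        Add the Stokes settling velocity to the transport (default off:
        for sub-50 nm particles in aqueous media sedimentation is
        negligible compared to diffusion).
    n_nodes:
        Spatial grid resolution of the Crank--Nicolson solver.
    n_size_bins:
        1 (default) evaluates transport at the mean hydrodynamic diameter;
        >1 averages deposition over a Gauss--Hermite quadrature of the
        hydrodynamic-size distribution.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise DosimetryError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise DosimetryError("times must be sorted and non-negative")
    h = setup.column_height_m
    if not h > 0:
        raise GeometryError("column height must be > 0")

    v = sedimentation_velocity(species, setup) if include_sedimentation else 0.0
    v = max(v, 0.0)  # buoyant particles never reach the bottom by settling

    if n_size_bins <= 1:
        D = diffusion_coefficient(species, setup)
        frac = _solve_deposition(D, v, h, times, n_nodes, cfl)
    else:
        radii, weights = _size_quadrature(species.hydrodynamic_radius, n_size_bins)
        frac = np.zeros(len(times))
        for r, w in zip(radii, weights):
            d_h = 2.0 * r * 1e-9
            D = BOLTZMANN_J_PER_K * setup.temperature / (3.0 * math.pi * setup.viscosity * d_h)
            v_r = v * (r / species.hydrodynamic_radius.mean) ** 2
            frac += w * _solve_deposition(D, v_r, h, times, n_nodes, cfl)

    return DepositionCurve(
        times=times,
        deposited_fraction=frac,
        species=species.name,
        column_height_mm=setup.column_height_mm,
    )


def deposition_series_fraction(D: float, h: float, t, n_terms: int = 200) -> np.ndarray:
    """Eigenfunction-series deposited fraction for pure diffusion.

    Closed-form solution of the absorbing-bottom / reflecting-top slab
    with uniform initial concentration; used as an independent oracle for
    the finite-difference solver (v = 0 only).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = np.arange(n_terms)[:, None]
    lam = (2 * n + 1) * np.pi / (2.0 * h)
    series = np.sum(8.0 / ((2 * n + 1) ** 2 * np.pi**2) * np.exp(-D * lam**2 * t[None, :]), axis=0)
    return 1.0 - series
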