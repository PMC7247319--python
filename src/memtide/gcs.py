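"""Gouy-Chapman-Stern double-layer electrostatics.

Surface charge <-> surface potential via the mixed-valence Grahame
relation, charge regulation by Stern-adsorbing cations, Debye screening,
analytic and numeric potential-decay profiles, ion distributions, and
zeta-potential conversions (Helmholtz-Smoluchowski; shear-plane decay).

Sign conventions: potentials in volts, surface charge in C/m^2,
anionic membranes have sigma < 0 and psi_0 < 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .constants import (
    ANGSTROM2_TO_M2,
    DEFAULT_EPS_R,
    DEFAULT_SHEAR_PLANE,
    DEFAULT_TEMPERATURE,
    DEFAULT_VISCOSITY,
    ELEMENTARY_CHARGE,
    FARADAY,
    GAS_CONSTANT,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "Ion",
    "ElectrolyteComposition",
    "ElectrostaticState",
    "SurfaceIonProfile",
    "debye_constant",
    "grahame_sigma",
    "solve_surface_potential",
    "peptide_modified_sigma",
    "zeta_from_mobility",
    "surface_potential_from_zeta",
    "potential_profile",
    "divalent_accumulation_ratio",
]

logger = logging.getLogger(__name__)

# Default intrinsic Stern association constants, 1/M
DEFAULT_STERN_MONOVALENT = 0.6
DEFAULT_STERN_CALCIUM = 12.0


@dataclass(frozen=True)
class Ion:
    """A dissolved ionic species.

    ``stern_k`` is the intrinsic 1:1 surface association constant in 1/M;
    zero means the ion does not adsorb to the Stern layer.
    """

    name: str
    valence: int
    conc: float  # bulk concentration, M
    stern_k: float = 0.0

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"ion concentration must be >= 0, got {self.conc}")
        if self.stern_k < 0:
            raise ValueError("stern_k must be >= 0")


@dataclass(frozen=True)
class ElectrolyteComposition:
    """An electroneutral set of ions in bulk solution."""

    ions: tuple[Ion, ...]

    def __post_init__(self) -> None:
        net = sum(i.valence * i.conc for i in self.ions)
        if abs(net) > 1e-12:
            raise ValueError(
                f"bulk electroneutrality violated: sum(z*C) = {net:.3e} M"
            )

    @classmethod
    def symmetric(cls, conc: float, valence: int = 1,
                  stern_k_cation: float = 0.0) -> "ElectrolyteComposition":
        """A Z:Z salt at the given concentration."""
        return cls((
            Ion("cation", valence, conc, stern_k_cation),
            Ion("anion", -valence, conc, 0.0),
        ))

    def with_ion(self, name: str, conc: float,
                 counter: str | None = None) -> "ElectrolyteComposition":
        """Return a copy with one ion's concentration changed, rebalancing
        electroneutrality by adjusting ``counter`` (default: the last ion
        of opposite charge sign)."""
        ions = list(self.ions)
        idx = next(i for i, ion in enumerate(ions) if ion.name == name)
        old = ions[idx]
        ions[idx] = replace(old, conc=conc)
        delta = old.valence * (conc - old.conc)
        if counter is None:
            sign = -1 if old.valence > 0 else 1
            cidx = max(
                i for i, ion in enumerate(ions)
                if (ion.valence > 0) == (sign > 0)
            )
        else:
            cidx = next(
                i for i, ion in enumerate(ions) if ion.name == counter
            )
        c_ion = ions[cidx]
        new_conc = c_ion.conc - delta / c_ion.valence
        if new_conc < 0:
            raise ValueError(
                f"cannot rebalance electroneutrality: {c_ion.name} would go "
                f"negative ({new_conc:.3e} M)"
            )
        ions[cidx] = replace(c_ion, conc=new_conc)
        return ElectrolyteComposition(tuple(ions))

    def ionic_strength(self) -> float:
        """I = 1/2 sum(z^2 C), M."""
        return 0.5 * sum(i.valence**2 * i.conc for i in self.ions)


@dataclass(frozen=True)
class ElectrostaticState:
    """A solved membrane surface electrostatic state."""

    sigma: float                 # prevailing surface charge, C/m^2
    sigma_max: float             # intrinsic (fully ionized) charge, C/m^2
    psi_0: float                 # surface potential, V
    kappa: float                 # Debye constant, 1/m
    electrolyte: ElectrolyteComposition
    temperature: float = DEFAULT_TEMPERATURE
    eps_r: float = DEFAULT_EPS_R
    shear_plane_x: float = DEFAULT_SHEAR_PLANE
    zeta: float | None = None
    viscosity: float = DEFAULT_VISCOSITY
    mobility: float | None = None


@dataclass(frozen=True)
class SurfaceIonProfile:
    """Potential decay and ion concentration profiles vs distance."""

    x_grid: np.ndarray              # m
    psi_x: np.ndarray               # V
    concentrations: dict[str, np.ndarray]  # M, keyed by ion name


def _thermal_voltage(temperature: float) -> float:
    return GAS_CONSTANT * temperature / FARADAY


def debye_constant(
    electrolyte: ElectrolyteComposition,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_r: float = DEFAULT_EPS_R,
) -> float:
    """Debye constant kappa (1/m) from the general ionic-strength form.

    kappa^2 = F^2 sum(z_i^2 C_i) / (eps_r eps_0 R T), concentrations in
    mol/m^3.  Reduces to the symmetric Z:Z form 2 Z^2 F^2 C / (eps RT).
    """
    s = sum(i.valence**2 * i.conc for i in electrolyte.ions) * 1e3  # mol/m^3
    if s <= 0:
        raise ValueError("zero ionic strength")
    kappa_sq = FARADAY**2 * s / (
        eps_r * VACUUM_PERMITTIVITY * GAS_CONSTANT * temperature
    )
    return math.sqrt(kappa_sq)


def grahame_sigma(
    psi_0: float,
    electrolyte: ElectrolyteComposition,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_r: float = DEFAULT_EPS_R,
) -> float:
    """Surface charge density balancing the diffuse layer at psi_0 (C/m^2).

    General mixed-valence form:
    sigma = sign(psi_0) sqrt(2 eps RT sum_i C_i [exp(-z_i F psi_0/RT) - 1]).
    """
    if not math.isfinite(psi_0):
        raise ValueError("psi_0 must be finite")
    if psi_0 == 0.0:
        return 0.0
    vt = _thermal_voltage(temperature)
    s = sum(
        i.conc * 1e3 * math.expm1(-i.valence * psi_0 / vt)
        for i in electrolyte.ions
    )
    radicand = (
        2.0 * eps_r * VACUUM_PERMITTIVITY * GAS_CONSTANT * temperature * s
    )
    assert radicand >= -1e-30, "negative Grahame radicand (non-electroneutral?)"
    return math.copysign(math.sqrt(max(radicand, 0.0)), psi_0)


def _regulated_sigma(
    psi: float,
    sigma_max: float,
    electrolyte: ElectrolyteComposition,
    vt: float,
) -> float:
    """Stern charge regulation: sigma_max screened by adsorbed counterions."""
    denom = 1.0
    for ion in electrolyte.ions:
        if ion.stern_k > 0.0:
            c_surface = ion.conc * math.exp(-ion.valence * psi / vt)
            denom += ion.stern_k * c_surface
    return sigma_max / denom


def solve_surface_potential(
    sigma_max: float,
    electrolyte: ElectrolyteComposition,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_r: float = DEFAULT_EPS_R,
    bracket: tuple[float, float] = (-0.5, 0.5),
    xtol: float = 1e-9,
) -> ElectrostaticState:
    """Solve the charge-regulation fixed point for the surface potential.

    Finds psi_0 such that the diffuse-layer (Grahame) charge equals the
    Stern-regulated surface charge
    ``sigma_max / (1 + sum_ads K_i C_i(0))`` with surface concentrations
    Boltzmann-weighted at psi_0.  Bracketed root-finding on psi_0.
    """
    kappa = debye_constant(electrolyte, temperature, eps_r)
    vt = _thermal_voltage(temperature)

    if sigma_max == 0.0:
        return ElectrostaticState(
            sigma=0.0, sigma_max=0.0, psi_0=0.0, kappa=kappa,
            electrolyte=electrolyte, temperature=temperature, eps_r=eps_r,
        )

    def residual(psi: float) -> float:
        return grahame_sigma(psi, electrolyte, temperature, eps_r) - \
            _regulated_sigma(psi, sigma_max, electrolyte, vt)

    lo, hi = (bracket[0], 0.0) if sigma_max < 0 else (0.0, bracket[1])
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"no sign change in bracket [{lo}, {hi}] V: residual({lo}) = "
            f"{f_lo:.3e}, residual({hi}) = {f_hi:.3e}; sigma_max = "
            f"{sigma_max:.3e} C/m^2"
        )
    psi_0 = brentq(residual, lo, hi, xtol=xtol)
    sigma = _regulated_sigma(psi_0, sigma_max, electrolyte, vt)
    return ElectrostaticState(
        sigma=sigma, sigma_max=sigma_max, psi_0=psi_0, kappa=kappa,
        electrolyte=electrolyte, temperature=temperature, eps_r=eps_r,
    )


def peptide_modified_sigma(
    sigma_lipid: float,
    peptide_occupancy: float,
    n: float,
    mean_area: float,
    peptide_valence: int = 3,
    floor_psi: float | None = -0.030,
    electrolyte: ElectrolyteComposition | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_r: float = DEFAULT_EPS_R,
) -> tuple[float, bool]:
    """Effective surface charge after partial neutralization by bound peptide.

    sigma_eff = sigma_lipid + occupancy * (valence * e) / (n * mean_area).

    If ``floor_psi`` is set and an electrolyte is given, sigma_eff is not
    allowed past the charge corresponding to that surface potential
    (default -30 mV) — bound peptide attenuates but does not reverse the
    surface potential.  Pass ``floor_psi=None`` to disable.

    Parameters
    ----------
    mean_area : float
        Mean lipid area, Angstrom^2.

    Returns
    -------
    (sigma_eff, floor_engaged) : (float, bool)
    """
    if not 0.0 <= peptide_occupancy <= 1.0:
        raise ValueError("peptide_occupancy must lie in [0, 1]")
    if n <= 0 or mean_area <= 0:
        raise ValueError("n and mean_area must be positive")
    delta = peptide_occupancy * peptide_valence * ELEMENTARY_CHARGE / (
        n * mean_area * ANGSTROM2_TO_M2
    )
    sigma_eff = sigma_lipid + delta
    floor_engaged = False
    if floor_psi is not None and electrolyte is not None:
        sigma_floor = grahame_sigma(floor_psi, electrolyte, temperature, eps_r)
        # for anionic membranes the floor caps how close to zero sigma gets
        if sigma_lipid < 0 and sigma_eff > sigma_floor:
            sigma_eff = sigma_floor
            floor_engaged = True
            logger.info(
                "surface-potential floor engaged: sigma clamped to "
                "%.4e C/m^2 (psi = %.1f mV)", sigma_floor, floor_psi * 1e3,
            )
    return sigma_eff, floor_engaged


def zeta_from_mobility(
    mu: float,
    eta: float = DEFAULT_VISCOSITY,
    eps_r: float = DEFAULT_EPS_R,
) -> float:
    """Helmholtz-Smoluchowski: zeta = mu * eta / (eps_r eps_0), volts."""
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    return mu * eta / (eps_r * VACUUM_PERMITTIVITY)


def _decay_residual(psi_0: float, zeta: float, kappa: float, x: float,
                    z: int, vt: float) -> float:
    """Forward residual of the shear-plane decay relation.

    kappa*x - ln[ ((e^{a_z}+1)(e^{a_0}-1)) / ((e^{a_z}-1)(e^{a_0}+1)) ]
    with a = Z F psi / (2 R T).
    """
    a_z = z * zeta / (2.0 * vt)
    a_0 = z * psi_0 / (2.0 * vt)
    num = (math.exp(a_z) + 1.0) * (math.exp(a_0) - 1.0)
    den = (math.exp(a_z) - 1.0) * (math.exp(a_0) + 1.0)
    return kappa * x - math.log(num / den)


def surface_potential_from_zeta(
    zeta: float,
    kappa: float,
    x: float = DEFAULT_SHEAR_PLANE,
    z: int = 1,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Back-extrapolate the shear-plane potential to the surface (volts).

    Inverts the symmetric-electrolyte Gouy decay: tanh(ZF psi(x)/4RT)
    = tanh(ZF psi_0/4RT) e^{-kappa x}, evaluated at the shear plane
    (default x = 2 Angstrom).  |psi_0| >= |zeta| always.
    """
    if abs(zeta) >= 0.300:
        raise ValueError(f"|zeta| = {abs(zeta):.3f} V exceeds sanity bound")
    if zeta == 0.0:
        return 0.0
    vt = _thermal_voltage(temperature)
    t = math.tanh(z * zeta / (4.0 * vt)) * math.exp(kappa * x)
    if abs(t) >= 1.0:
        raise ValueError(
            f"decay relation has no solution: tanh(ZFzeta/4RT)*e^(kx) = "
            f"{t:.4f} outside (-1, 1); zeta too large for this kappa*x"
        )
    return 4.0 * vt / z * math.atanh(t)


def potential_profile(
    state: ElectrostaticState,
    x_max: float,
    points: int = 200,
) -> SurfaceIonProfile:
    """Potential decay psi(x) and ion distributions C_i(x) from the surface.

    Symmetric electrolytes use the analytic Gouy solution; mixed-valence
    systems integrate the Poisson-Boltzmann first integral
    dpsi/dx = -sign(psi_0) sqrt((2RT/eps) sum_i C_i [e^{-z_i F psi/RT}-1]).
    """
    x = np.linspace(0.0, x_max, points)
    elec = state.electrolyte
    vt = _thermal_voltage(state.temperature)
    psi_0 = state.psi_0

    valences = {abs(i.valence) for i in elec.ions}
    if psi_0 == 0.0:
        psi = np.zeros_like(x)
    elif len(valences) == 1:
        z = valences.pop()
        gamma = math.tanh(z * psi_0 / (4.0 * vt))
        g = gamma * np.exp(-state.kappa * x)
        psi = (2.0 * vt / z) * np.log((1.0 + g) / (1.0 - g))
    else:
        eps = state.eps_r * VACUUM_PERMITTIVITY
        sign = math.copysign(1.0, psi_0)

        def rhs(_x, y):
            psi_val = y[0]
            s = sum(
                i.conc * 1e3 * math.expm1(-i.valence * psi_val / vt)
                for i in elec.ions
            )
            s = max(s, 0.0)
            return [-sign * math.sqrt(
                2.0 * GAS_CONSTANT * state.temperature / eps * s
            )]

        sol = solve_ivp(
            rhs, (0.0, x_max), [psi_0], t_eval=x,
            rtol=1e-10, atol=1e-12, method="RK45", max_step=x_max / 50,
        )
        if not sol.success:
            raise RuntimeError(f"profile integration failed: {sol.message}")
        psi = sol.y[0]

    concentrations = {
        i.name: i.conc * np.exp(-i.valence * psi / vt) for i in elec.ions
    }
    return SurfaceIonProfile(x_grid=x, psi_x=psi, concentrations=concentrations)


def divalent_accumulation_ratio(
    state_bare: ElectrostaticState,
    state_bound: ElectrostaticState,
) -> float:
    """Ratio of surface divalent-cation Boltzmann enhancement, bare/bound.

    exp(-2 F psi_bare / RT) / exp(-2 F psi_bound / RT).
    """
    vt_bare = _thermal_voltage(state_bare.temperature)
    vt_bound = _thermal_voltage(state_bound.temperature)
    return math.exp(-2.0 * state_bare.psi_0 / vt_bare) / math.exp(
        -2.0 * state_bound.psi_0 / vt_bound
    )
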