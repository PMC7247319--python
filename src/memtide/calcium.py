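"""Coupled equilibrium of Ca2+ among bulk, a fluorescent indicator, and
the membrane interfacial region.

The indicator binds Ca2+ 1:1; the membrane sequesters Ca2+ both in the
diffuse double layer (Boltzmann excess) and the Stern layer, with the
electrostatic state recomputed self-consistently as bound peptide
attenuates the surface charge.  Free bulk Ca2+ is the root of the total
mass balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import (
    ANGSTROM2_TO_M2,
    AVOGADRO,
    FARADAY,
    GAS_CONSTANT,
    VACUUM_PERMITTIVITY,
)
from .gcs import (
    ElectrolyteComposition,
    ElectrostaticState,
    peptide_modified_sigma,
    solve_surface_potential,
)
from .membranes import (
    MembraneSpec,
    intrinsic_surface_charge_density,
    mean_lipid_area,
)

__all__ = [
    "CalciumAssayState",
    "surface_calcium_excess",
    "solve_assay",
    "peptide_displacement_curve",
]

# Default indicator dissociation constant (low-affinity Ca2+ probe), M.
DEFAULT_PROBE_KD = 14e-6
CA_ION_NAME = "Ca"


@dataclass(frozen=True)
class CalciumAssayState:
    """Configuration and (after solving) outputs of the indicator assay.

    The electrolyte must contain an ion named ``"Ca"`` (valence +2); its
    bulk concentration is replaced by the solved free value, with the
    anion rebalanced for electroneutrality.
    """

    probe_total: float                 # M
    ca_total: float                    # M
    electrolyte: ElectrolyteComposition
    probe_kd: float = DEFAULT_PROBE_KD
    membrane: MembraneSpec | None = None
    l_eff: float = 0.0                 # M, outer-leaflet lipid
    peptide_occupancy: float = 0.0
    peptide_n: float = 6.9             # lipids per bound peptide
    peptide_valence: int = 3
    floor_psi: float | None = -0.030   # V; None disables the floor
    include_diffuse: bool = True
    include_stern: bool = True
    # outputs (populated by solve_assay)
    ca_free: float | None = None
    ca_probe_bound: float | None = None
    ca_surface: float | None = None
    predicted_signal: float | None = None
    psi_0: float | None = None
    floor_engaged: bool = False

    def __post_init__(self) -> None:
        if self.probe_total < 0 or self.ca_total < 0 or self.l_eff < 0:
            raise ValueError("concentrations must be nonnegative")
        if not 0.0 <= self.peptide_occupancy <= 1.0:
            raise ValueError("peptide_occupancy must lie in [0, 1]")
        if self.l_eff > 0 and self.membrane is None:
            raise ValueError("membrane spec required when l_eff > 0")
        names = {i.name for i in self.electrolyte.ions}
        if CA_ION_NAME not in names:
            raise ValueError(
                f"electrolyte must contain an ion named {CA_ION_NAME!r}"
            )


def surface_calcium_excess(
    state: ElectrostaticState,
    l_eff: float,
    mean_area: float,
    include_diffuse: bool = True,
    include_stern: bool = True,
) -> float:
    """Solution-equivalent molarity of Ca2+ held at the membrane surface.

    Diffuse part: integral of (C_Ca(x) - C_Ca,bulk) over the double layer,
    computed by quadrature in the potential variable using the
    Poisson-Boltzmann first integral.  Stern part: Langmuir-competitive
    occupancy of surface charge sites.  Both per unit area, scaled by the
    accessible membrane area ``l_eff * N_A * mean_area`` per litre.

    Parameters
    ----------
    mean_area : float
        Mean lipid cross-sectional area, Angstrom^2.
    """
    ca_ion = next(
        i for i in state.electrolyte.ions if i.name == CA_ION_NAME
    )
    if l_eff == 0.0 or ca_ion.conc == 0.0:
        return 0.0
    vt = GAS_CONSTANT * state.temperature / FARADAY
    eps = state.eps_r * VACUUM_PERMITTIVITY
    psi_0 = state.psi_0

    gamma = 0.0  # mol / m^2
    if include_diffuse and psi_0 != 0.0:
        ions = state.electrolyte.ions

        def dpsi_dx_mag(psi):
            s = sum(
                i.conc * 1e3 * math.expm1(-i.valence * psi / vt)
                for i in ions
            )
            return math.sqrt(
                2.0 * GAS_CONSTANT * state.temperature / eps * max(s, 0.0)
            )

        def integrand(psi):
            excess = ca_ion.conc * 1e3 * math.expm1(
                -ca_ion.valence * psi / vt
            )
            return excess / dpsi_dx_mag(psi)

        lo, hi = (psi_0, 0.0) if psi_0 < 0 else (0.0, psi_0)
        val, _ = quad(integrand, lo, hi, limit=200)
        gamma += abs(val)

    if include_stern and state.sigma_max != 0.0:
        denom = 1.0
        theta_num = 0.0
        for ion in state.electrolyte.ions:
            if ion.stern_k > 0.0:
                c0 = ion.conc * math.exp(-ion.valence * psi_0 / vt)
                term = ion.stern_k * c0
                denom += term
                if ion.name == CA_ION_NAME:
                    theta_num = term
        theta_ca = theta_num / denom
        sites_per_area = abs(state.sigma_max) / FARADAY  # mol charges / m^2
        gamma += theta_ca * sites_per_area

    area_per_litre = l_eff * AVOGADRO * mean_area * ANGSTROM2_TO_M2  # m^2/L
    return gamma * area_per_litre


def _solve_membrane_state(
    assay: CalciumAssayState, electrolyte: ElectrolyteComposition
):
    sigma_max = intrinsic_surface_charge_density(assay.membrane)
    area = mean_lipid_area(assay.membrane)
    sigma_eff, floor_engaged = peptide_modified_sigma(
        sigma_max,
        assay.peptide_occupancy,
        assay.peptide_n,
        area,
        assay.peptide_valence,
        floor_psi=assay.floor_psi,
        electrolyte=electrolyte,
    )
    state = solve_surface_potential(sigma_eff, electrolyte)
    # Stern sites scale with the peptide-free lattice charge
    state = replace(state, sigma_max=sigma_eff)
    return state, area, floor_engaged


def solve_assay(assay: CalciumAssayState) -> CalciumAssayState:
    """Solve the three-way Ca2+ mass balance; returns a populated copy.

    Root-finds free bulk Ca2+ such that free + probe-bound + surface
    excess equals total, with the surface electrostatics recomputed at
    each trial free concentration.
    """
    if assay.ca_total == 0.0:
        return replace(
            assay, ca_free=0.0, ca_probe_bound=0.0, ca_surface=0.0,
            predicted_signal=0.0, psi_0=None,
        )

    def components(ca_free: float):
        probe_bound = (
            assay.probe_total * ca_free / (assay.probe_kd + ca_free)
        )
        if assay.membrane is not None and assay.l_eff > 0:
            elec = assay.electrolyte.with_ion(CA_ION_NAME, ca_free)
            state, area, floor_engaged = _solve_membrane_state(assay, elec)
            surface = surface_calcium_excess(
                state, assay.l_eff, area,
                assay.include_diffuse, assay.include_stern,
            )
            psi_0 = state.psi_0
        else:
            surface, psi_0, floor_engaged = 0.0, None, False
        return probe_bound, surface, psi_0, floor_engaged

    def balance(ca_free: float) -> float:
        probe_bound, surface, _, _ = components(ca_free)
        return ca_free + probe_bound + surface - assay.ca_total

    lo, hi = 0.0, assay.ca_total
    f_hi = balance(hi)
    if f_hi < 0:
        raise RuntimeError(
            f"mass balance not bracketed: residual at free = total is "
            f"{f_hi:.3e} M (surface excess negative?)"
        )
    ca_free = brentq(balance, lo, hi, xtol=1e-18, rtol=8.9e-16)
    probe_bound, surface, psi_0, floor_engaged = components(ca_free)
    # close the balance exactly against quadrature round-off
    surface_closed = assay.ca_total - ca_free - probe_bound
    signal = probe_bound / assay.probe_total if assay.probe_total > 0 else 0.0
    return replace(
        assay,
        ca_free=float(ca_free),
        ca_probe_bound=float(probe_bound),
        ca_surface=float(max(surface_closed, 0.0)),
        predicted_signal=float(signal),
        psi_0=psi_0,
        floor_engaged=floor_engaged,
    )


def peptide_displacement_curve(
    base: CalciumAssayState, occupancies
) -> tuple[np.ndarray, np.ndarray, float]:
    """Indicator response vs peptide occupancy of the membrane.

    Returns (occupancy, predicted signal, occupancy at 95% of the
    asymptotic signal rise).  Signal is monotone nondecreasing: bound
    peptide releases surface Ca2+ into the bulk.
    """
    occupancies = np.asarray(occupancies, dtype=float)
    signals = np.empty(occupancies.size)
    for i, occ in enumerate(occupancies):
        solved = solve_assay(replace(base, peptide_occupancy=float(occ)))
        signals[i] = solved.predicted_signal
    s0, s_inf = signals[0], signals[-1]
    if s_inf > s0:
        target = s0 + 0.95 * (s_inf - s0)
        idx = int(np.searchsorted(signals, target))
        occ95 = float(occupancies[min(idx, occupancies.size - 1)])
    else:
        occ95 = float(occupancies[0])
    return occupancies, signals, occ95
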