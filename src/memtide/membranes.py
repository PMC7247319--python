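"""Lipid species, bilayer compositions, and derived geometric/charge quantities.

A membrane is an ideal mixture of lipid species, each carrying a formal
charge (0, -1 or -2 elementary charges) and an approximate cross-sectional
area.  Everything downstream (binding-site areas, intrinsic surface charge
densities for the electrostatic solver) derives from mole-fraction-weighted
averages over the composition.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .constants import ANGSTROM2_TO_M2, ELEMENTARY_CHARGE

__all__ = [
    "LipidSpecies",
    "MembraneSpec",
    "load_species_library",
    "effective_lipid_concentration",
    "mean_lipid_area",
    "intrinsic_surface_charge_density",
    "binding_site_area",
    "anionic_lipids_per_peptide",
]

_ALLOWED_CHARGES = (0, -1, -2)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid type with formal headgroup charge and cross-sectional area.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"POPC"``.
    formal_charge : int
        Formal charge in elementary units; must be 0, -1 or -2.
    cross_sectional_area : float
        Approximate area per lipid in the bilayer plane, Angstrom^2.
    """

    name: str
    formal_charge: int
    cross_sectional_area: float

    def __post_init__(self) -> None:
        if self.cross_sectional_area <= 0:
            raise ValueError(
                f"cross_sectional_area must be positive, got "
                f"{self.cross_sectional_area}"
            )
        if self.formal_charge not in _ALLOWED_CHARGES:
            raise ValueError(
                f"formal_charge must be one of {_ALLOWED_CHARGES}, got "
                f"{self.formal_charge}"
            )


def load_species_library() -> dict[str, LipidSpecies]:
    """Load the shipped lipid species table (name, charge, area)."""
    text = (
        importlib.resources.files("memtide")
        .joinpath("data/lipids.tsv")
        .read_text()
    )
    species: dict[str, LipidSpecies] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, charge, area = line.split("\t")
        species[name] = LipidSpecies(name, int(charge), float(area))
    return species


@dataclass(frozen=True)
class MembraneSpec:
    """An ideal lipid mixture: ordered (species, mole fraction) pairs."""

    components: tuple[tuple[LipidSpecies, float], ...]
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("membrane composition must not be empty")
        fractions = [f for _, f in self.components]
        if any(f < 0 for f in fractions):
            raise ValueError("mole fractions must be nonnegative")
        total = sum(fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total}")

    @classmethod
    def from_fractions(
        cls,
        fractions: dict[str, float],
        library: dict[str, LipidSpecies] | None = None,
        temperature: float = 298.15,
    ) -> "MembraneSpec":
        """Build a spec from ``{species name: mole fraction}``."""
        lib = library if library is not None else load_species_library()
        comps = tuple((lib[name], frac) for name, frac in fractions.items())
        return cls(comps, temperature)

    @property
    def anionic_fraction(self) -> float:
        """Total mole fraction of charged (anionic) species."""
        return sum(f for sp, f in self.components if sp.formal_charge != 0)

    @property
    def mean_charge(self) -> float:
        """Mole-fraction-weighted mean formal charge (elementary units)."""
        return sum(f * sp.formal_charge for sp, f in self.components)


def effective_lipid_concentration(total_lipid: float) -> float:
    """Outer-leaflet lipid concentration accessible to the peptide.

    Only the outer leaflet of a unilamellar vesicle is peptide-accessible,
    so the effective concentration is half the total.

    Parameters
    ----------
    total_lipid : float
        Total lipid concentration, M. Must be nonnegative.
    """
    if total_lipid < 0:
        raise ValueError(f"total_lipid must be nonnegative, got {total_lipid}")
    return total_lipid / 2.0


def mean_lipid_area(spec: MembraneSpec) -> float:
    """Mole-fraction-weighted mean lipid cross-sectional area, Angstrom^2."""
    return sum(f * sp.cross_sectional_area for sp, f in spec.components)


def intrinsic_surface_charge_density(spec: MembraneSpec) -> float:
    """Fully-ionized surface charge density sigma_max, C/m^2.

    sigma_max = (sum_i fraction_i * charge_i * e) / mean area.  Negative
    for anionic membranes.
    """
    area = mean_lipid_area(spec)
    if area <= 0:
        raise ValueError("mean lipid area must be positive")
    return spec.mean_charge * ELEMENTARY_CHARGE / (area * ANGSTROM2_TO_M2)


def binding_site_area(n: float, spec: MembraneSpec) -> float:
    """Area of an n-lipid binding site, Angstrom^2."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    return n * mean_lipid_area(spec)


def anionic_lipids_per_peptide(n: float, spec: MembraneSpec) -> float:
    """Average number of anionic lipids within an n-lipid binding site."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    return n * spec.anionic_fraction
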