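"""Seeded generators emulating the experimental inputs the pipeline fits.

Every generator is a pure function of (parameters, design, config): the
noise-free output equals the corresponding forward model bit-for-bit, and
a fixed seed reproduces the same series.  Replicate k of a config uses
seed + k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .binding import (
    LIPID_INTO_PEPTIDE,
    PEPTIDE_INTO_LIPID,
    BindingParameters,
    TitrationSeries,
    bound_peptide,
)
from .calcium import CalciumAssayState, solve_assay
from .gcs import (
    ElectrolyteComposition,
    peptide_modified_sigma,
    potential_profile,
    solve_surface_potential,
)
from .itc import ITCExperiment, ITCThermodynamics, simulate_heats
from .membranes import (
    MembraneSpec,
    intrinsic_surface_charge_density,
    mean_lipid_area,
)

__all__ = [
    "SyntheticDatasetConfig",
    "PeptideTitrationDesign",
    "gen_fluorescence_titration",
    "gen_lipid_titration",
    "gen_itc",
    "gen_charge_attenuation_series",
    "gen_calcium_titration",
]

MULTIPLICATIVE = "multiplicative_gaussian"
ADDITIVE = "additive_gaussian"


@dataclass(frozen=True)
class SyntheticDatasetConfig:
    """Seeding and noise structure shared by all generators."""

    seed: int = 0
    noise_model: str = MULTIPLICATIVE
    noise_scale: float = 0.0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_model not in (MULTIPLICATIVE, ADDITIVE):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def rng(self, replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + replicate)

    def apply_noise(self, y: np.ndarray, rng: np.random.Generator,
                    scale_ref: float | None = None) -> np.ndarray:
        if self.noise_scale == 0.0:
            return y
        if self.noise_model == MULTIPLICATIVE:
            return y * (1.0 + self.noise_scale * rng.standard_normal(y.size))
        ref = self.noise_scale if scale_ref is None \
            else self.noise_scale * scale_ref
        return y + ref * rng.standard_normal(y.size)


@dataclass(frozen=True)
class PeptideTitrationDesign:
    """Sampling schedule for a peptide-into-lipid titration.

    Defaults mirror 4-nmol increments into a 1 mL cuvette (4 uM steps).
    """

    peptide_max: float = 48e-6      # M
    peptide_step: float = 4e-6      # M
    l_eff: float = 125e-6           # M; design grid spans 25-125 uM

    def axis(self) -> np.ndarray:
        return np.arange(
            self.peptide_step,
            self.peptide_max + 0.5 * self.peptide_step,
            self.peptide_step,
        )


def gen_fluorescence_titration(
    params: BindingParameters,
    design: PeptideTitrationDesign = PeptideTitrationDesign(),
    config: SyntheticDatasetConfig = SyntheticDatasetConfig(),
    membrane: MembraneSpec | None = None,
    replicate: int = 0,
) -> TitrationSeries:
    """Peptide-into-lipid titration with the single-site forward model."""
    p_tot = design.axis()
    pb = bound_peptide(p_tot, design.l_eff, params.n, params.k_d)
    y = params.c_free * (p_tot - pb) + params.c_bound * pb
    y = config.apply_noise(y, config.rng(replicate))
    return TitrationSeries(
        mode=PEPTIDE_INTO_LIPID,
        fixed_species_total=design.l_eff,
        titrant_totals=p_tot,
        signal=y,
        membrane=membrane,
        label=f"synthetic peptide titration (seed {config.seed + replicate})",
    )


def gen_lipid_titration(
    params: BindingParameters,
    peptide_total: float,
    l_eff_axis,
    config: SyntheticDatasetConfig = SyntheticDatasetConfig(),
    membrane: MembraneSpec | None = None,
    replicate: int = 0,
) -> TitrationSeries:
    """Lipid-into-peptide F/F0 titration (saturation ratio = c_bound)."""
    l_eff = np.asarray(l_eff_axis, dtype=float)
    pb = bound_peptide(peptide_total, l_eff, params.n, params.k_d)
    r = params.c_bound
    y = 1.0 + (r - 1.0) * pb / peptide_total
    y = config.apply_noise(y, config.rng(replicate))
    return TitrationSeries(
        mode=LIPID_INTO_PEPTIDE,
        fixed_species_total=peptide_total,
        titrant_totals=l_eff,
        signal=y,
        membrane=membrane,
        label=f"synthetic lipid titration (seed {config.seed + replicate})",
    )


def gen_itc(
    params: ITCThermodynamics,
    experiment: ITCExperiment,
    config: SyntheticDatasetConfig = SyntheticDatasetConfig(),
    replicate: int = 0,
) -> ITCExperiment:
    """Synthetic thermogram: forward heats plus additive noise.

    Noise is additive on heats, scaled by the largest |Q| so that
    ``noise_scale`` reads as a fraction of the peak heat.
    """
    q = simulate_heats(experiment, params)
    rng = config.rng(replicate)
    if config.noise_scale > 0.0:
        q = q + config.noise_scale * float(np.max(np.abs(q))) * \
            rng.standard_normal(q.size)
    return replace(experiment, integrated_heats=q)


def gen_charge_attenuation_series(
    membrane: MembraneSpec,
    electrolyte: ElectrolyteComposition,
    occupancy_grid,
    readout: str = "zeta",
    config: SyntheticDatasetConfig = SyntheticDatasetConfig(),
    peptide_n: float = 6.9,
    floor_psi: float | None = -0.030,
    ans_amplitude: float = 1.0,
    replicate: int = 0,
) -> TitrationSeries:
    """Zeta or ANS readout versus peptide occupancy of the membrane.

    The forward chain is occupancy -> peptide-modified sigma -> surface
    potential -> zeta at the shear plane (or an ANS proxy increasing as
    |psi_0| shrinks).
    """
    if readout not in ("zeta", "ans"):
        raise ValueError(f"readout must be 'zeta' or 'ans', got {readout!r}")
    occ = np.asarray(occupancy_grid, dtype=float)
    sigma_max = intrinsic_surface_charge_density(membrane)
    area = mean_lipid_area(membrane)
    out = np.empty(occ.size)
    for i, o in enumerate(occ):
        sigma_eff, _ = peptide_modified_sigma(
            sigma_max, float(o), peptide_n, area,
            floor_psi=floor_psi, electrolyte=electrolyte,
        )
        state = solve_surface_potential(sigma_eff, electrolyte)
        if readout == "zeta":
            # zeta = psi at the shear plane: forward decay evaluated at x
            prof = potential_profile(state, state.shear_plane_x, points=2)
            out[i] = prof.psi_x[-1]
        else:
            # ANS binding grows as the negative surface potential attenuates
            psi0_bare = solve_surface_potential(sigma_max, electrolyte).psi_0
            out[i] = ans_amplitude * (1.0 - state.psi_0 / psi0_bare)
    out = config.apply_noise(out, config.rng(replicate),
                             scale_ref=float(np.max(np.abs(out))))
    # occupancy grid plays the role of the titrant axis (dimensionless dose)
    return TitrationSeries(
        mode=PEPTIDE_INTO_LIPID,
        fixed_species_total=0.0,
        titrant_totals=occ if occ[0] > 0 else occ + 1e-30,
        signal=out,
        membrane=membrane,
        label=f"synthetic {readout} series (seed {config.seed + replicate})",
    )


def gen_calcium_titration(
    base: CalciumAssayState,
    ca_grid,
    config: SyntheticDatasetConfig = SyntheticDatasetConfig(),
    replicate: int = 0,
) -> TitrationSeries:
    """Indicator signal versus total Ca2+, solving the assay per point."""
    ca = np.asarray(ca_grid, dtype=float)
    y = np.empty(ca.size)
    for i, c in enumerate(ca):
        solved = solve_assay(replace(base, ca_total=float(c)))
        y[i] = solved.predicted_signal
    y = config.apply_noise(y, config.rng(replicate))
    return TitrationSeries(
        mode=PEPTIDE_INTO_LIPID,
        fixed_species_total=base.probe_total,
        titrant_totals=ca,
        signal=y,
        membrane=base.membrane,
        label=f"synthetic Ca titration (seed {config.seed + replicate})",
    )
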