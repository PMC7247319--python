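"""Isothermal titration calorimetry: forward heat model and Wiseman fitting.

Lipid-into-peptide titrations: vesicles injected stepwise into a fixed
cell of peptide, with perfusion (overflow) dilution — each injection
multiplies prior cell contents by (1 - v/V0).  Heats derive from the
change in bound peptide per injection; fitting recovers (K_A, n, dH) and
the thermodynamic decomposition dG = -RT ln(K_A c0), dS = (dH - dG)/T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .binding import bound_peptide
from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT

__all__ = [
    "ITCExperiment",
    "ITCThermodynamics",
    "simulate_heats",
    "wiseman_coordinates",
    "fit_wiseman",
    "thermodynamic_decomposition",
]

# Standard-state concentration for dG = -RT ln(K_A * C_STANDARD)
C_STANDARD = 1.0  # M


@dataclass(frozen=True)
class ITCExperiment:
    """Injection schedule and geometry of a lipid-into-peptide run."""

    peptide_cell_conc: float                 # M
    cell_volume: float = 170e-6              # L
    syringe_lipid_total: float = 8e-3        # M, total lipid in syringe
    injection_volumes: np.ndarray = field(
        default_factory=lambda: np.full(20, 2.5e-6)
    )                                        # L
    integrated_heats: np.ndarray | None = None  # J, observed
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        v = np.asarray(self.injection_volumes, dtype=float)
        object.__setattr__(self, "injection_volumes", v)
        if self.cell_volume <= 0 or np.any(v <= 0):
            raise ValueError("volumes must be positive")
        if self.integrated_heats is not None:
            q = np.asarray(self.integrated_heats, dtype=float)
            object.__setattr__(self, "integrated_heats", q)
            if q.shape != v.shape:
                raise ValueError(
                    "heats series must match injection schedule length"
                )
        if float(v.sum()) > self.cell_volume:
            warnings.warn(
                "cumulative injected volume exceeds cell volume; perfusion "
                "correction is approximate in this regime",
                stacklevel=2,
            )

    @property
    def syringe_lipid_eff(self) -> float:
        """Outer-leaflet (peptide-accessible) lipid in the syringe, M."""
        return self.syringe_lipid_total / 2.0


@dataclass(frozen=True)
class ITCThermodynamics:
    """One-site binding thermodynamics.

    ``n`` is lipids (effective) per bound peptide; ``k_a`` the per-site
    association constant (1/M).  Energies in J/mol.
    """

    k_a: float
    n: float
    delta_h: float
    temperature: float = DEFAULT_TEMPERATURE
    stderr: dict = field(default_factory=dict)

    @property
    def k_d(self) -> float:
        return 1.0 / self.k_a

    @property
    def delta_g(self) -> float:
        return -GAS_CONSTANT * self.temperature * math.log(
            self.k_a * C_STANDARD
        )

    @property
    def delta_s(self) -> float:
        return (self.delta_h - self.delta_g) / self.temperature

    @property
    def minus_t_delta_s(self) -> float:
        return -self.temperature * self.delta_s


def _cell_trajectory(experiment: ITCExperiment):
    """Per-injection cell concentrations with perfusion dilution.

    Yields (dilution factor, peptide total, effective lipid total) after
    each injection.
    """
    v0 = experiment.cell_volume
    p = experiment.peptide_cell_conc
    l = 0.0
    for v in experiment.injection_volumes:
        d = 1.0 - v / v0
        p = p * d
        l = l * d + experiment.syringe_lipid_eff * (v / v0)
        yield d, p, l


def simulate_heats(
    experiment: ITCExperiment, params: ITCThermodynamics
) -> np.ndarray:
    """Per-injection heats (J) for one-site binding.

    Q_j = dH * V0 * (B_j - B_{j-1} (1 - v_j/V0)) where B is the bound
    peptide concentration in the cell after injection j.
    """
    kd = params.k_d
    heats = np.empty(experiment.injection_volumes.size)
    b_prev = 0.0
    for j, (d, p, l) in enumerate(_cell_trajectory(experiment)):
        b = bound_peptide(p, l, params.n, kd)
        heats[j] = params.delta_h * experiment.cell_volume * (b - b_prev * d)
        b_prev = b
    return heats


def wiseman_coordinates(experiment: ITCExperiment, heats=None):
    """(molar ratio, heat per mole of injectant) for the Wiseman plot.

    x = effective lipid / peptide in the cell after each injection;
    y = Q_j / (moles of effective lipid injected), J/mol.
    """
    q = np.asarray(
        heats if heats is not None else experiment.integrated_heats,
        dtype=float,
    )
    ratios = np.empty(q.size)
    for j, (_, p, l) in enumerate(_cell_trajectory(experiment)):
        ratios[j] = l / p
    moles_injected = (
        experiment.syringe_lipid_eff * experiment.injection_volumes
    )
    return ratios, q / moles_injected


def fit_wiseman(
    experiment: ITCExperiment,
    discard_first: bool = False,
) -> ITCThermodynamics:
    """Fit observed heats with the one-site model for (K_A, n, dH).

    ``discard_first`` drops the first injection (common practice for
    diffusion across the syringe tip).  Warns when the isotherm is
    featureless (low c-value).
    """
    if experiment.integrated_heats is None:
        raise ValueError("experiment carries no observed heats")
    q_obs = experiment.integrated_heats
    n_inform = q_obs.size - (1 if discard_first else 0)
    if n_inform < 8:
        raise ValueError("need at least 8 informative injections")

    w = np.ones(q_obs.size)
    if discard_first:
        w[0] = 0.0

    def unpack(p):
        return math.exp(p[0]), math.exp(p[1]), p[2]

    q_scale = float(np.max(np.abs(q_obs)))

    def resid(p):
        k_a, n, dh = unpack(p)
        model = simulate_heats(
            experiment,
            ITCThermodynamics(k_a, n, dh, experiment.temperature),
        )
        return w * (model - q_obs) / q_scale

    # crude dH seed: all peptide bound over the run
    dh0 = float(np.sum(q_obs)) / (
        experiment.cell_volume * experiment.peptide_cell_conc
    )
    bounds = ([math.log(1.0), math.log(1e-2), -np.inf],
              [math.log(1e12), math.log(1e4), np.inf])
    best = None
    for log_ka0 in (math.log(1e3), math.log(1e4), math.log(1e5),
                    math.log(1e6)):
        for n0 in (2.0, 5.0, 15.0):
            sol = least_squares(
                resid, [log_ka0, math.log(n0), dh0], bounds=bounds,
                method="trf", x_scale="jac",
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
            if best is not None and best.cost < 1e-24:
                break
        else:
            continue
        break
    if best is None:
        raise RuntimeError("Wiseman fit did not converge from any start")
    sol = best
    k_a, n, dh = unpack(sol.x)

    # Wiseman c-value: K_A * site concentration at mid-titration
    c_value = k_a * experiment.peptide_cell_conc
    if c_value < 1.0:
        warnings.warn(
            f"low c-value ({c_value:.2g}): isotherm nearly featureless, "
            "parameters poorly determined",
            stacklevel=2,
        )

    m, npar = sol.fun.size, 3
    dof = max(m - npar, 1)
    s_sq = 2.0 * sol.cost / dof
    try:
        cov = s_sq * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(npar, np.nan)
    stderr = {
        "k_a": k_a * se[0],
        "n": n * se[1],
        "delta_h": se[2],
    }
    return ITCThermodynamics(
        k_a=k_a, n=n, delta_h=dh,
        temperature=experiment.temperature, stderr=stderr,
    )


def thermodynamic_decomposition(
    k_a: float, delta_h: float, temperature: float = DEFAULT_TEMPERATURE
):
    """(dG, dS, -T dS) in J/mol from K_A (1/M) and dH (J/mol)."""
    if k_a <= 0:
        raise ValueError("K_A must be positive")
    delta_g = -GAS_CONSTANT * temperature * math.log(k_a * C_STANDARD)
    delta_s = (delta_h - delta_g) / temperature
    return delta_g, delta_s, -temperature * delta_s
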