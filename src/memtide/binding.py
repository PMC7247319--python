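"""Equilibrium peptide-membrane binding: forward models and fitting.

Single-site Langmuir adsorption treated exactly (no free ~ total
approximation): the lipid presents ``L_eff / n`` independent sites and the
bound-peptide concentration is the root of the mass-action quadratic.
Covers both titration directions, global salt-series fits with a shared
saturation point, Scatchard transforms, and partition coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import WATER_MOLARITY
from .membranes import MembraneSpec

__all__ = [
    "TitrationSeries",
    "BindingParameters",
    "ScatchardResult",
    "PartitionFit",
    "bound_peptide",
    "fit_peptide_titration",
    "fit_lipid_titration",
    "fit_global_salt_series",
    "scatchard_transform",
    "partition_coefficient",
    "fractional_saturation",
]

PEPTIDE_INTO_LIPID = "peptide_into_lipid"
LIPID_INTO_PEPTIDE = "lipid_into_peptide"

_MULTISTART_KDS = np.logspace(-8, -3, 5)  # M, used when first start fails


@dataclass(frozen=True)
class TitrationSeries:
    """One titration: a fixed species titrated with the other.

    ``titrant_totals`` is the cumulative titrant axis (M; effective
    outer-leaflet concentration when the titrant is lipid) and
    ``fixed_species_total`` the concentration of the species held fixed.
    """

    mode: str
    fixed_species_total: float
    titrant_totals: np.ndarray
    signal: np.ndarray
    membrane: MembraneSpec | None = None
    salt: object | None = None  # ElectrolyteComposition, opaque here
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in (PEPTIDE_INTO_LIPID, LIPID_INTO_PEPTIDE):
            raise ValueError(f"unknown titration mode {self.mode!r}")
        t = np.asarray(self.titrant_totals, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "titrant_totals", t)
        object.__setattr__(self, "signal", s)
        if t.shape != s.shape:
            raise ValueError("titrant axis and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("titrant axis must be strictly increasing")
        if np.any(t < 0) or self.fixed_species_total < 0:
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class BindingParameters:
    """Fitted single-site binding parameters.

    ``n`` is lipids per bound peptide, ``k_d`` the per-site dissociation
    constant (M); the per-lipid-monomer constant is ``n * k_d``.  ``k_p``
    is the dimensionless partition coefficient when fitted.  Amplitudes are
    the free/bound signal coefficients (signal units per M bound for
    peptide titrations; the saturation ratio ``r`` for lipid titrations).
    """

    n: float
    k_d: float
    c_free: float = 0.0
    c_bound: float = 0.0
    k_p: float = float("nan")
    stderr: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    unidentifiable: bool = False
    message: str = ""

    @property
    def n_k_d(self) -> float:
        """Per-lipid-monomer dissociation constant, M."""
        return self.n * self.k_d


def bound_peptide(p_total, l_eff, n: float, k_d: float):
    """Bound-peptide concentration from the single-site quadratic (M).

    Sites ``S = l_eff / n``; the physical root of
    ``PB^2 - (P + S + K_D) PB + P S = 0`` is

        PB = ((P + S + K_D) - sqrt((P + S + K_D)^2 - 4 P S)) / 2

    and satisfies ``0 <= PB <= min(P, S)``.  Accepts scalars or arrays.
    """
    if n <= 0 or k_d <= 0:
        raise ValueError("n and k_d must be positive")
    p = np.asarray(p_total, dtype=float)
    l = np.asarray(l_eff, dtype=float)
    if np.any(p < 0) or np.any(l < 0):
        raise ValueError("concentrations must be nonnegative")
    s = l / n
    b = p + s + k_d
    disc = b * b - 4.0 * p * s
    assert np.all(disc >= -1e-30), "negative discriminant"
    # smaller root in cancellation-free product form: PB = 2PS/(b + sqrt(disc))
    denom = b + np.sqrt(np.maximum(disc, 0.0))
    pb = np.where(denom > 0.0, 2.0 * p * s / np.where(denom > 0, denom, 1.0),
                  0.0)
    pb = np.minimum(pb, np.minimum(p, s))  # clip tiny fp overshoot
    if np.isscalar(p_total) and np.isscalar(l_eff):
        return float(pb)
    return pb


def fractional_saturation(p_total, params: BindingParameters, l_eff: float):
    """Fraction of lipid sites occupied, theta = PB / (L_eff / n) in [0, 1]."""
    pb = bound_peptide(p_total, l_eff, params.n, params.k_d)
    s_total = l_eff / params.n
    return pb / s_total


def _flat_signal(y: np.ndarray) -> bool:
    scale = max(float(np.max(np.abs(y))), 1e-300)
    return float(np.ptp(y)) < 1e-6 * scale


def _fit_with_multistart(resid, p0, bounds, kd_index):
    """Damped least squares; multistart on log-spaced K_D if needed."""
    best = None
    starts = [p0]
    sol = least_squares(resid, p0, bounds=bounds, method="trf")
    if sol.success and sol.cost < 1e-20:
        return sol
    best = sol if sol.success else None
    for kd in _MULTISTART_KDS:
        p = list(p0)
        p[kd_index] = math.log(kd)
        starts.append(p)
        sol = least_squares(resid, p, bounds=bounds, method="trf")
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            "binding fit did not converge from any start "
            f"({len(starts)} starts tried)"
        )
    return best


def _param_stderr(sol, names):
    """Asymptotic standard errors from the Jacobian at the optimum."""
    m, p = sol.fun.size, sol.x.size
    if m <= p:
        return {k: float("nan") for k in names}
    dof = m - p
    s_sq = 2.0 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = s_sq * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se.tolist()))


def fit_peptide_titration(
    series: TitrationSeries | list[TitrationSeries],
) -> BindingParameters:
    """Fit peptide-into-lipid titration(s) for (n, K_D, amplitudes).

    Model: ``signal = c_f (P_total - PB) + c_b PB`` with PB from
    :func:`bound_peptide`.  A list of series at different fixed lipid
    concentrations is fit jointly with shared (n, K_D, c_f, c_b).
    Reports the per-lipid-monomer constant ``n * K_D`` alongside.
    """
    series_list = [series] if isinstance(series, TitrationSeries) else series
    for s in series_list:
        if s.mode != PEPTIDE_INTO_LIPID:
            raise ValueError("fit_peptide_titration requires peptide titrations")
        if s.titrant_totals.size < 6:
            raise ValueError("need at least 6 points per series")

    all_y = np.concatenate([s.signal for s in series_list])
    if _flat_signal(all_y):
        return BindingParameters(
            n=float("nan"), k_d=float("nan"),
            unidentifiable=True,
            message="flat signal: no binding response, parameters "
                    "unidentifiable",
        )

    def unpack(p):
        return math.exp(p[0]), math.exp(p[1]), p[2], p[3]

    def resid(p):
        n, kd, c_f, c_b = unpack(p)
        out = []
        for s in series_list:
            pt = s.titrant_totals
            pb = bound_peptide(pt, s.fixed_species_total, n, kd)
            out.append(c_f * (pt - pb) + c_b * pb - s.signal)
        return np.concatenate(out)

    y_scale = float(np.max(np.abs(all_y)))
    x_scale = float(max(np.max(s.titrant_totals) for s in series_list))
    p0 = [math.log(7.0), math.log(1e-6), 0.0, y_scale / x_scale]
    bounds = ([math.log(1e-2), math.log(1e-12), -np.inf, -np.inf],
              [math.log(1e4), math.log(1.0), np.inf, np.inf])
    sol = _fit_with_multistart(resid, p0, bounds, kd_index=1)
    n, kd, c_f, c_b = unpack(sol.x)
    se = _param_stderr(sol, ["log_n", "log_k_d", "c_free", "c_bound"])
    # delta-method back-transform for the log-parameters
    stderr = {
        "n": n * se["log_n"],
        "k_d": kd * se["log_k_d"],
        "c_free": se["c_free"],
        "c_bound": se["c_bound"],
    }
    return BindingParameters(
        n=n, k_d=kd, c_free=c_f, c_bound=c_b, stderr=stderr,
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def fit_lipid_titration(
    series: TitrationSeries,
    n: float = 1.0,
    fit_n: bool = False,
) -> BindingParameters:
    """Fit a lipid-into-peptide titration F/F0 curve for (K_D, r).

    Model: ``F/F0 = 1 + (r - 1) PB / P_total``.  By default the lipid
    monomer is the site (``n = 1``) so the fitted K_D is directly the
    per-lipid-monomer constant; pass ``fit_n=True`` to fit the site size
    as well (weakly identified in the dilute-peptide regime).
    """
    if series.mode != LIPID_INTO_PEPTIDE:
        raise ValueError("fit_lipid_titration requires a lipid titration")
    if series.titrant_totals.size < 6:
        raise ValueError("need at least 6 points")

    y = series.signal
    p_tot = series.fixed_species_total
    l_eff = series.titrant_totals
    if _flat_signal(y - 1.0) and abs(float(np.mean(y)) - 1.0) < 1e-6:
        return BindingParameters(
            n=n, k_d=float("nan"), unidentifiable=True,
            message="r = 1 (no spectral change): K_D unidentifiable",
        )

    if fit_n:
        def unpack(p):
            return math.exp(p[0]), math.exp(p[1]), p[2]

        def resid(p):
            nn, kd, r = unpack(p)
            pb = bound_peptide(p_tot, l_eff, nn, kd)
            return 1.0 + (r - 1.0) * pb / p_tot - y

        p0 = [math.log(max(n, 1.0)), math.log(1e-6), float(y[-1])]
        bounds = ([math.log(1e-2), math.log(1e-12), -np.inf],
                  [math.log(1e4), math.log(1.0), np.inf])
        sol = _fit_with_multistart(resid, p0, bounds, kd_index=1)
        nn, kd, r = unpack(sol.x)
        names = ["log_n", "log_k_d", "r"]
    else:
        def unpack(p):
            return n, math.exp(p[0]), p[1]

        def resid(p):
            _, kd, r = unpack(p)
            pb = bound_peptide(p_tot, l_eff, n, kd)
            return 1.0 + (r - 1.0) * pb / p_tot - y

        p0 = [math.log(1e-6), float(y[-1])]
        bounds = ([math.log(1e-12), -np.inf], [math.log(1.0), np.inf])
        sol = _fit_with_multistart(resid, p0, bounds, kd_index=0)
        nn, kd, r = unpack(sol.x)
        names = ["log_k_d", "r"]

    se = _param_stderr(sol, names)
    stderr = {"k_d": kd * se["log_k_d"], "r": se["r"]}
    if "log_n" in se:
        stderr["n"] = nn * se["log_n"]
    return BindingParameters(
        n=nn, k_d=kd, c_free=1.0, c_bound=r, stderr=stderr,
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def fit_global_salt_series(
    series_set: list[TitrationSeries],
) -> list[BindingParameters]:
    """Globally fit lipid titrations that share a saturation point.

    All series must share mode (lipid-into-peptide) and membrane; each
    gets its own K_D while the saturation ratio ``r`` is common — the
    convention for salt series in which high-salt curves do not saturate.
    A single series degenerates to :func:`fit_lipid_titration`.
    """
    if not series_set:
        raise ValueError("empty series set")
    modes = {s.mode for s in series_set}
    if modes != {LIPID_INTO_PEPTIDE}:
        raise ValueError(f"incompatible modes in set: {sorted(modes)}")
    if len(series_set) == 1:
        return [fit_lipid_titration(series_set[0])]

    m = len(series_set)

    def resid(p):
        r = p[0]
        out = []
        for i, s in enumerate(series_set):
            kd = math.exp(p[1 + i])
            pb = bound_peptide(
                s.fixed_species_total, s.titrant_totals, 1.0, kd
            )
            out.append(
                1.0 + (r - 1.0) * pb / s.fixed_species_total - s.signal
            )
        return np.concatenate(out)

    p0 = [float(series_set[0].signal[-1])] + [math.log(1e-6)] * m
    bounds = ([-np.inf] + [math.log(1e-12)] * m,
              [np.inf] + [math.log(1.0)] * m)
    sol = least_squares(resid, p0, bounds=bounds, method="trf")
    if not sol.success:
        raise RuntimeError(f"global salt-series fit failed: {sol.message}")
    r = sol.x[0]
    se = _param_stderr(sol, ["r"] + [f"log_k_d_{i}" for i in range(m)])
    joint_norm = float(np.linalg.norm(sol.fun))
    results = []
    for i in range(m):
        kd = math.exp(sol.x[1 + i])
        results.append(BindingParameters(
            n=1.0, k_d=kd, c_free=1.0, c_bound=r,
            stderr={"k_d": kd * se[f"log_k_d_{i}"], "r": se["r"]},
            residual_norm=joint_norm,
        ))
    return results


@dataclass(frozen=True)
class ScatchardResult:
    """Scatchard-transformed data and its linear fit.

    ``nu`` is bound peptide per effective lipid; the fit of
    ``nu / P_free`` vs ``nu`` has slope ``-1/K_D`` (per-site) and
    x-intercept ``1/n``.
    """

    nu: np.ndarray
    nu_over_free: np.ndarray
    slope: float
    intercept: float
    x_intercept: float
    k_d: float
    n: float
    r_squared: float
    nonlinear: bool


def scatchard_transform(
    series: TitrationSeries,
    params_for_free: BindingParameters,
) -> ScatchardResult:
    """Transform a titration to Scatchard coordinates and fit the line.

    Bound peptide is recovered from the signal via the fitted amplitudes:
    peptide titrations use ``PB = (y - c_f P)/(c_b - c_f)``; lipid
    titrations use ``PB = P (y - 1)/(r - 1)``.
    """
    p = params_for_free
    if series.mode == PEPTIDE_INTO_LIPID:
        p_tot = series.titrant_totals
        l_eff = np.full_like(p_tot, series.fixed_species_total)
        if p.c_bound == p.c_free:
            raise ValueError("degenerate amplitudes: c_bound == c_free")
        pb = (series.signal - p.c_free * p_tot) / (p.c_bound - p.c_free)
    else:
        p_tot = np.full_like(series.titrant_totals,
                             series.fixed_species_total)
        l_eff = series.titrant_totals
        r = p.c_bound
        if r == 1.0:
            raise ValueError("degenerate saturation ratio r = 1")
        pb = p_tot * (series.signal - 1.0) / (r - 1.0)

    p_free = p_tot - pb
    mask = (p_free > 0) & (l_eff > 0) & (pb > 0)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 points with positive free peptide")
    nu = pb[mask] / l_eff[mask]
    y = nu / p_free[mask]

    a = np.vstack([nu, np.ones_like(nu)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(a, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(res[0]) if res.size else float(
        np.sum((y - a @ [slope, intercept]) ** 2)
    )
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    nonlinear = r_squared < 0.99
    if nonlinear:
        warnings.warn(
            f"Scatchard plot is nonlinear (R^2 = {r_squared:.4f}); "
            "single-site parameters unreliable",
            stacklevel=2,
        )
    x_intercept = -intercept / slope
    return ScatchardResult(
        nu=nu, nu_over_free=y,
        slope=float(slope), intercept=float(intercept),
        x_intercept=float(x_intercept),
        k_d=float(-1.0 / slope), n=float(1.0 / x_intercept),
        r_squared=r_squared, nonlinear=nonlinear,
    )


@dataclass(frozen=True)
class PartitionFit:
    """Partition-coefficient fit with its convention recorded."""

    k_p: float
    convention: str
    r: float
    residual_norm: float
    stderr: dict


def partition_coefficient(
    series: TitrationSeries,
    convention: str = "water_normalized",
) -> PartitionFit:
    """Fit a lipid titration with a partition-equilibrium model.

    ``site_free``: f_b = K_x L_eff / (1 + K_x L_eff).
    ``water_normalized``: f_b = K_P L_eff / ([W] + K_P L_eff), [W] = 55.3 M.
    The observed F/F0 is ``1 + (r - 1) f_b``.
    """
    if series.mode != LIPID_INTO_PEPTIDE:
        raise ValueError("partition_coefficient requires a lipid titration")
    if convention not in ("site_free", "water_normalized"):
        raise ValueError(f"unknown convention {convention!r}")
    l_eff = series.titrant_totals
    y = series.signal

    def f_bound(k, l):
        if convention == "site_free":
            return k * l / (1.0 + k * l)
        return k * l / (WATER_MOLARITY + k * l)

    def resid(p):
        k, r = math.exp(p[0]), p[1]
        return 1.0 + (r - 1.0) * f_bound(k, l_eff) - y

    k0 = math.log(1e4 if convention == "water_normalized" else 1e5)
    sol = least_squares(
        resid, [k0, float(y[-1])],
        bounds=([math.log(1e-6), -np.inf], [math.log(1e12), np.inf]),
        method="trf",
    )
    if not sol.success:
        raise RuntimeError(f"partition fit failed: {sol.message}")
    k_p, r = math.exp(sol.x[0]), sol.x[1]
    se = _param_stderr(sol, ["log_k_p", "r"])
    return PartitionFit(
        k_p=float(k_p), convention=convention, r=float(r),
        residual_norm=float(np.linalg.norm(sol.fun)),
        stderr={"k_p": k_p * se["log_k_p"], "r": se["r"]},
    )
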