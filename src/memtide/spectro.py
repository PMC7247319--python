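"""Reduction of raw fluorescence readings to derived statistics.

Covers blank subtraction, laurdan/prodan generalized polarization,
steady-state anisotropy, Stern-Volmer quenching slopes, and
hyperbolic/Hill saturation-curve fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SaturationFit",
    "background_subtract",
    "generalized_polarization_laurdan",
    "generalized_polarization_prodan",
    "steady_state_anisotropy",
    "stern_volmer_fit",
    "fit_saturation_curve",
]

PRODAN_K_DEFAULT = 2.8
ANISOTROPY_PHYSICAL_RANGE = (-0.2, 0.4)


def background_subtract(raw, blank):
    """Elementwise ``raw - blank``; negative results are kept but flagged.

    Returns
    -------
    (corrected, has_negative) : (ndarray, bool)
    """
    raw = np.asarray(raw, dtype=float)
    blank = np.asarray(blank, dtype=float)
    if raw.shape != blank.shape:
        raise ValueError(
            f"raw and blank must have equal length, got {raw.shape} vs "
            f"{blank.shape}"
        )
    corrected = raw - blank
    has_negative = bool(np.any(corrected < 0))
    if has_negative:
        warnings.warn(
            "background-subtracted signal is negative at some points "
            "(noise floor); values retained, not clipped",
            stacklevel=2,
        )
    return corrected, has_negative


def generalized_polarization_laurdan(i_440: float, i_490: float) -> float:
    """Two-wavelength GP: (I440 - I490) / (I440 + I490)."""
    denom = i_440 + i_490
    if denom <= 0:
        raise ValueError("I_440 + I_490 must be positive")
    return (i_440 - i_490) / denom


def generalized_polarization_prodan(
    i_420: float, i_480: float, i_530: float, k: float = PRODAN_K_DEFAULT
) -> float:
    """Three-wavelength GP: (R12 - 1)/(R12 + 1) with R12 = I420*k/(I480*k - I530).

    ``k`` is an instrument cross-calibration constant, default 2.8.
    """
    denom = i_480 * k - i_530
    if denom == 0:
        raise ValueError("singular denominator: I_480*k == I_530")
    r12 = i_420 * k / denom
    return (r12 - 1.0) / (r12 + 1.0)


def steady_state_anisotropy(
    i_vv: float, i_vh: float, i_hv: float, i_hh: float
) -> float:
    """<r> = (I_VV - G*I_VH) / (I_VV + 2*G*I_VH), with G = I_HV/I_HH.

    Warns when the result lies outside the physically meaningful range
    [-0.2, 0.4].
    """
    if i_hh <= 0:
        raise ValueError("I_HH must be positive to compute the G-factor")
    g = i_hv / i_hh
    denom = i_vv + 2.0 * g * i_vh
    if denom <= 0:
        raise ValueError("anisotropy denominator must be positive")
    r = (i_vv - g * i_vh) / denom
    lo, hi = ANISOTROPY_PHYSICAL_RANGE
    if not lo <= r <= hi:
        warnings.warn(
            f"anisotropy {r:.4g} outside physical range [{lo}, {hi}]",
            stacklevel=2,
        )
    return r


def stern_volmer_fit(quencher_concs, f_values, f_0):
    """Least-squares slope of (F0/F - 1) vs [Q], constrained through origin.

    Returns
    -------
    (k_sv, stderr) : (float, float)
        Quenching constant in 1/M and its standard error.
    """
    q = np.asarray(quencher_concs, dtype=float)
    f = np.asarray(f_values, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(f <= 0):
        raise ValueError("all F values must be positive")
    if np.all(q == 0):
        raise ValueError("quencher axis is identically zero")
    y = f_0 / f - 1.0
    # closed-form through-origin regression
    sxx = float(np.dot(q, q))
    k_sv = float(np.dot(q, y)) / sxx
    resid = y - k_sv * q
    dof = max(q.size - 1, 1)
    stderr = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return k_sv, stderr


@dataclass(frozen=True)
class SaturationFit:
    """Parameters of a saturating dose-response fit.

    ``signal = baseline + amplitude * x^h / (half_saturation^h + x^h)``;
    the hyperbolic model is the Hill model with ``hill_coefficient = 1``.
    """

    model: str
    amplitude: float
    half_saturation: float
    hill_coefficient: float
    baseline: float
    residual_norm: float
    degenerate: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        h = self.hill_coefficient
        with np.errstate(invalid="ignore"):
            frac = np.where(
                x > 0,
                x**h / (self.half_saturation**h + x**h),
                0.0,
            )
        return self.baseline + self.amplitude * frac


def fit_saturation_curve(x, y, model: str = "hyperbolic") -> SaturationFit:
    """Fit a hyperbolic or Hill saturation curve by nonlinear least squares.

    Degenerate (flat) data yields amplitude 0 and a ``degenerate`` flag
    instead of a spurious half-saturation.
    """
    if model not in ("hyperbolic", "hill"):
        raise ValueError(f"model must be 'hyperbolic' or 'hill', got {model!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")

    y_range = float(np.ptp(y))
    if y_range == 0.0:
        return SaturationFit(
            model=model,
            amplitude=0.0,
            half_saturation=float("nan"),
            hill_coefficient=1.0,
            baseline=float(y[0]),
            residual_norm=0.0,
            degenerate=True,
        )

    amp0 = float(y[-1] - y[0])
    k0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    base0 = float(y[0])

    if model == "hyperbolic":
        p0 = [amp0, k0, base0]

        def resid(p):
            amp, k, base = p
            return base + amp * x / (k + x) - y

        bounds = ([-np.inf, 1e-300, -np.inf], [np.inf, np.inf, np.inf])
    else:
        p0 = [amp0, k0, 1.0, base0]

        def resid(p):
            amp, k, h, base = p
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(x > 0, x**h / (k**h + x**h), 0.0)
            return base + amp * frac - y

        bounds = (
            [-np.inf, 1e-300, 1e-6, -np.inf],
            [np.inf, np.inf, np.inf, np.inf],
        )

    sol = least_squares(resid, p0, bounds=bounds, method="trf")
    if not sol.success:
        raise RuntimeError(
            f"saturation fit did not converge: {sol.message} "
            f"(status {sol.status}, cost {sol.cost:.3g})"
        )
    if model == "hyperbolic":
        amp, k, base = sol.x
        h = 1.0
    else:
        amp, k, h, base = sol.x
    return SaturationFit(
        model=model,
        amplitude=float(amp),
        half_saturation=float(k),
        hill_coefficient=float(h),
        baseline=float(base),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )
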