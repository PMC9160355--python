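"""Exponential-decay and binding-isotherm fits.

RNA half-lives (rifampicin-chase time courses) and ATP-hydrolysis time
courses are fit to single exponentials ``y = A*exp(-lam*t)``; Rho–RNA
gel-shift titrations are fit to a hyperbolic isotherm
``y = bmax*x/(kd + x)`` or the Hill sigmoid ``y = bmax*x**n/(kd**n + x**n)``
(multiple Rho-binding sites make the isotherms sigmoidal).  Both fits use
bounded nonlinear least squares started from analytic linearizations, so
no random initialization is involved.

The decay fit reports both the rate constant lam (per minute) and the
initial rate A*lam (signal per minute); which of the two is "the rate"
depends on the assay's calibration, so both are labeled outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, ValidationError

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecayFit:
    """y = A*exp(-lam*t); half_life = ln2/lam when the data decay."""

    A: float
    lam: float
    half_life: Optional[float]
    initial_rate: Optional[float]  # A*lam, signal/min
    rss: float
    n_points: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BindingFit:
    model: str  # "hyperbolic" or "hill"
    kd: float
    hill_n: float
    bmax: float
    rss: float
    n_points: int
    flags: tuple[str, ...] = ()


def _decay(t: np.ndarray, A: float, lam: float) -> np.ndarray:
    return A * np.exp(-lam * t)


def fit_exponential_decay(
    t: Sequence[float], y: Sequence[float]
) -> DecayFit:
    """Fit y = A*exp(-lam*t) by nonlinear least squares.

    Initialization is the log-linear regression of ln y on t.  Data that do
    not decay (fitted lam <= 0) are returned flagged, with no half-life.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("t and y must have equal length")
    if len(np.unique(t)) < 3:
        raise InsufficientDataError("need >= 3 distinct time points")
    if np.any(y <= 0):
        raise ValidationError("signals must be > 0 for log-linear initialization")
    slope, logA = np.polyfit(t, np.log(y), 1)
    A0, lam0 = float(np.exp(logA)), float(-slope)
    span = float(t.max() - t.min())

    def _negligible(lam: float) -> bool:
        # no measurable decay over the observed time span
        return lam * span <= 1e-9

    if lam0 <= 0 or _negligible(lam0):
        resid = y - _decay(t, A0, lam0)
        return DecayFit(
            A=A0, lam=lam0, half_life=None, initial_rate=None,
            rss=float(resid @ resid), n_points=len(t),
            flags=("non_decaying",),
        )
    popt, _ = curve_fit(_decay, t, y, p0=[A0, lam0], maxfev=10_000)
    A, lam = (float(v) for v in popt)
    resid = y - _decay(t, A, lam)
    rss = float(resid @ resid)
    if lam <= 0 or _negligible(lam):
        return DecayFit(A, lam, None, None, rss, len(t), flags=("non_decaying",))
    return DecayFit(
        A=A, lam=lam, half_life=LN2 / lam, initial_rate=A * lam,
        rss=rss, n_points=len(t),
    )


def _hyperbolic(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * x / (kd + x)


def _hill(x: np.ndarray, bmax: float, kd: float, n: float) -> np.ndarray:
    return bmax * x**n / (kd**n + x**n)


def _aicc(rss: float, n: int, k: int) -> float:
    # small-sample corrected information criterion for LS fits
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_binding_isotherm(
    conc: Sequence[float],
    frac_bound: Sequence[float],
    model: str = "auto",
    fix_hill_n: Optional[float] = None,
) -> BindingFit:
    """Fit a binding isotherm and report the dissociation constant Kd.

    ``model`` is ``hyperbolic``, ``hill`` or ``auto`` (pick the lower
    small-sample information criterion).  ``fix_hill_n`` pins the Hill
    coefficient instead of fitting it (n = 1 reduces to the hyperbola).
    Concentrations in nM; fractions bound in [0, 1].  Titrations that never
    approach the fitted plateau are flagged ``wide_ci`` rather than
    rejected.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(frac_bound, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("conc and frac_bound must have equal length")
    if len(x) < 4:
        raise InsufficientDataError("need >= 4 concentrations")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("concentrations and fractions must be >= 0")
    if model not in ("hyperbolic", "hill", "auto"):
        raise ValidationError(f"unknown model {model!r}")

    bmax0 = max(float(y.max()), 1e-6)
    half = bmax0 / 2.0
    above = x[y >= half]
    kd0 = float(above.min()) if above.size else float(x[x > 0].max())
    kd0 = max(kd0, 1e-9)

    def _fit_hyperbolic() -> BindingFit:
        popt, _ = curve_fit(
            _hyperbolic, x, y, p0=[bmax0, kd0],
            bounds=([1e-9, 1e-9], [1.2, np.inf]), maxfev=20_000,
        )
        bmax, kd = (float(v) for v in popt)
        resid = y - _hyperbolic(x, bmax, kd)
        return BindingFit("hyperbolic", kd, 1.0, bmax, float(resid @ resid), len(x))

    def _fit_hill() -> BindingFit:
        if fix_hill_n is not None:
            n = float(fix_hill_n)
            popt, _ = curve_fit(
                lambda xx, bmax, kd: _hill(xx, bmax, kd, n),
                x, y, p0=[bmax0, kd0],
                bounds=([1e-9, 1e-9], [1.2, np.inf]), maxfev=20_000,
            )
            bmax, kd = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                _hill, x, y, p0=[bmax0, kd0, 1.5],
                bounds=([1e-9, 1e-9, 1.0], [1.2, np.inf, 8.0]), maxfev=20_000,
            )
            bmax, kd, n = (float(v) for v in popt)
        resid = y - _hill(x, bmax, kd, n)
        return BindingFit("hill", kd, n, bmax, float(resid @ resid), len(x))

    if model == "hyperbolic":
        fit = _fit_hyperbolic()
    elif model == "hill":
        fit = _fit_hill()
    else:
        hyp, hill = _fit_hyperbolic(), _fit_hill()
        fit = min(
            (hyp, hill),
            key=lambda f: _aicc(f.rss, f.n_points, 2 if f.model == "hyperbolic" else 3),
        )
    if float(y.max()) < 0.5 * fit.bmax:
        fit = BindingFit(
            fit.model, fit.kd, fit.hill_n, fit.bmax, fit.rss, fit.n_points,
            flags=fit.flags + ("wide_ci",),
        )
    return fit
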