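"""Thermal-denaturation analysis from intrinsic tryptophan fluorescence.

Unfolding of a Trp-containing domain red-shifts its emission band, so the
intensity ratio I328/I352 falls (or rises) through a two-state transition.
The melting temperature T_m is the inflection point of a four-parameter
logistic fitted to ratio vs temperature:

    f(x) = y0 + a / (1 + exp(-b (x - x0)))

with y0 the pre-transition level, a the amplitude, b the steepness (1/degC)
and x0 = T_m.  Data that an optimiser cannot describe with this shape (noise,
no transition in range) are gated out rather than assigned a meaningless T_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SpectrumSeries",
    "MeltCurve",
    "SigmoidFit",
    "logistic4",
    "ratio_from_spectra",
    "fit_sigmoid",
    "assess_sigmoidality",
    "melt_anova",
]


def logistic4(x, y0: float, a: float, b: float, x0: float):
    """Four-parameter logistic y0 + a/(1 + exp(-b(x - x0)))."""
    return y0 + a / (1.0 + np.exp(-b * (np.asarray(x, dtype=float) - x0)))


@dataclass(frozen=True)
class SpectrumSeries:
    """Temperature-resolved emission spectra (M temperatures x W wavelengths)."""

    temperatures: np.ndarray  # degC, strictly increasing
    wavelengths: np.ndarray  # nm grid, strictly increasing
    intensities: np.ndarray  # (M, W), arbitrary units
    replicate_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        w = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(t) <= 0) or t.min() < 0 or t.max() > 100:
            raise ValueError("temperatures must be strictly increasing in [0, 100] degC")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if inten.shape != (len(t), len(w)):
            raise ValueError(
                f"intensity matrix {inten.shape} inconsistent with "
                f"{len(t)} temperatures x {len(w)} wavelengths"
            )
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class MeltCurve:
    """I328/I352 (or other two-wavelength ratio) against temperature."""

    temperatures: np.ndarray
    ratio: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if len(t) != len(r):
            raise ValueError("temperature and ratio lengths differ")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("ratios must be finite and positive")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "ratio", r)


@dataclass(frozen=True)
class SigmoidFit:
    y0: float
    a: float
    b: float  # 1/degC
    x0: float  # inflection = T_m, degC
    covariance: np.ndarray  # 4x4
    r_squared: float
    residual_rms: float
    sigmoidal: bool
    reasons: tuple[str, ...] = ()
    converged: bool = True

    @property
    def Tm(self) -> float:
        """Melting temperature; NaN when the data are not sigmoidal."""
        return self.x0 if self.sigmoidal else math.nan

    @property
    def se_x0(self) -> float:
        v = self.covariance[3, 3]
        return math.sqrt(v) if np.isfinite(v) and v >= 0 else math.inf

    def predict(self, x):
        return logistic4(x, self.y0, self.a, self.b, self.x0)


def ratio_from_spectra(
    s: SpectrumSeries,
    lam_num: float = 328.0,
    lam_den: float = 352.0,
    blank: SpectrumSeries | None = None,
) -> MeltCurve:
    """Reduce a spectrum series to the two-wavelength intensity ratio.

    Wavelengths are snapped to the nearest grid point (1 nm grids make
    interpolation pointless).  A blank series of identical shape is
    subtracted first when supplied.
    """
    w = s.wavelengths
    if not (w[0] <= lam_num <= w[-1]) or not (w[0] <= lam_den <= w[-1]):
        raise ValueError(
            f"requested wavelengths {lam_num}/{lam_den} nm outside grid "
            f"[{w[0]}, {w[-1]}]"
        )
    inten = s.intensities
    if blank is not None:
        if blank.intensities.shape != inten.shape:
            raise ValueError("blank series shape does not match sample")
        inten = inten - blank.intensities
    i_num = int(np.argmin(np.abs(w - lam_num)))
    i_den = int(np.argmin(np.abs(w - lam_den)))
    den = inten[:, i_den]
    if np.any(den <= 0):
        raise ValueError("non-positive denominator intensity after blank subtraction")
    return MeltCurve(s.temperatures, inten[:, i_num] / den, s.replicate_id)


def _init_sigmoid(t: np.ndarray, r: np.ndarray) -> tuple[float, float, float, float]:
    y0 = float(np.mean(r[:3]))
    a = float(r[-1] - r[0])
    if a == 0.0:
        a = 1e-3
    dr = np.diff(r) / np.diff(t)
    x0 = float(t[:-1][np.argmax(np.abs(dr))])
    lo, hi = y0 + 0.25 * a, y0 + 0.75 * a
    frac = (r - r[0]) / a if a != 0 else np.zeros_like(r)
    inside = t[(frac > 0.25) & (frac < 0.75)]
    span = float(inside.max() - inside.min()) if len(inside) > 1 else float(t[-1] - t[0]) / 4
    b = 4.0 / max(span, 1e-6)
    return y0, a, b, x0


def fit_sigmoid(
    curve: MeltCurve,
    init: tuple[float, float, float, float] | None = None,
    gate: bool = True,
) -> SigmoidFit:
    """Fit the four-parameter logistic and extract T_m.

    Requires >= 6 points spanning >= 30 degC.  When ``gate`` is true the
    sigmoidality checks of :func:`assess_sigmoidality` decide whether x0 is
    reported as a T_m at all.
    """
    t = curve.temperatures
    r = curve.ratio
    if len(t) < 6 or (t[-1] - t[0]) < 30:
        raise ValueError("need >= 6 points spanning >= 30 degC")
    p0 = init if init is not None else _init_sigmoid(t, r)
    nan_cov = np.full((4, 4), np.nan)
    try:
        popt, pcov = optimize.curve_fit(
            logistic4, t, r, p0=p0, maxfev=20000, xtol=1e-14, ftol=1e-14
        )
        converged = True
    except RuntimeError:
        popt, pcov, converged = np.array(p0), nan_cov, False
    resid = r - logistic4(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    fit = SigmoidFit(
        y0=float(popt[0]),
        a=float(popt[1]),
        b=float(popt[2]),
        x0=float(popt[3]),
        covariance=np.asarray(pcov, dtype=float),
        r_squared=r2,
        residual_rms=rms,
        sigmoidal=converged,
        converged=converged,
    )
    if gate:
        ok, reasons = assess_sigmoidality(fit, curve)
        fit = SigmoidFit(
            **{**fit.__dict__, "sigmoidal": ok, "reasons": tuple(reasons)}
        )
    return fit


def assess_sigmoidality(fit: SigmoidFit, curve: MeltCurve) -> tuple[bool, list[str]]:
    """Decide whether a fitted transition is a real sigmoid.

    Rejects when the optimiser failed, the amplitude is below 3x the residual
    noise, the inflection lies outside the sampled temperature range, the
    transition is broader than the sampled range (a near-zero-steepness
    logistic can mimic a straight line arbitrarily well), or the standard
    error of the inflection exceeds 5 degC.
    """
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("optimizer failed")
    else:
        if abs(fit.a) < 3.0 * fit.residual_rms:
            reasons.append("amplitude below noise")
        t = curve.temperatures
        if not (t[0] <= fit.x0 <= t[-1]):
            reasons.append("inflection outside range")
        if abs(fit.b) * (t[-1] - t[0]) < 1.0:
            reasons.append("transition broader than sampled range")
        if not (fit.se_x0 <= 5.0):
            reasons.append("inflection standard error > 5 degC")
    return (len(reasons) == 0, reasons)


def melt_anova(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across groups of replicate T_m values.

    Returns (F, p).  Degenerate input (zero within- and between-group
    variance) gives F = 0, p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ss_between < 1e-12 * (ss_between + ss_within):
        ss_between = 0.0  # identical group means up to rounding
    df_b = len(gs) - 1
    df_w = len(all_vals) - len(gs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p
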