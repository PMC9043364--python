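"""Backbone dynamics from NMR relaxation data.

The steady-state heteronuclear 1H->15N NOE is the ratio of crosspeak
intensities with and without proton saturation; values near the rigid-limit
(~0.8 at high field) indicate an ordered backbone, while low or negative
values mark residues with fast picosecond motions (flexible loops, termini).
T1/T2 relaxation rates come from mono-exponential fits to delay series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "HetNOERecord",
    "DecaySeries",
    "DecayFit",
    "het_noe",
    "classify_mobility",
    "fit_monoexponential",
    "T1_DELAYS_S",
    "T2_DELAYS_S",
]

# standard delay schedules (s) for amide 15N T1/T2 series
T1_DELAYS_S = (0.020, 0.060, 0.080, 0.100, 0.200, 0.400, 0.600, 0.800, 1.000, 1.200, 1.400)
T2_DELAYS_S = (0.016, 0.030, 0.060, 0.095, 0.125, 0.160, 0.190, 0.220, 0.250, 0.345, 0.440, 0.500)


@dataclass(frozen=True)
class HetNOERecord:
    id: int | str
    I_sat: float
    I_ref: float
    noe: float
    sigma_noe: float


@dataclass(frozen=True)
class DecaySeries:
    id: int | str
    delays: tuple[float, ...]  # s, strictly increasing, >= 0
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.delays)
        if len(d) < 2 or any(b <= a for a, b in zip(d, d[1:])) or d[0] < 0:
            raise ValueError("delays must be non-negative and strictly increasing")
        if len(self.intensities) != len(d):
            raise ValueError("delay and intensity lengths differ")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "intensities", tuple(float(x) for x in self.intensities))


@dataclass(frozen=True)
class DecayFit:
    id: int | str
    I0: float
    T_relax: float  # s
    se_I0: float
    se_T: float
    converged: bool
    message: str = ""


def het_noe(
    I_sat: float,
    I_ref: float,
    sigma_sat: float = 0.0,
    sigma_ref: float = 0.0,
    id: int | str = "",
) -> HetNOERecord:
    """NOE = I_sat / I_ref with first-order error propagation.

    Negative NOEs are legal (highly mobile residues); a zero reference
    intensity is not.
    """
    if I_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    noe = I_sat / I_ref
    if I_sat == 0:
        sigma = abs(sigma_sat / I_ref)
    else:
        sigma = abs(noe) * math.sqrt((sigma_sat / I_sat) ** 2 + (sigma_ref / I_ref) ** 2)
    return HetNOERecord(id=id, I_sat=I_sat, I_ref=I_ref, noe=noe, sigma_noe=sigma)


def classify_mobility(
    records, flexible_below: float = 0.75
) -> dict[str, list[HetNOERecord]]:
    """Split residues into {flexible, ordered} sets by their NOE.

    A residue is flexible iff noe < flexible_below (strict); the default
    cutoff sits between the ~0.8 typical of an ordered backbone and the
    0.5-0.7 band of mobile loops.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to classify")
    return {
        "flexible": [r for r in records if r.noe < flexible_below],
        "ordered": [r for r in records if r.noe >= flexible_below],
    }


def fit_monoexponential(series: DecaySeries) -> DecayFit:
    """Least-squares fit of I(t) = I0 exp(-t / T_relax) to a delay series.

    Designed for the usual 11-12 point schedules; two points determine the
    pair exactly (e-folding identity).  Non-decaying data (flat or rising)
    yield ``converged=False`` rather than an unphysical time constant.
    """
    t = np.asarray(series.delays)
    y = np.asarray(series.intensities)
    if np.any(y <= 0):
        raise ValueError("intensities must be positive for a decay fit")
    # log-linear start, refined by nonlinear least squares on the raw scale
    slope, icpt = np.polyfit(t, np.log(y), 1)
    if slope >= -1e-12:
        return DecayFit(series.id, float(y[0]), math.inf, math.nan, math.nan,
                        converged=False, message="data do not decay")
    p0 = (math.exp(icpt), -1.0 / slope)
    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, I0, T: I0 * np.exp(-tt / T), t, y, p0=p0, maxfev=10000
        )
    except RuntimeError as e:
        return DecayFit(series.id, math.nan, math.nan, math.nan, math.nan,
                        converged=False, message=str(e))
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return DecayFit(
        id=series.id,
        I0=float(popt[0]),
        T_relax=float(popt[1]),
        se_I0=float(se[0]),
        se_T=float(se[1]),
        converged=popt[1] > 0,
    )
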