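"""Single-site ("independent") ITC binding model: forward simulation, fitting,
and thermodynamic state functions.

The model treats the macromolecule M (here a CW reader domain) as carrying
``n`` identical independent sites for the ligand X (a methylated histone-tail
peptide).  At total concentrations ``Mt`` and ``Xt`` the bound-complex
concentration follows 1:1 mass action,

    [MX] = (b - sqrt(b^2 - 4 n Mt Xt)) / 2,   b = n Mt + Xt + Kd,

and the cumulative heat evolved in a cell of volume ``V0`` is
``Q = dH * V0 * [MX]``.  Per-injection heats include the standard
perfusion-cell displacement correction: injecting volume ``v`` pushes an
equal volume of partially equilibrated mixture out of the active volume, so

    q_i = Q_i - Q_{i-1} + (v_i / V0) * (Q_i + Q_{i-1}) / 2 .

Concentration dilution uses the displacement approximation
``Mt_i = M0 (1 - d/2V0)/(1 + d/2V0)`` and ``Xt_i = X0 (d/V0)/(1 + d/2V0)``
with ``d`` the cumulative injected volume.

Units follow instrument conventions: volumes in liters, concentrations in
molar, heats in microjoules, enthalpies in kJ/mol, temperatures in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

R_GAS = 8.314  # J/(mol K)

__all__ = [
    "ThermodynamicParameters",
    "TitrationDesign",
    "Isotherm",
    "FitResult",
    "solve_bound_concentration",
    "predict_injection_heats",
    "subtract_blank",
    "fit_independent_model",
    "derive_state_functions",
    "compare_groups_ttest",
]


def derive_state_functions(Kd: float, dH: float, T: float = 298.15) -> tuple[float, float, float]:
    """Gibbs energy, entropic term and entropy from Kd and binding enthalpy.

    Parameters
    ----------
    Kd : dissociation constant, molar.
    dH : binding enthalpy, kJ/mol.
    T : absolute temperature, K.

    Returns
    -------
    (dG, TdS, dS) : kJ/mol, kJ/mol, J/(mol K).

    dG = R T ln Kd (negative for sub-molar Kd), TdS = dH - dG, dS = 1000 TdS / T.
    """
    if Kd <= 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    dG = R_GAS * T * math.log(Kd) / 1000.0
    TdS = dH - dG
    dS = 1000.0 * TdS / T
    return dG, TdS, dS


@dataclass(frozen=True)
class ThermodynamicParameters:
    """Binding thermodynamics of one 1:1 association reaction.

    ``dG``, ``TdS`` and ``dS`` are derived from ``Kd``, ``dH`` and ``T`` at
    construction and always satisfy dG = RT ln Kd, TdS = dH - dG.
    """

    Kd: float  # dissociation constant, M
    dH: float  # binding enthalpy, kJ/mol
    n: float = 1.0  # stoichiometric coefficient
    T: float = 298.15  # K
    dG: float = field(init=False)
    dS: float = field(init=False)
    TdS: float = field(init=False)

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.T <= 0 or self.n <= 0:
            raise ValueError("Kd, T and n must all be positive")
        dG, TdS, dS = derive_state_functions(self.Kd, self.dH, self.T)
        object.__setattr__(self, "dG", dG)
        object.__setattr__(self, "TdS", TdS)
        object.__setattr__(self, "dS", dS)

    @property
    def Ka(self) -> float:
        """Association constant, 1/M."""
        return 1.0 / self.Kd


@dataclass(frozen=True)
class TitrationDesign:
    """Geometry and schedule of one ITC titration.

    V0: active cell volume (L); M0: initial cell concentration (M);
    X0: syringe concentration (M); inj_volumes: per-injection volumes (L).
    """

    V0: float
    M0: float
    X0: float
    inj_volumes: tuple[float, ...]
    T: float = 298.15

    def __post_init__(self) -> None:
        if min(self.V0, self.M0, self.X0) <= 0:
            raise ValueError("V0, M0 and X0 must be positive")
        if len(self.inj_volumes) < 2:
            raise ValueError("at least two injections required")
        if any(v <= 0 for v in self.inj_volumes):
            raise ValueError("injection volumes must be positive")
        object.__setattr__(self, "inj_volumes", tuple(self.inj_volumes))

    @property
    def n_injections(self) -> int:
        return len(self.inj_volumes)

    @property
    def cumulative_volume(self) -> np.ndarray:
        """Cumulative injected volume after each injection (L)."""
        return np.cumsum(self.inj_volumes)

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Effective total cell concentrations (Mt_i, Xt_i) after each
        injection under the displacement dilution approximation."""
        d = self.cumulative_volume
        r = d / (2.0 * self.V0)
        Mt = self.M0 * (1.0 - r) / (1.0 + r)
        Xt = self.X0 * (d / self.V0) / (1.0 + r)
        return Mt, Xt

    @property
    def molar_ratio(self) -> np.ndarray:
        Mt, Xt = self.totals()
        return Xt / Mt


def standard_design(
    M0: float = 80e-6,
    X0: float = 800e-6,
    V0: float = 185e-6,
    n_inj: int = 22,
    inj_volume: float = 2e-6,
    T: float = 298.15,
) -> TitrationDesign:
    """Canonical titration layout used throughout: 22 x 2 ul injections of
    peptide into a 185 ul cell at 25 C, cell/syringe concentrations inside
    the 50-180 / 400-1800 uM working ranges."""
    return TitrationDesign(V0=V0, M0=M0, X0=X0, inj_volumes=(inj_volume,) * n_inj, T=T)


@dataclass(frozen=True)
class Isotherm:
    """An ITC experiment: a design plus integrated per-injection heats (uJ)."""

    design: TitrationDesign
    heats: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.heats) != self.design.n_injections:
            raise ValueError(
                f"{len(self.heats)} heats for {self.design.n_injections} injections"
            )
        object.__setattr__(self, "heats", tuple(float(h) for h in self.heats))

    @property
    def molar_ratio(self) -> np.ndarray:
        return self.design.molar_ratio

    def normalized_heats(self) -> np.ndarray:
        """Heat per mole of injectant, kJ/mol (for plotting/initialisation)."""
        moles = np.asarray(self.design.inj_volumes) * self.design.X0
        return np.asarray(self.heats) * 1e-9 / moles


@dataclass(frozen=True)
class FitResult:
    params: ThermodynamicParameters
    param_uncertainties: dict[str, float]
    residual_rms: float
    converged: bool
    c_value: float
    weak_binding: bool
    message: str = ""


def solve_bound_concentration(Mt: float, Xt: float, Kd: float, n: float = 1.0) -> float:
    """Bound-complex concentration [MX] (M) at 1:1 mass-action equilibrium
    with site concentration ``n * Mt``.

    Root of [MX]^2 - b [MX] + n Mt Xt = 0 with b = n Mt + Xt + Kd, taking
    the physical (smaller) branch; 0 <= [MX] <= min(n Mt, Xt).
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if Mt < 0 or Xt < 0 or n < 0:
        raise ValueError("concentrations and n must be non-negative")
    if Mt == 0 or Xt == 0 or n == 0:
        return 0.0
    b = n * Mt + Xt + Kd
    disc = b * b - 4.0 * n * Mt * Xt
    if disc < -1e-12:
        raise ArithmeticError(f"negative discriminant {disc}")
    disc = max(disc, 0.0)
    # subtraction b - sqrt(disc) cancels badly for weak binding; rewrite via
    # the conjugate so the small root is computed stably
    root = 2.0 * n * Mt * Xt / (b + math.sqrt(disc))
    return min(root, n * Mt, Xt)


def predict_injection_heats(
    truth: ThermodynamicParameters, design: TitrationDesign
) -> np.ndarray:
    """Per-injection heats (uJ) for a single-site isotherm.

    Cumulative heat Q_i = dH * V0 * [MX]_i (converted kJ -> uJ); injection
    heats carry the displacement correction described in the module docstring.
    """
    if abs(truth.T - design.T) > 1e-9:
        raise ValueError(
            f"temperature mismatch: truth {truth.T} K vs design {design.T} K"
        )
    Mt, Xt = design.totals()
    mx = np.array(
        [solve_bound_concentration(m, x, truth.Kd, truth.n) for m, x in zip(Mt, Xt)]
    )
    Q = truth.dH * design.V0 * mx * 1e9  # uJ
    Qprev = np.concatenate([[0.0], Q[:-1]])
    v = np.asarray(design.inj_volumes)
    return Q - Qprev + (v / design.V0) * (Q + Qprev) / 2.0


def subtract_blank(sample: Isotherm, blank: "Isotherm | float") -> Isotherm:
    """Subtract the heat of ligand dilution (a blank titration into buffer,
    or its per-injection mean) from a sample isotherm."""
    heats = np.asarray(sample.heats)
    if isinstance(blank, Isotherm):
        if blank.design.n_injections != sample.design.n_injections:
            raise ValueError(
                "blank and sample injection counts differ; pass the blank's "
                "mean heat instead"
            )
        corrected = heats - np.asarray(blank.heats)
    else:
        corrected = heats - float(blank)
    return replace(sample, heats=tuple(corrected))


def _initial_guess(iso: Isotherm) -> tuple[float, float, float]:
    """Heuristic start: dH from the mean of the first three normalized heats,
    Kd from the molar ratio at the half-height of the heat curve, n = 1."""
    q_norm = iso.normalized_heats()
    dH0 = float(np.mean(q_norm[:3]))
    if dH0 == 0.0:
        dH0 = -1.0
    ratio = iso.molar_ratio
    cum = np.cumsum(iso.heats)
    half = cum[-1] / 2.0
    idx = int(np.argmin(np.abs(cum - half)))
    r_half = float(ratio[idx])
    # at the equivalence point r ~ n; curve steepness there encodes c = M0/Kd.
    # A mid-range c is a safe start for the local optimiser.
    Kd0 = iso.design.M0 * max(abs(r_half - 1.0), 0.02)
    Kd0 = min(max(Kd0, 1e-12), 1.0)
    return Kd0, dH0, 1.0


def fit_independent_model(
    iso: Isotherm,
    free_n: bool = True,
    init: tuple[float, float, float] | None = None,
) -> FitResult:
    """Least-squares fit of (Kd, dH, n) to per-injection heats.

    Parameters
    ----------
    iso : the blank-corrected isotherm.
    free_n : fit the stoichiometric coefficient; when False n is fixed at 1.
    init : optional (Kd, dH, n) starting point.

    Kd is optimised on a log scale within [1e-12, 1] M; |dH| <= 500 kJ/mol;
    n in [0.1, 10].  Standard errors come from the Jacobian-based covariance
    at the optimum.  Fits with c = n M0 / Kd < 1 are flagged as weak-binding
    (too little curvature to pin down Kd, the regime seen for the weakest
    reader-domain mutants).
    """
    design = iso.design
    if design.n_injections < 6:
        raise ValueError("need at least 6 injections to fit three parameters")
    q_obs = np.asarray(iso.heats)
    Kd0, dH0, n0 = init if init is not None else _initial_guess(iso)

    def model(theta: np.ndarray) -> np.ndarray:
        logKd, dH, n = theta
        p = ThermodynamicParameters(Kd=math.exp(logKd), dH=dH, n=n, T=design.T)
        return predict_injection_heats(p, design)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - q_obs

    lo = [math.log(1e-12), -500.0, 0.1]
    hi = [0.0, 500.0, 10.0]
    x0 = [math.log(min(max(Kd0, 1e-12), 1.0)), dH0, n0]
    if not free_n:
        lo[2], hi[2] = 1.0 - 1e-12, 1.0 + 1e-12
        x0[2] = 1.0
    sol = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    logKd, dH, n = sol.x
    Kd = math.exp(logKd)
    params = ThermodynamicParameters(Kd=Kd, dH=dH, n=n, T=design.T)
    resid = sol.fun
    rms = float(np.sqrt(np.mean(resid**2)))
    dof = max(len(q_obs) - (3 if free_n else 2), 1)

    # covariance from J^T J; propagate log Kd -> Kd
    se = {"Kd": math.nan, "dH": math.nan, "n": math.nan}
    converged = bool(sol.success)
    try:
        J = sol.jac
        cov = np.linalg.inv(J.T @ J) * (resid @ resid) / dof
        se["Kd"] = float(math.sqrt(max(cov[0, 0], 0.0)) * Kd)
        se["dH"] = float(math.sqrt(max(cov[1, 1], 0.0)))
        se["n"] = float(math.sqrt(max(cov[2, 2], 0.0))) if free_n else 0.0
    except np.linalg.LinAlgError:
        converged = False
    if not free_n:
        se.pop("n")

    c_value = n * design.M0 / Kd
    weak = c_value < 1.0
    signal = float(np.max(np.abs(q_obs)))
    msg = ""
    if weak:
        msg = "weak-binding regime (c < 1), parameters unreliable"
    if signal == 0.0 or abs(dH) * design.V0 * design.M0 * 1e9 < 10 * rms + 1e-12:
        converged = False
        msg = msg or "no usable heat signal"
    if not sol.success:
        msg = msg or f"optimizer did not converge: {sol.message}"
    return FitResult(
        params=params,
        param_uncertainties=se,
        residual_rms=rms,
        converged=converged,
        c_value=float(c_value),
        weak_binding=weak,
        message=msg,
    )


def compare_groups_ttest(groupA, groupB) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test with pooled variance.

    Degenerate inputs follow the replicate-comparison convention: zero pooled
    variance with equal means gives p = 1, with unequal means p = 0.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two replicates")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    dmean = float(np.mean(a) - np.mean(b))
    if sp2 == 0.0:
        return (0.0, 1.0) if dmean == 0.0 else (math.inf, 0.0)
    t = dmean / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
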