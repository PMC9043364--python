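import numpy as np
import pytest
from scipy.optimize import brentq

from cwbind import thermo

# Seven reported binding systems (construct:ligand) used for round-trip and
# self-consistency checks: (Kd M, dH kJ/mol, n, dS J/(mol K)).
PRINTED_SYSTEMS = {
    "WT:me1": (1.3e-6, -89.0, 1.0, -192.0),
    "WT:me2": (4.6e-6, -84.0, 1.0, -178.0),
    "WT:me3": (14.2e-6, -60.0, 1.0, -109.0),
    "L919A:me1": (12.2e-6, -77.0, 0.87, -164.0),
    "D870A:me1": (1.4e-6, -79.0, 1.0, -153.0),
    "D870A:me2": (7.5e-6, -93.0, 1.0, -215.0),
    "D870A:me3": (18.5e-6, -57.0, 1.0, -102.0),
}

# Reported melting temperatures (degC) of wild type and mutants +- ligand.
PRINTED_TM = {
    "WT": 67.3,
    "WT+me1": 71.4,
    "WT+me2": 71.6,
    "WT+me3": 64.9,
    "L919A": 56.9,
    "L919A+me1": 46.7,
}


def mx_bisection(Mt: float, Xt: float, Kd: float, n: float = 1.0) -> float:
    """Independent oracle: bound concentration by bracketed root-finding on
    the mass-action equation (n Mt - x)(Xt - x) = Kd x."""
    if Mt == 0 or Xt == 0 or n == 0:
        return 0.0
    f = lambda x: (n * Mt - x) * (Xt - x) - Kd * x
    return brentq(f, 0.0, min(n * Mt, Xt), xtol=1e-18, rtol=1e-15)


@pytest.fixture
def design() -> thermo.TitrationDesign:
    """Canonical 22 x 2 ul titration: 80 uM cell, 800 uM syringe, 185 ul."""
    return thermo.standard_design()


@pytest.fixture
def wt_me1_truth() -> thermo.ThermodynamicParameters:
    return thermo.ThermodynamicParameters(Kd=1.3e-6, dH=-89.0, n=1.0)


def noise_free_isotherm(Kd, dH, n, design=None) -> thermo.Isotherm:
    if design is None:
        design = thermo.standard_design()
    truth = thermo.ThermodynamicParameters(Kd=Kd, dH=dH, n=n, T=design.T)
    q = thermo.predict_injection_heats(truth, design)
    return thermo.Isotherm(design=design, heats=tuple(q))
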