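"""Synthetic instrument output with controlled ground truth.

Every generator is a pure function of its parameters and seed, and its
output round-trips through the corresponding analysis module, so the whole
pipeline is testable without instrument data or downloads.  Defaults mirror
the study conditions the analysis modules target: 22 x 2 ul titrations of
0.4-1.8 mM peptide into 50-180 uM protein, 5-90 degC melts read out as the
I328/I352 ratio, ~60-peak amide fingerprints, the standard T1/T2 delay
schedules, and idealized indole ring pairs at a designed opening angle.
"""

from __future__ import annotations

import math

import numpy as np

from .csp import ALPHA_N, Peak, PeakList
from .geometry import (
    INDOLE_TEMPLATE_2D,
    RING_ATOM_NAMES,
    AtomRecord,
    StructureModel,
    write_pdb,
)
from .melt import MeltCurve, SpectrumSeries, logistic4
from .relax import T1_DELAYS_S, DecaySeries
from .thermo import (
    Isotherm,
    ThermodynamicParameters,
    TitrationDesign,
    predict_injection_heats,
    standard_design,
)

__all__ = [
    "gen_isotherm",
    "gen_melt",
    "gen_fingerprint",
    "gen_relaxation_noe",
    "gen_relaxation_decay",
    "gen_ringpair",
]


def gen_isotherm(
    truth: ThermodynamicParameters,
    design: TitrationDesign | None = None,
    noise_sigma: float = 2.0,
    seed: int = 0,
    blank_heat: float = -1.0,
) -> tuple[Isotherm, Isotherm]:
    """Simulated ITC run: (sample, blank) isotherms.

    Heats are the single-site forward model plus additive Gaussian noise of
    ``noise_sigma`` uJ; the blank is a constant peptide-dilution heat with
    the same noise.  The default 2 uJ noise reproduces replicate K_d scatter
    of roughly a quarter of K_d over triplicates, matching the spread of
    the replicate experiments these simulations emulate.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if design is None:
        design = standard_design()
    rng = np.random.default_rng(seed)
    q = predict_injection_heats(truth, design)
    sample = q + blank_heat + rng.normal(0.0, noise_sigma, len(q))
    blank = np.full(len(q), blank_heat) + rng.normal(0.0, noise_sigma, len(q))
    return (
        Isotherm(design=design, heats=tuple(sample)),
        Isotherm(design=design, heats=tuple(blank)),
    )


def gen_melt(
    y0: float = 1.20,
    a: float = -0.45,
    b: float = 0.35,
    x0: float = 67.3,
    schedule: np.ndarray | None = None,
    spectral: bool = False,
    noise_sigma: float = 0.0,
    seed: int = 0,
    replicate_id: str = "",
) -> "MeltCurve | SpectrumSeries":
    """Two-state melting data with a logistic I328/I352 ratio.

    In curve mode the ratio follows the four-parameter logistic exactly
    (plus optional Gaussian noise).  In spectral mode two log-normal-shaped
    emission bands peaking near 330 and 355 nm (native/denatured basis
    spectra) are mixed by the logistic folded fraction so that the
    328/352 ratio reproduces the same target curve.
    """
    t = np.arange(5.0, 90.0 + 1e-9, 2.5) if schedule is None else np.asarray(schedule, float)
    if t.min() < 0 or t.max() > 100:
        raise ValueError("temperature schedule must lie within [0, 100] degC")
    rng = np.random.default_rng(seed)
    ratio = logistic4(t, y0, a, b, x0)
    if not spectral:
        ratio = ratio + rng.normal(0.0, noise_sigma, len(t))
        return MeltCurve(t, ratio, replicate_id)

    lam = np.arange(310.0, 410.0 + 1e-9, 1.0)

    def band(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * (np.log(lam / center) / width) ** 2)

    native = band(330.0, 0.045)
    denat = band(355.0, 0.050)
    i328, i352 = int(np.argmin(np.abs(lam - 328))), int(np.argmin(np.abs(lam - 352)))
    rn = native[i328] / native[i352]
    rd = denat[i328] / denat[i352]
    # mixing weight w on the denominator scale reproduces ratio exactly:
    # ratio = (w*native + (1-w)*denat)[328] / (w*native + (1-w)*denat)[352]
    w = (ratio - rd) * denat[i352] / (
        (ratio - rd) * denat[i352] + (rn - ratio) * native[i352]
    )
    if np.any(w < -1e-9) or np.any(w > 1 + 1e-9):
        raise ValueError("target ratio outside the basis-spectra ratio range")
    inten = np.outer(w, native) + np.outer(1.0 - w, denat)
    inten = inten * 1000.0
    inten = inten + rng.normal(0.0, noise_sigma, inten.shape)
    return SpectrumSeries(t, lam, inten, replicate_id)


def gen_fingerprint(
    n_peaks: int = 60,
    shifted_fraction: float = 0.0,
    displacement_ppm: float = 0.3,
    jitter_ppm: float = 0.01,
    seed: int = 0,
    alphaN: float = ALPHA_N,
) -> tuple[PeakList, PeakList, list[bool]]:
    """Reference/query fingerprint pair with a designed shifted fraction.

    Peaks are placed uniformly over the amide window (1H 6.5-10.5 ppm,
    15N 105-135 ppm) with a minimum mutual scaled separation of
    2 x displacement so that nearest-neighbour matching is unambiguous.
    Exactly ``round(n_peaks * shifted_fraction)`` peaks are moved by
    ``displacement_ppm`` in the alphaN-scaled metric along a random
    direction; the rest are jittered by ``jitter_ppm``.  Returns
    (reference, query, truth labels) with labels True for shifted peaks.
    """
    if not 0.0 <= shifted_fraction <= 1.0:
        raise ValueError("shifted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    min_sep = 2.0 * displacement_ppm
    h_lo, h_hi, n_lo, n_hi = 6.5, 10.5, 105.0, 135.0
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n_peaks and attempts <= 200 * n_peaks:
        attempts += 1
        h = rng.uniform(h_lo, h_hi)
        n = rng.uniform(n_lo, n_hi)
        if all(
            math.hypot(h - h2, alphaN * (n - n2)) > min_sep for h2, n2 in pts
        ):
            pts.append((h, n))
    if len(pts) < n_peaks:
        # near the packing limit random sequential placement stalls; fall
        # back to a lightly jittered hexagonal lattice in the scaled metric
        # (real fingerprints at this density are likewise quasi-regular)
        s = 1.02 * min_sep if min_sep > 0 else 0.1
        jit = 0.45 * (s - min_sep)
        sites = []
        y, row = 0.0, 0
        while y <= alphaN * (n_hi - n_lo):
            x = (s / 2.0 if row % 2 else 0.0)
            while x <= (h_hi - h_lo):
                sites.append((h_lo + x, n_lo + y / alphaN))
                x += s
            y += s * math.sqrt(3.0) / 2.0
            row += 1
        if len(sites) < n_peaks:
            raise ValueError(
                f"cannot pack {n_peaks} peaks with scaled separation {min_sep} ppm"
            )
        idx = rng.choice(len(sites), size=n_peaks, replace=False)
        pts = [
            (
                sites[i][0] + rng.uniform(-jit, jit) / math.sqrt(2.0),
                sites[i][1] + rng.uniform(-jit, jit) / (alphaN * math.sqrt(2.0)),
            )
            for i in idx
        ]

    n_shift = round(n_peaks * shifted_fraction)
    shifted_idx = set(rng.choice(n_peaks, size=n_shift, replace=False).tolist())
    ref, qry, labels = [], [], []
    for i, (h, n) in enumerate(pts):
        ref.append(Peak(id=i + 1, dH=h, dN=n, assigned=False))
        mag = displacement_ppm if i in shifted_idx else jitter_ppm
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dh = mag * math.cos(theta)
        dn = mag * math.sin(theta) / alphaN  # scaled-metric displacement
        qry.append(Peak(id=i + 1, dH=h + dh, dN=n + dn, assigned=False))
        labels.append(i in shifted_idx)
    return PeakList(tuple(ref)), PeakList(tuple(qry)), labels


def gen_relaxation_noe(
    noe_profile: dict,
    noise: float = 0.0,
    seed: int = 0,
) -> list[tuple[int | str, float, float]]:
    """(id, I_sat, I_ref) rows with I_ref = 1 and I_sat = noe, under
    multiplicative Gaussian noise of relative scale ``noise``."""
    rng = np.random.default_rng(seed)
    rows = []
    for rid, noe in noe_profile.items():
        i_ref = 1.0 * (1.0 + rng.normal(0.0, noise))
        i_sat = noe * (1.0 + rng.normal(0.0, noise))
        rows.append((rid, i_sat, i_ref))
    return rows


def gen_relaxation_decay(
    T_relax: float,
    I0: float = 100.0,
    delays=T1_DELAYS_S,
    noise: float = 0.0,
    seed: int = 0,
    id: int | str = "",
) -> DecaySeries:
    """Mono-exponential decay series on a delay schedule, with
    multiplicative Gaussian noise of relative scale ``noise``."""
    rng = np.random.default_rng(seed)
    t = np.asarray(delays, float)
    y = I0 * np.exp(-t / T_relax) * (1.0 + rng.normal(0.0, noise, len(t)))
    return DecaySeries(id=id, delays=tuple(t), intensities=tuple(y))


def gen_ringpair(
    angle_deg: float,
    separation_A: float = 8.0,
    seed: int = 0,
) -> StructureModel:
    """Two idealized planar indole rings at a designed inter-plane angle.

    Ring 1 lies in the z = 0 plane; ring 2 is the same template rotated by
    ``angle_deg`` about the shared in-plane x axis and displaced by
    ``separation_A`` along x.  Both are emitted as TRP residues 1 and 2 of
    chain A; the seed only randomises a rigid-body orientation applied to
    the whole model (the designed angle is rotation-invariant).
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError("angle_deg must be in [0, 180]")
    rng = np.random.default_rng(seed)
    phi = math.radians(angle_deg)
    rot_x = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(phi), -math.sin(phi)],
            [0.0, math.sin(phi), math.cos(phi)],
        ]
    )
    # random global rigid motion (proper rotation from QR with positive diag)
    Q, Rm = np.linalg.qr(rng.normal(size=(3, 3)))
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    shift = rng.normal(0.0, 5.0, 3)

    atoms = []
    serial = 1
    for res_seq, transform in ((1, None), (2, rot_x)):
        for name in RING_ATOM_NAMES:
            x2, y2 = INDOLE_TEMPLATE_2D[name]
            p = np.array([x2, y2, 0.0])
            if transform is not None:
                p = transform @ p + np.array([separation_A, 0.0, 0.0])
            p = Q @ p + shift
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    alt_loc="",
                    res_name="TRP",
                    chain_id="A",
                    res_seq=res_seq,
                    insertion_code="",
                    x=float(p[0]),
                    y=float(p[1]),
                    z=float(p[2]),
                    element="N" if name == "NE1" else "C",
                )
            )
            serial += 1
    return StructureModel(atoms=tuple(atoms), model_number=1)


def ringpair_pdb(angle_deg: float, separation_A: float = 8.0, seed: int = 0) -> str:
    """PDB text for :func:`gen_ringpair` (round-trips through read_pdb)."""
    return write_pdb(gen_ringpair(angle_deg, separation_A, seed))
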