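"""Tryptophan ring-plane geometry of reader-domain binding pockets.

Methylated-lysine readers sandwich the ligand between aromatic side chains;
the opening angle between the two tryptophan indole planes characterises the
pocket.  For each Trp the nine ring atoms (CG, CD1, NE1, CE2, CD2, CE3, CZ2,
CZ3, CH2) are fitted with a total-least-squares plane, and the pocket angle
is the angle between the two plane normals.  Two conventions are reported:

* ``angle_unsigned`` — arccos(|n1.n2|), in [0, 90] degrees; independent of
  any normal-sign choice and the primary output.
* ``angle_oriented`` — arccos(n1.n2) in [0, 180] with each fitted normal
  signed to agree with the Newell-method normal of the canonical ring
  perimeter CG-CD1-NE1-CE2-CZ2-CH2-CZ3-CE3-CD2, making the orientation
  deterministic.

PDB parsing is delegated to gemmi; only fixed-column PDB text is supported,
alternate locations other than blank/'A' are dropped, and for multi-model
(NMR) entries model 1 is the headline with the per-model spread reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "RingAtoms",
    "PlaneFit",
    "PocketAngle",
    "RING_ATOM_NAMES",
    "RING_PERIMETER",
    "read_pdb",
    "extract_trp_ring",
    "fit_plane",
    "newell_normal",
    "interplane_angle",
    "pocket_angle",
    "write_pdb",
]

RING_ATOM_NAMES = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")
# canonical perimeter winding used for the deterministic oriented normal
RING_PERIMETER = ("CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2")

# idealized planar indole ring, Angstrom, centroid at origin (in-plane 2D
# coordinates; aromatic bond lengths ~1.37-1.41 A)
INDOLE_TEMPLATE_2D = {
    "CG": (-1.6612, -1.1106),
    "CD1": (-2.4120, +0.0483),
    "NE1": (-1.5554, +1.1160),
    "CE2": (-0.2512, +0.6807),
    "CD2": (-0.2856, -0.7140),
    "CE3": (+0.9372, -1.4162),
    "CZ3": (+2.1419, -0.7033),
    "CH2": (+2.1423, +0.6894),
    "CZ2": (+0.9442, +1.4098),
}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    element: str

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureModel:
    atoms: tuple[AtomRecord, ...]
    model_number: int = 1

    def residue_atoms(self, chain: str, res_seq: int) -> list[AtomRecord]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain and a.res_seq == res_seq
        ]


@dataclass(frozen=True)
class RingAtoms:
    """The nine indole ring atoms of one tryptophan, name -> xyz (A)."""

    residue_id: str
    coords: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [n for n in RING_ATOM_NAMES if n not in self.coords]
        if missing:
            raise ValueError(f"{self.residue_id}: missing ring atoms {missing}")
        pts = self.array()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        off = d[np.triu_indices(9, 1)]
        if off.min() < 1.2 or off.max() > 5.5:
            raise ValueError(
                f"{self.residue_id}: ring atom distances outside [1.2, 5.5] A "
                f"(min {off.min():.2f}, max {off.max():.2f})"
            )

    def array(self, order=RING_ATOM_NAMES) -> np.ndarray:
        return np.array([self.coords[n] for n in order])


@dataclass(frozen=True)
class PlaneFit:
    centroid: np.ndarray
    unit_normal: np.ndarray
    rms_out_of_plane: float


@dataclass(frozen=True)
class PocketAngle:
    structure_id: str
    chain: str
    residue_pair: tuple[int, int]
    model_number: int
    angle_unsigned: float  # deg, [0, 90]
    angle_oriented: float  # deg, [0, 180]
    rms1: float
    rms2: float


def read_pdb(text: str) -> list[StructureModel]:
    """Parse fixed-column PDB text into one StructureModel per MODEL block.

    Alternate locations other than blank or 'A' are discarded.  Hydrogens
    are retained (downstream ring extraction selects heavy atoms by name).
    """
    st = gemmi.read_pdb_string(text)
    models = []
    for model in st:
        atoms = []
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            atom_name=atom.name,
                            alt_loc="" if atom.altloc in ("", "\x00") else atom.altloc,
                            res_name=res.name,
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            insertion_code=(res.seqid.icode or "").strip(),
                            x=atom.pos.x,
                            y=atom.pos.y,
                            z=atom.pos.z,
                            element=atom.element.name,
                        )
                    )
        models.append(StructureModel(atoms=tuple(atoms), model_number=model.num))
    if not models or not any(m.atoms for m in models):
        raise ValueError("no ATOM/HETATM records found")
    return models


def extract_trp_ring(
    model: StructureModel, chain: str, res_seq: int, include_cb: bool = False
) -> RingAtoms:
    """Pull the nine indole ring atoms of TRP ``res_seq`` in ``chain``.

    ``include_cb`` adds the sp3 CB atom to the returned set (sensitivity
    check only; CB sits off the aromatic plane).
    """
    atoms = model.residue_atoms(chain, res_seq)
    if not atoms:
        raise ValueError(f"residue {chain}/{res_seq} not found")
    res_name = atoms[0].res_name
    if res_name != "TRP":
        raise ValueError(f"residue {chain}/{res_seq} is {res_name}, not a tryptophan")
    wanted = RING_ATOM_NAMES + (("CB",) if include_cb else ())
    coords = {a.atom_name: a.coord for a in atoms if a.atom_name in wanted}
    if include_cb and "CB" not in coords:
        raise ValueError(f"residue {chain}/{res_seq}: CB requested but absent")
    ring = RingAtoms(residue_id=f"{chain}/TRP{res_seq}", coords={
        n: coords[n] for n in RING_ATOM_NAMES if n in coords
    })
    if include_cb:
        # bypass the 9-atom invariant check by carrying CB alongside
        object.__setattr__(ring, "coords", {**ring.coords, "CB": coords["CB"]})
    return ring


def fit_plane(ring: RingAtoms, include_cb: bool = False) -> PlaneFit:
    """Total-least-squares plane through the ring atoms.

    The normal is the singular direction of least coordinate variance; the
    fitted plane minimises the sum of squared out-of-plane distances over
    all planes (through the centroid of the points).
    """
    names = list(RING_ATOM_NAMES) + (["CB"] if include_cb and "CB" in ring.coords else [])
    pts = np.array([ring.coords[n] for n in names])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise ValueError(f"{ring.residue_id}: ring atoms are collinear/degenerate")
    normal = Vt[2]
    rms = float(math.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(centroid=centroid, unit_normal=normal / np.linalg.norm(normal), rms_out_of_plane=rms)


def newell_normal(ring: RingAtoms) -> np.ndarray:
    """Unit normal of the ring polygon by the Newell method over the
    canonical perimeter winding; sign is deterministic."""
    pts = ring.array(order=RING_PERIMETER)
    n = np.zeros(3)
    for i in range(len(pts)):
        p, q = pts[i], pts[(i + 1) % len(pts)]
        n += np.cross(p, q)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError(f"{ring.residue_id}: degenerate perimeter")
    return n / norm


def interplane_angle(
    p1: PlaneFit,
    p2: PlaneFit,
    oriented_normals: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """(angle_unsigned, angle_oriented) in degrees between two fitted planes.

    The unsigned angle uses |n1.n2| and lives in [0, 90].  The oriented
    angle needs a deterministic sign for each normal: pass the Newell
    normals of the two rings and each fitted normal is flipped to agree
    with its reference before taking arccos(n1.n2) in [0, 180].
    """
    n1, n2 = p1.unit_normal.copy(), p2.unit_normal.copy()
    for n in (n1, n2):
        if np.linalg.norm(n) < 1e-12:
            raise ValueError("zero-length plane normal")
    if oriented_normals is not None:
        r1, r2 = oriented_normals
        if np.dot(n1, r1) < 0:
            n1 = -n1
        if np.dot(n2, r2) < 0:
            n2 = -n2
    dot = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    oriented = math.degrees(math.acos(dot))
    unsigned = math.degrees(math.acos(min(abs(dot), 1.0)))
    return unsigned, oriented


def _angle_for_model(
    model: StructureModel, chain: str, res_pair: tuple[int, int],
    structure_id: str, include_cb: bool,
) -> PocketAngle:
    rings = [extract_trp_ring(model, chain, r, include_cb) for r in res_pair]
    fits = [fit_plane(rg, include_cb) for rg in rings]
    unsigned, oriented = interplane_angle(
        fits[0], fits[1], oriented_normals=(newell_normal(rings[0]), newell_normal(rings[1]))
    )
    return PocketAngle(
        structure_id=structure_id,
        chain=chain,
        residue_pair=tuple(res_pair),
        model_number=model.model_number,
        angle_unsigned=unsigned,
        angle_oriented=oriented,
        rms1=fits[0].rms_out_of_plane,
        rms2=fits[1].rms_out_of_plane,
    )


def pocket_angle(
    structure: "list[StructureModel] | StructureModel | str",
    res_pair: tuple[int, int],
    chain: str = "A",
    structure_id: str = "",
    include_cb: bool = False,
) -> tuple[PocketAngle, list[PocketAngle]]:
    """Binding-pocket angle between two tryptophans of one structure.

    ``structure`` may be PDB text, a single model, or a model list; for NMR
    ensembles every model is evaluated, the first model is the headline
    value, and the full per-model list is returned alongside it.
    """
    if isinstance(structure, str):
        models = read_pdb(structure)
    elif isinstance(structure, StructureModel):
        models = [structure]
    else:
        models = list(structure)
    per_model = [
        _angle_for_model(m, chain, res_pair, structure_id, include_cb) for m in models
    ]
    return per_model[0], per_model


def write_pdb(model: StructureModel) -> str:
    """Serialize a StructureModel to fixed-column PDB text."""
    lines = []
    for a in model.atoms:
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {a.serial:>5d} {name}{a.alt_loc or ' '}{a.res_name:<3s} "
            f"{a.chain_id}{a.res_seq:>4d}{a.insertion_code or ' '}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
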