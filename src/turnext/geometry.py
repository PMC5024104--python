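"""Backbone geometry: PDB reading, dihedral angles, C-alpha distances.

Every downstream analysis consumes the quantities computed here: the phi/psi
dihedrals of the two central residues of a candidate turn, the Calpha(i) -
Calpha(i+3) distance that gates turn detection (< 7 A), and a chain
continuity check that rejects windows spanning missing density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np

from ._angles import wrap_angle

__all__ = [
    "ResidueBackbone",
    "BackboneDihedrals",
    "MissingAtomError",
    "read_backbone",
    "compute_dihedrals",
    "dihedral",
    "ca_distance",
    "check_continuity",
]

#: Continuity bounds for consecutive Calpha-Calpha distances (Angstrom).
#: Admits trans (~3.8 A) and cis (~2.9 A) peptides, rejects chain breaks.
CA_CA_MIN = 2.7
CA_CA_MAX = 4.3

BACKBONE_ATOMS = ("N", "CA", "C")


class MissingAtomError(ValueError):
    """A required backbone atom is absent from a residue."""


@dataclass
class ResidueBackbone:
    """Backbone atom coordinates and identity of one residue.

    ``residue_number``/``insertion_code`` carry the author numbering from the
    input file; positional indices used internally are 0-based and never
    exposed.  A residue missing any of N, CA, C is *incomplete* and is
    excluded from turn windows.
    """

    chain_id: str
    residue_number: int
    amino_acid: str
    coords_N: Optional[np.ndarray] = None
    coords_CA: Optional[np.ndarray] = None
    coords_C: Optional[np.ndarray] = None
    coords_O: Optional[np.ndarray] = None
    insertion_code: str = ""

    @property
    def is_complete(self) -> bool:
        return (
            self.coords_N is not None
            and self.coords_CA is not None
            and self.coords_C is not None
        )

    def atom(self, name: str) -> Optional[np.ndarray]:
        return getattr(self, f"coords_{name}")

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"


@dataclass
class BackboneDihedrals:
    """phi/psi/omega of one residue, degrees in (-180, 180], or None.

    phi and omega are undefined at a chain start (no preceding C/CA), psi at
    a chain end (no following N); undefined angles are ``None``, never a
    sentinel value.
    """

    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken alphabetically by altloc id
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def read_backbone(path, format: str = "pdb") -> list[list[ResidueBackbone]]:
    """Read backbone coordinates from a structure file.

    Returns one list of :class:`ResidueBackbone` per chain of the first
    model, in file order.  Altloc conformers are resolved to the highest
    occupancy one; hetero records are kept only when they carry a full
    backbone within the polymer chain (e.g. modified residues).

    Raises ``ValueError`` if the file cannot be parsed.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise ValueError(f"cannot read structure file {path}: {exc}") from None
    if len(structure) == 0:
        raise ValueError(f"no model found in {path}")

    chains: list[list[ResidueBackbone]] = []
    for chain in structure[0]:
        residues: list[ResidueBackbone] = []
        for res in chain:
            rec = ResidueBackbone(
                chain_id=chain.name,
                residue_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                amino_acid=res.name,
            )
            for name in ("N", "CA", "C", "O"):
                group = [a for a in res if a.name == name]
                if group:
                    atom = _pick_altloc(group)
                    setattr(rec, f"coords_{name}",
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
            if res.het_flag == "H" and not rec.is_complete:
                continue  # ligands/waters; keep modified residues in-chain
            if any(rec.atom(n) is not None for n in ("N", "CA", "C", "O")):
                residues.append(rec)
        if residues:
            chains.append(residues)
    return chains


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of four points, degrees in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_angle(-np.degrees(np.arctan2(y, x)))


def compute_dihedrals(chain: Sequence[ResidueBackbone]) -> list[BackboneDihedrals]:
    """phi/psi/omega for every residue of an ordered chain.

    phi_i uses C(i-1), N(i), CA(i), C(i); psi_i uses N(i), CA(i), C(i),
    N(i+1); omega_i uses CA(i-1), C(i-1), N(i), CA(i).  Any missing atom in
    a quadruple leaves that angle undefined.
    """
    out: list[BackboneDihedrals] = []
    for i, res in enumerate(chain):
        prev = chain[i - 1] if i > 0 else None
        nxt = chain[i + 1] if i + 1 < len(chain) else None
        d = BackboneDihedrals()
        if prev is not None:
            if all(p is not None for p in
                   (prev.coords_C, res.coords_N, res.coords_CA, res.coords_C)):
                d.phi = dihedral(prev.coords_C, res.coords_N,
                                 res.coords_CA, res.coords_C)
            if all(p is not None for p in
                   (prev.coords_CA, prev.coords_C, res.coords_N, res.coords_CA)):
                d.omega = dihedral(prev.coords_CA, prev.coords_C,
                                   res.coords_N, res.coords_CA)
        if nxt is not None:
            if all(p is not None for p in
                   (res.coords_N, res.coords_CA, res.coords_C, nxt.coords_N)):
                d.psi = dihedral(res.coords_N, res.coords_CA,
                                 res.coords_C, nxt.coords_N)
        out.append(d)
    return out


def ca_distance(chain: Sequence[ResidueBackbone], i: int, j: int) -> float:
    """Euclidean Calpha-Calpha distance between residues i and j (Angstrom)."""
    a, b = chain[i].coords_CA, chain[j].coords_CA
    if a is None or b is None:
        raise MissingAtomError(
            f"CA missing for residue {chain[i].label if a is None else chain[j].label}"
        )
    return float(np.linalg.norm(a - b))


def check_continuity(chain: Sequence[ResidueBackbone], window: range) -> bool:
    """True iff the window is geometrically continuous.

    Every residue must be complete and every consecutive Calpha-Calpha
    distance must lie in [2.7, 4.3] A, which accepts both trans and
    cis peptide bonds while rejecting gaps from missing density.
    """
    idx = list(window)
    if any(not chain[i].is_complete for i in idx):
        return False
    for a, b in zip(idx, idx[1:]):
        d = ca_distance(chain, a, b)
        if not (CA_CA_MIN <= d <= CA_CA_MAX):
            return False
    return True
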