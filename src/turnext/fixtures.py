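"""Synthetic inputs: angular mixtures and toy backbones built from dihedrals.

Two generators make the whole pipeline testable without external data:

* :func:`sample_turn_quads` draws dihedral quads from a mixture of
  wrapped-normal components (optionally plus a uniform "miscellaneous"
  component), emulating a turn population with recurrent conformations
  embedded in diffuse ones.  :func:`type_iv_benchmark` is the standard
  population used for clustering validation: four well-separated sigma=10 deg
  modes of equal weight carrying half the mass, the other half uniform —
  mirroring a type-IV population in which the four recurrent types together
  represent about half of the turns and the remainder is unstructured.

* :func:`build_backbone` places backbone atoms by sequential
  internal-coordinate (NeRF) construction at ideal bond lengths and angles
  from a per-residue (phi, psi, omega) specification, so that recomputed
  dihedrals round-trip to the inputs within 0.1 deg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np

from ._angles import wrap_angle
from .geometry import ResidueBackbone
from .secondary import SSRecord
from .turns import TurnTypeDefinition, load_definitions

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "TurnDataset",
    "sample_turn_quads",
    "type_iv_benchmark",
    "BENCHMARK_CENTERS",
    "build_backbone",
    "write_toy_pdb",
    "make_turn_structure",
    "all_coil_for",
]

# ---------------------------------------------------------------------------
# angular mixtures


@dataclass(frozen=True)
class MixtureComponent:
    """One mixture component.

    kind "wrapped_normal": per-angle normal of sd ``spread`` around
    ``center``, wrapped into (-180, 180].  kind "uniform": uniform over the
    full angle space (center/spread ignored).
    """

    weight: float
    center: Optional[tuple] = None
    spread: float = 10.0
    kind: str = "wrapped_normal"

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("component weights must be positive")
        if self.kind == "wrapped_normal":
            if self.center is None or len(self.center) != 4:
                raise ValueError("wrapped_normal components need a 4-angle center")
            if self.spread <= 0:
                raise ValueError("spread must be positive")
        elif self.kind != "uniform":
            raise ValueError(f"unknown component kind: {self.kind!r}")


@dataclass
class MixtureSpec:
    components: Sequence[MixtureComponent]
    n: int
    seed: int = 0


@dataclass
class TurnDataset:
    """Sampled quads plus the generating component of each (for oracles)."""

    quads: np.ndarray            # (T, 4), wrapped
    component_labels: np.ndarray  # (T,), index into the spec's components
    spec: Optional[MixtureSpec] = None

    def __len__(self) -> int:
        return len(self.quads)


def sample_turn_quads(spec: MixtureSpec) -> TurnDataset:
    """Draw a seeded sample from the mixture; component identity recorded."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components], float)
    weights = weights / weights.sum()
    labels = rng.choice(len(spec.components), size=spec.n, p=weights)
    quads = np.empty((spec.n, 4))
    for idx, comp in enumerate(spec.components):
        mask = labels == idx
        m = int(mask.sum())
        if not m:
            continue
        if comp.kind == "uniform":
            quads[mask] = rng.uniform(-180.0, 180.0, size=(m, 4))
        else:
            quads[mask] = np.asarray(comp.center, float) + rng.normal(
                0.0, comp.spread, size=(m, 4))
    return TurnDataset(wrap_angle(quads), labels, spec)


#: Mode centers of the standard clustering benchmark: two of the extended
#: turn-type centers plus two synthetic centers, chosen pairwise
#: well-separated relative to the sigma = 10 deg component spread.
BENCHMARK_CENTERS = np.array([
    [-120.0, 130.0, 55.0, 41.0],
    [-85.0, -15.0, -125.0, 55.0],
    [60.0, 40.0, 80.0, -170.0],
    [140.0, -100.0, 170.0, -80.0],
])


def type_iv_benchmark(n: int, seed: int, sigma: float = 10.0,
                      mode_weight: float = 0.125) -> TurnDataset:
    """Benchmark type-IV-like population: 4 equal modes + uniform remainder."""
    comps = [MixtureComponent(weight=mode_weight, center=tuple(c), spread=sigma)
             for c in BENCHMARK_CENTERS]
    rest = 1.0 - 4 * mode_weight
    if rest > 0:
        comps.append(MixtureComponent(weight=rest, kind="uniform"))
    return sample_turn_quads(MixtureSpec(comps, n=n, seed=seed))


# ---------------------------------------------------------------------------
# toy backbone construction (internal coordinates, ideal geometry)

# ideal backbone geometry; self-consistent values for round-trip fixtures
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of atom d given a-b-c, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(angle_spec: Sequence[tuple], amino_acids: Sequence[str],
                   chain_id: str = "A") -> list[ResidueBackbone]:
    """Build a chain at ideal geometry from per-residue (phi, psi, omega).

    phi and omega of the first residue are unused (no preceding peptide);
    psi of the last residue only orients its carbonyl oxygen.  Recomputed
    dihedrals agree with the specification within 0.1 deg.
    """
    if len(angle_spec) != len(amino_acids):
        raise ValueError("angle_spec and amino_acids must have equal length")
    if len(angle_spec) < 1:
        raise ValueError("cannot build an empty chain")
    coords = []  # per residue: dict with N, CA, C
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for r in range(1, len(angle_spec)):
        phi, _psi, omega = angle_spec[r]
        psi_prev = angle_spec[r - 1][1]
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"],
                   BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = _place(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, omega)
        c = _place(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    chain = []
    for r, (atoms, aa) in enumerate(zip(coords, amino_acids)):
        psi = angle_spec[r][1]
        o = _place(atoms["N"], atoms["CA"], atoms["C"],
                   BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        chain.append(ResidueBackbone(
            chain_id=chain_id, residue_number=r + 1, amino_acid=aa.upper(),
            coords_N=atoms["N"], coords_CA=atoms["CA"], coords_C=atoms["C"],
            coords_O=o,
        ))
    return chain


def write_toy_pdb(chain: Sequence[ResidueBackbone], path) -> None:
    """Write a minimal single-chain PDB file readable by read_backbone."""
    if not chain:
        raise ValueError("cannot write an empty chain")
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain[0].chain_id)
    for res in chain:
        r = gemmi.Residue()
        r.name = res.amino_acid
        r.seqid = gemmi.SeqId(res.residue_number, res.insertion_code or " ")
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            pos = res.atom(name)
            if pos is None:
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 0.0
            r.add_atom(atom)
        ch.add_residue(r)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


EXTENDED_PHI_PSI = (-139.0, 135.0)  # flanking beta-strand-like geometry


def make_turn_structure(type_name: str,
                        definitions: Optional[Sequence[TurnTypeDefinition]] = None,
                        ) -> tuple[list[ResidueBackbone], list[SSRecord]]:
    """Six-residue fixture whose central quad sits at a type's canonical values.

    The turn window is residues 2..5 (author numbering), i.e. i at index 1;
    the quad lands on residues 3 and 4, flanked by extended residues.  Types
    requiring a cis-proline get PRO with omega = 0 at position i+2.  Returns
    the chain plus an all-coil secondary-structure annotation.
    """
    if definitions is None:
        definitions = load_definitions()
    by_name = {d.name: d for d in definitions}
    if type_name not in by_name:
        raise ValueError(f"unknown turn type: {type_name!r}")
    d = by_name[type_name]
    q = d.canonical
    ext = EXTENDED_PHI_PSI
    angles = [
        (ext[0], ext[1], 180.0),
        (ext[0], ext[1], 180.0),
        (q.phi1, q.psi1, 180.0),
        (q.phi2, q.psi2, 0.0 if d.requires_cis_pro_i2 else 180.0),
        (ext[0], ext[1], 180.0),
        (ext[0], ext[1], 180.0),
    ]
    aas = ["ALA"] * 6
    if d.requires_cis_pro_i2:
        aas[3] = "PRO"
    chain = build_backbone(angles, aas)
    return chain, all_coil_for(chain)


def write_toy_dssp(records: Sequence[SSRecord], path) -> None:
    """Write a minimal classic-format DSSP file readable by parse_dssp.

    Only the fields the parser consumes are populated (residue identity,
    state code); hydrogen-bond and accessibility columns are zeroed.
    ``None`` entries in ``records`` become chain-break ('!') lines.
    """
    if not records:
        raise ValueError("cannot write an empty DSSP file")
    lines = [
        "==== Secondary Structure Definition, toy fixture ====",
        "REFERENCE   synthetic annotation for testing",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"
        "    X-CA   Y-CA   Z-CA",
    ]
    for idx, rec in enumerate(records, start=1):
        row = [" "] * 115
        row[:5] = f"{idx:5d}"
        if rec is None:
            row[13] = "!"
        else:
            row[5:10] = f"{rec.residue_number:5d}"
            row[10] = rec.insertion_code or " "
            row[11] = rec.chain_id[:1]
            row[13] = rec.amino_acid[:1] if len(rec.amino_acid) == 1 else \
                {"ALA": "A", "GLY": "G", "PRO": "P"}.get(rec.amino_acid, "X")
            row[16] = rec.dssp_code
            row[34:38] = "   0"
            for start, stop, text in ((38, 45, "      0"), (46, 50, " 0.0"),
                                      (50, 56, "     0"), (57, 61, " 0.0"),
                                      (61, 67, "     0"), (68, 72, " 0.0"),
                                      (72, 78, "     0"), (79, 83, " 0.0")):
                row[start:stop] = text
            for pos in (45, 56, 67, 78):
                row[pos] = ","
            row[103:109] = f"{0.0:6.1f}"
            row[109:115] = f"{0.0:6.1f}"
        lines.append("".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def all_coil_for(chain: Sequence[ResidueBackbone]) -> list[SSRecord]:
    """Companion all-coil annotation for a synthetic chain."""
    return [SSRecord(r.chain_id, r.residue_number, r.insertion_code,
                     r.amino_acid, " ") for r in chain]
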