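"""Beta-turn detection and type assignment.

A beta-turn is a window of four consecutive residues i..i+3 whose
Calpha(i)-Calpha(i+3) distance is below 7 A, whose two central residues are
non-helical, and which is not buried inside a strand (when strand states are
present, at least one of the four residues must be coil).  The conformation
of a turn is the quad of dihedral angles (phi_{i+1}, psi_{i+1}, phi_{i+2},
psi_{i+2}).

Assignment follows the classical tolerance rule: a quad matches a type's
canonical quad when at least three wrapped absolute deviations are within
30 deg and the remaining one within 45 deg (both inclusive).  The eight
classical types are tested first (the three VI types only in the presence of
a cis-proline at i+2); a quad matching none of them is type IV, and is then
tested against the four extended types IV1-IV4 discovered by clustering the
former miscellaneous category; still no match means IV_misc.  Obsolete types
(III, III', V, V') are reported as annotations only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from ._angles import abs_delta, wrap_angle
from .geometry import BackboneDihedrals, ResidueBackbone, ca_distance, check_continuity
from .secondary import SSRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DihedralQuad",
    "TurnTypeDefinition",
    "BetaTurn",
    "load_definitions",
    "load_regions",
    "matches_definition",
    "rmsda_to_canonical",
    "assign_classical",
    "assign_extended",
    "assign_obsolete",
    "detect_turns",
    "assign_turns",
    "classify_extent",
    "label_regions",
]

#: Calpha(i)-Calpha(i+3) detection threshold (Angstrom).
MAX_CA_DISTANCE = 7.0
#: Crawford short-turn distance threshold (Angstrom).
CRAWFORD_DISTANCE = 5.7
#: Tolerance rule: at least three deviations <= TOL_MAIN, the rest <= TOL_LOOSE.
TOL_MAIN = 30.0
TOL_LOOSE = 45.0
#: Cis peptide bond: |omega| at or below this value (degrees).
CIS_OMEGA_MAX = 30.0
#: Full turn (chain reversal ~180 deg) vs half turn (~90 deg) boundary.
FULL_TURN_MIN_ANGLE = 135.0


class DihedralQuad(tuple):
    """(phi_{i+1}, psi_{i+1}, phi_{i+2}, psi_{i+2}) in degrees, (-180, 180]."""

    def __new__(cls, phi1, psi1, phi2, psi2):
        raw = (phi1, psi1, phi2, psi2)
        if any(v is None or not math.isfinite(v) for v in raw):
            raise ValueError("all four quad angles must be defined and finite")
        return super().__new__(cls, (wrap_angle(v) for v in raw))

    phi1 = property(lambda self: self[0])
    psi1 = property(lambda self: self[1])
    phi2 = property(lambda self: self[2])
    psi2 = property(lambda self: self[3])

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass(frozen=True)
class TurnTypeDefinition:
    name: str
    canonical: DihedralQuad
    requires_cis_pro_i2: bool = False
    tier: str = "classical"  # classical | extended | obsolete


@dataclass
class BetaTurn:
    """One detected (and possibly typed) beta-turn starting at residue i."""

    chain_id: str
    start_residue: int
    start_insertion_code: str
    sequence: str  # 4 one-letter codes
    quad: DihedralQuad
    ca_distance_i_i3: float
    assigned_type: Optional[str] = None
    obsolete_annotation: Optional[str] = None
    extent: Optional[str] = None  # full | half
    crawford_short: Optional[bool] = None
    region_labels: dict = field(default_factory=dict)
    start_index: int = -1  # 0-based position in the chain, internal


# ---------------------------------------------------------------------------
# configuration loading

def _parse_defs(entries, tier):
    return [
        TurnTypeDefinition(
            name=str(e["name"]),
            canonical=DihedralQuad(*e["canonical"]),
            requires_cis_pro_i2=bool(e.get("cis_pro_i2", False)),
            tier=tier,
        )
        for e in entries
    ]


def load_definitions(path=None) -> list[TurnTypeDefinition]:
    """Load turn-type definitions from YAML (bundled defaults if no path)."""
    if path is None:
        text = resources.files("turnext.data").joinpath("turn_types.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    defs: list[TurnTypeDefinition] = []
    for tier in ("classical", "extended", "obsolete"):
        defs.extend(_parse_defs(raw.get(tier, []), tier))
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate turn-type names in definitions config")
    return defs


@dataclass(frozen=True)
class RegionBox:
    name: str
    phi: tuple[float, float]  # [min, max)
    psi: tuple[float, float]  # [min, max); min > max wraps through 180

    def contains(self, phi: float, psi: float) -> bool:
        lo, hi = self.phi
        if not (lo <= phi < hi):
            return False
        lo, hi = self.psi
        if lo <= hi:
            return lo <= psi < hi
        return psi >= lo or psi < hi


def _interval_overlap(a, b):
    """Do half-open (possibly wrapped) intervals intersect?"""
    def segments(iv):
        lo, hi = iv
        if lo <= hi:
            return [(lo, hi)]
        return [(lo, 180.0 + 1e-9), (-180.0, hi)]
    for lo1, hi1 in segments(a):
        for lo2, hi2 in segments(b):
            if max(lo1, lo2) < min(hi1, hi2):
                return True
    return False


def load_regions(path=None) -> dict[str, list[RegionBox]]:
    """Load Ramachandran-region boxes; overlapping boxes are a config error."""
    if path is None:
        text = resources.files("turnext.data").joinpath("regions.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    schemes: dict[str, list[RegionBox]] = {}
    for scheme, entries in raw.items():
        boxes = [RegionBox(e["name"], tuple(e["phi"]), tuple(e["psi"]))
                 for e in entries]
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                if (_interval_overlap(a.phi, b.phi)
                        and _interval_overlap(a.psi, b.psi)):
                    raise ValueError(
                        f"regions {a.name!r} and {b.name!r} overlap in scheme "
                        f"{scheme!r}")
        schemes[scheme] = boxes
    return schemes


# ---------------------------------------------------------------------------
# matching

def matches_definition(quad: DihedralQuad, definition: TurnTypeDefinition,
                       tol_main: float = TOL_MAIN,
                       tol_loose: float = TOL_LOOSE) -> bool:
    """Tolerance rule: >= 3 deviations <= tol_main, the rest <= tol_loose.

    Tolerances are inclusive; the cis-proline requirement of VI types is
    checked by the caller, not here.
    """
    dev = abs_delta(quad.as_array(), definition.canonical.as_array())
    return bool((dev <= tol_main).sum() >= 3 and dev.max() <= tol_loose)


def rmsda_to_canonical(quad: DihedralQuad, definition: TurnTypeDefinition) -> float:
    dev = abs_delta(quad.as_array(), definition.canonical.as_array())
    return float(np.sqrt((dev ** 2).mean()))


def _best_match(quad, candidates):
    hits = [d for d in candidates if matches_definition(quad, d)]
    if not hits:
        return None
    return min(hits, key=lambda d: (rmsda_to_canonical(quad, d), d.name))


def assign_classical(quad: DihedralQuad, cis_pro_at_i2: bool,
                     definitions: Sequence[TurnTypeDefinition]) -> str:
    """Name of the matching classical type, or "IV".

    VI types are eligible only with a cis-proline at i+2; multiple matches
    are resolved by minimal RMSDA to the canonical quad.
    """
    cands = [d for d in definitions if d.tier == "classical"
             and (cis_pro_at_i2 or not d.requires_cis_pro_i2)]
    best = _best_match(quad, cands)
    return best.name if best else "IV"


def assign_extended(quad: DihedralQuad,
                    definitions: Sequence[TurnTypeDefinition]) -> str:
    """For a type-IV quad: IV1-IV4 under the same rule, else IV_misc."""
    best = _best_match(quad, [d for d in definitions if d.tier == "extended"])
    return best.name if best else "IV_misc"


def assign_obsolete(quad: DihedralQuad,
                    definitions: Sequence[TurnTypeDefinition]) -> Optional[str]:
    """Obsolete-type annotation (III, III', V, V') or None."""
    best = _best_match(quad, [d for d in definitions if d.tier == "obsolete"])
    return best.name if best else None


# ---------------------------------------------------------------------------
# detection and full assignment

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _one_letter(aa3: str) -> str:
    return _THREE_TO_ONE.get(aa3.upper(), "X")


def _ss_lookup(ss_records: Sequence[SSRecord]):
    return {(r.chain_id, r.residue_number, r.insertion_code): r
            for r in ss_records}


def detect_turns(chain: Sequence[ResidueBackbone],
                 dihedrals: Sequence[BackboneDihedrals],
                 ss_records: Sequence[SSRecord]) -> list[BetaTurn]:
    """Emit every qualifying 4-residue window as an untyped BetaTurn.

    Conditions: geometric continuity, d(CA_i, CA_{i+3}) < 7 A, central
    residues non-helical (3-class), and, when any residue of the window is
    a strand, at least one must be coil.  Overlapping windows are all kept.
    Windows with an undefined central dihedral are skipped with a log entry.
    """
    lookup = _ss_lookup(ss_records)
    turns: list[BetaTurn] = []
    for i in range(len(chain) - 3):
        window = range(i, i + 4)
        if not check_continuity(chain, window):
            continue
        d13 = ca_distance(chain, i, i + 3)
        if d13 >= MAX_CA_DISTANCE:
            continue
        states = []
        for j in window:
            r = chain[j]
            rec = lookup.get((r.chain_id, r.residue_number, r.insertion_code))
            states.append(rec.reduced3 if rec is not None else "coil")
        if states[1] == "helix" or states[2] == "helix":
            continue
        if "strand" in states and "coil" not in states:
            continue
        angles = (dihedrals[i + 1].phi, dihedrals[i + 1].psi,
                  dihedrals[i + 2].phi, dihedrals[i + 2].psi)
        if any(a is None for a in angles):
            logger.info("window at %s: undefined central dihedral, skipped",
                        chain[i].label)
            continue
        turns.append(BetaTurn(
            chain_id=chain[i].chain_id,
            start_residue=chain[i].residue_number,
            start_insertion_code=chain[i].insertion_code,
            sequence="".join(_one_letter(chain[j].amino_acid) for j in window),
            quad=DihedralQuad(*angles),
            ca_distance_i_i3=d13,
            start_index=i,
        ))
    return turns


def _has_cis_pro_i2(chain, dihedrals, i) -> bool:
    res = chain[i + 2]
    om = dihedrals[i + 2].omega
    return (res.amino_acid.upper() == "PRO" and om is not None
            and abs(om) <= CIS_OMEGA_MAX)


def classify_extent(chain: Sequence[ResidueBackbone],
                    turn: BetaTurn) -> tuple[Optional[str], bool]:
    """Efimov extent (full ~180 deg reversal vs half ~90 deg) + Crawford flag.

    The reversal angle is measured between u1 = CA_{i+1}-CA_i and
    u2 = CA_{i+3}-CA_{i+2}; theta >= 135 deg (closer to a full reversal
    than to a right angle) classifies the turn as full.
    """
    i = turn.start_index
    u1 = chain[i + 1].coords_CA - chain[i].coords_CA
    u2 = chain[i + 3].coords_CA - chain[i + 2].coords_CA
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    crawford = turn.ca_distance_i_i3 < CRAWFORD_DISTANCE
    if n1 == 0 or n2 == 0:
        logger.warning("degenerate CA trace in turn at %s", chain[i].label)
        return None, crawford
    cosang = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    theta = math.degrees(math.acos(cosang))
    return ("full" if theta >= FULL_TURN_MIN_ANGLE else "half"), crawford


def label_regions(quad: DihedralQuad, scheme: str,
                  regions: dict[str, list[RegionBox]]) -> tuple[str, str]:
    """Region names containing (phi, psi) of residues i+1 and i+2."""
    try:
        boxes = regions[scheme]
    except KeyError:
        raise ValueError(f"unknown region scheme: {scheme!r}") from None
    out = []
    for phi, psi in ((quad.phi1, quad.psi1), (quad.phi2, quad.psi2)):
        hit = next((b.name for b in boxes if b.contains(phi, psi)), "unassigned")
        out.append(hit)
    return tuple(out)


def assign_turns(chain: Sequence[ResidueBackbone],
                 dihedrals: Sequence[BackboneDihedrals],
                 ss_records: Sequence[SSRecord],
                 definitions: Optional[Sequence[TurnTypeDefinition]] = None,
                 regions: Optional[dict[str, list[RegionBox]]] = None,
                 ) -> list[BetaTurn]:
    """Detect and fully annotate the beta-turns of one chain."""
    if definitions is None:
        definitions = load_definitions()
    if regions is None:
        regions = load_regions()
    turns = detect_turns(chain, dihedrals, ss_records)
    for t in turns:
        cis = _has_cis_pro_i2(chain, dihedrals, t.start_index)
        name = assign_classical(t.quad, cis, definitions)
        if name == "IV":
            name = assign_extended(t.quad, definitions)
        t.assigned_type = name
        t.obsolete_annotation = assign_obsolete(t.quad, definitions)
        t.extent, t.crawford_short = classify_extent(chain, t)
        t.region_labels = {s: label_regions(t.quad, s, regions) for s in regions}
    return turns
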