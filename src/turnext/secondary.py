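"""DSSP output parsing and 8-state to 3/4-class reduction.

DSSP assigns one of eight states per residue (H, G, I, E, B, T, S or blank).
Turn detection needs a coarser view: the 3-class scheme groups all helices
(H, G, I) as *helix*, keeps E as *strand* and sends everything else to
*coil*; the 4-class scheme additionally separates hydrogen-bonded turns
(T) out of the coil.  A 5-class variant exposing bends (S) is provided for
completeness but is not used by the turn-detection pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.PDB.DSSP import make_dssp_dict

from .geometry import ResidueBackbone

logger = logging.getLogger(__name__)

__all__ = ["SSRecord", "parse_dssp", "reduce_states", "all_coil_records"]

DSSP_CODES = frozenset("HGIEBTS ")

_THREE = {"H": "helix", "G": "helix", "I": "helix", "E": "strand",
          "B": "coil", "T": "coil", "S": "coil", " ": "coil"}
_FOUR = dict(_THREE, T="turn")
_FIVE = dict(_FOUR, S="bend")
_SCHEMES = {"three": _THREE, "four": _FOUR, "five": _FIVE}


def reduce_states(dssp_code: str, scheme: str = "three") -> str:
    """Map one 8-state DSSP code to a reduced class label.

    3-class: H/G/I -> helix, E -> strand, else coil.  4-class: as 3-class
    but T -> turn.  5-class: additionally S -> bend.  Blank (coil in DSSP)
    may be given as ``" "`` or ``"-"``.
    """
    code = " " if dssp_code in ("", "-") else dssp_code
    try:
        table = _SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown reduction scheme: {scheme!r}") from None
    if code not in DSSP_CODES:
        raise ValueError(f"unknown DSSP code: {dssp_code!r}")
    return table[code]


@dataclass
class SSRecord:
    """Secondary-structure state of one residue."""

    chain_id: str
    residue_number: int
    insertion_code: str
    amino_acid: str
    dssp_code: str

    @property
    def reduced3(self) -> str:
        return reduce_states(self.dssp_code, "three")

    @property
    def reduced4(self) -> str:
        return reduce_states(self.dssp_code, "four")


def parse_dssp(path) -> list[SSRecord]:
    """Parse a classic-format DSSP output file.

    One record per residue line, in file order; chain-break lines (``!``)
    are skipped by the underlying parser.  Raises ``ValueError`` when the
    header/residue table cannot be located.
    """
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:
        raise ValueError(f"malformed DSSP file {path}: {exc}") from None
    if not keys:
        raise ValueError(f"malformed DSSP file {path}: no residue records found")
    records = []
    for chain_id, res_id in keys:
        aa, ss = dssp_dict[(chain_id, res_id)][0], dssp_dict[(chain_id, res_id)][1]
        _, resnum, icode = res_id
        records.append(SSRecord(
            chain_id=chain_id,
            residue_number=resnum,
            insertion_code=icode.strip(),
            amino_acid=aa,
            dssp_code=" " if ss in ("-", "") else ss,
        ))
    return records


def all_coil_records(chain: Sequence[ResidueBackbone]) -> list[SSRecord]:
    """Permissive fallback when no DSSP file is available: everything coil.

    Without helix information the non-helical gate of turn detection cannot
    exclude anything, so this is *not* equivalent to running with a real
    DSSP assignment; a loud warning is logged.
    """
    logger.warning(
        "no DSSP assignment supplied: marking all %d residues of chain %s as "
        "coil; turn detection will not exclude helical central residues",
        len(chain), chain[0].chain_id if chain else "?",
    )
    return [
        SSRecord(r.chain_id, r.residue_number, r.insertion_code,
                 r.amino_acid, " ")
        for r in chain
    ]
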