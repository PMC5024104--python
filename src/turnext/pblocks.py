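"""Protein Block assignment by nearest-prototype angular distance.

Protein Blocks are a structural alphabet of 16 five-residue backbone
prototypes, labelled a to p, defined by 8 dihedral angles
(psi(n-2), phi(n-1), psi(n-1), phi(n), psi(n), phi(n+1), psi(n+1),
phi(n+2)) around the residue n being described.  A residue whose window is
fully defined receives the label of the prototype with minimal RMSDA over
those 8 angles; the two residues at each chain end (and any residue with an
undefined angle in its window) are marked 'Z'.  PB m is the alpha-helix
core, PB d the beta-strand core.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from ._angles import wrap_angle
from .geometry import BackboneDihedrals

__all__ = ["load_prototypes", "assign_pbs", "UNASSIGNED_PB"]

UNASSIGNED_PB = "Z"


def load_prototypes(path=None) -> dict[str, np.ndarray]:
    """Load the 16 PB prototypes (bundled reference values by default)."""
    if path is None:
        text = resources.files("turnext.data").joinpath(
            "pb_prototypes.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)["prototypes"]
    if len(raw) != 16:
        raise ValueError(f"expected 16 PB prototypes, found {len(raw)}")
    protos = {}
    for label in sorted(raw):
        angles = np.asarray(raw[label], float)
        if angles.shape != (8,):
            raise ValueError(f"prototype {label!r} must have 8 angles")
        protos[str(label)] = wrap_angle(angles)
    return protos


def _window(dihedrals: Sequence[BackboneDihedrals], n: int) -> Optional[np.ndarray]:
    if n - 2 < 0 or n + 2 >= len(dihedrals):
        return None
    vals = (
        dihedrals[n - 2].psi, dihedrals[n - 1].phi, dihedrals[n - 1].psi,
        dihedrals[n].phi, dihedrals[n].psi,
        dihedrals[n + 1].phi, dihedrals[n + 1].psi, dihedrals[n + 2].phi,
    )
    if any(v is None for v in vals):
        return None
    return np.asarray(vals, float)


def assign_pbs(dihedrals: Sequence[BackboneDihedrals],
               prototypes: Optional[dict[str, np.ndarray]] = None) -> str:
    """Per-residue PB string for one chain ('Z' where unassignable).

    Ties in the nearest-prototype search resolve to the alphabetically
    first label.
    """
    if prototypes is None:
        prototypes = load_prototypes()
    labels = sorted(prototypes)
    proto = np.stack([prototypes[l] for l in labels])  # (16, 8)
    out = []
    for n in range(len(dihedrals)):
        win = _window(dihedrals, n)
        if win is None:
            out.append(UNASSIGNED_PB)
            continue
        d = wrap_angle(win[None, :] - proto)
        out.append(labels[int(np.argmin((d * d).sum(axis=1)))])
    return "".join(out)
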