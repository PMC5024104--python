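"""Positional amino-acid (or Protein-Block) propensities as Z-scores.

For each turn type, the occurrences of symbol i at window position j
(i, i+1, i+2, i+3) are counted and compared with the expectation under the
background composition: n_exp(i, j) = N_j * f_i, the position total times
the overall frequency of the symbol.  The normalized deviation

    z = (n_obs - n_exp) / sqrt(n_exp)

uses the Poisson approximation for the denominator by default; a binomial
variant sqrt(n_exp * (1 - f_i)) is selectable.  |z| >= 4.42 marks strong
over/under-representation (p < 1e-5), 1.96 <= |z| < 4.42 weak (p < 0.05),
inclusive at the lower bound of each tier.  The same machinery applies to
any symbol alphabet, notably the 16 Protein-Block letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .turns import BetaTurn

__all__ = [
    "CountTable",
    "PropensityTable",
    "STRONG_Z",
    "WEAK_Z",
    "POSITIONS",
    "count_occurrences",
    "zscores",
    "classify_representation",
    "format_tier_letter",
]

STRONG_Z = 4.42  # |z| at/above: strong (p < 1e-5)
WEAK_Z = 1.96    # |z| at/above: weak   (p < 5e-2)

POSITIONS = ("i", "i+1", "i+2", "i+3")

AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class CountTable:
    """Observed counts for one turn type: symbols x 4 window positions."""

    n_obs: pd.DataFrame          # index: symbols (may include 'X'), columns: POSITIONS
    background: pd.Series        # frequency f_i per symbol, sums to 1 (no 'X')
    turn_type: str = "ALL"

    @property
    def position_totals(self) -> pd.Series:
        return self.n_obs.sum(axis=0)


def _background_freq(symbols: Iterable[str]) -> pd.Series:
    counts = pd.Series(list(symbols)).value_counts()
    counts = counts[counts.index != "X"]
    if counts.empty:
        raise ValueError("no known symbols to derive a background from")
    return counts / counts.sum()


def count_occurrences(turns: Sequence[BetaTurn],
                      background_sequences: Optional[Iterable[str]] = None,
                      alphabet: Optional[Sequence[str]] = None,
                      ) -> dict[str, CountTable]:
    """Count symbols per position, grouped by assigned turn type.

    ``background_sequences`` is an iterable of residue strings (e.g. full
    chain sequences) defining the background composition f_i; when omitted
    the residues of the turn windows themselves are used.  Unknown residues
    count under 'X' and are excluded from the background and from Z-scores.
    Returns one table per turn type plus an "ALL" table over every turn.
    """
    if background_sequences is None:
        background_sequences = [t.sequence for t in turns]
    known = list(alphabet) if alphabet is not None else list(AA_ALPHABET)
    symbols = [s for s in known if s != "X"] + ["X"]
    bg = _background_freq(s if s in known else "X"
                          for s in "".join(background_sequences))
    bg = bg.reindex([s for s in symbols if s != "X"], fill_value=0.0)
    if bg.sum() == 0:
        raise ValueError("background has no symbols from the alphabet")
    bg = bg / bg.sum()

    def empty():
        return pd.DataFrame(0, index=pd.Index(symbols, name="symbol"),
                            columns=list(POSITIONS))

    per_type: dict[str, pd.DataFrame] = {"ALL": empty()}
    for t in turns:
        if t.assigned_type is None:
            raise ValueError(f"turn at {t.chain_id}:{t.start_residue} is untyped")
        if len(t.sequence) != 4:
            raise ValueError("turn sequence must resolve to 4 residues")
        tab = per_type.setdefault(t.assigned_type, empty())
        for pos, sym in zip(POSITIONS, t.sequence):
            sym = sym if sym in tab.index else "X"
            if sym not in tab.index:
                continue
            tab.loc[sym, pos] += 1
            per_type["ALL"].loc[sym, pos] += 1
    return {name: CountTable(tab, bg.copy(), name)
            for name, tab in per_type.items()}


def classify_representation(z: Optional[float]) -> str:
    """Tier of a Z-score: strong/weak over/under, or neutral.

    Thresholds are inclusive at the larger tier: |z| >= 4.42 strong,
    1.96 <= |z| < 4.42 weak.
    """
    if z is None or (isinstance(z, float) and math.isnan(z)):
        return "neutral"
    mag = abs(z)
    if mag < WEAK_Z:
        return "neutral"
    direction = "over" if z > 0 else "under"
    return f"{'strong' if mag >= STRONG_Z else 'weak'}_{direction}"


def format_tier_letter(symbol: str, tier: str) -> str:
    """Report convention: strong tier uppercase, weak tier lowercase."""
    if tier.startswith("strong"):
        return symbol.upper()
    if tier.startswith("weak"):
        return symbol.lower()
    return ""


@dataclass
class PropensityTable:
    """Z-scores and tiers for one turn type."""

    turn_type: str
    n_obs: pd.DataFrame
    n_exp: pd.DataFrame
    z: pd.DataFrame      # NaN where n_exp == 0
    tier: pd.DataFrame   # strings from classify_representation


def zscores(table: CountTable, denominator: str = "poisson") -> PropensityTable:
    """Normalize a count table into Z-scores.

    n_exp(i, j) = N_j * f_i.  The default Poisson denominator is
    sqrt(n_exp); the binomial variant uses sqrt(n_exp * (1 - f_i)).
    Cells with n_exp = 0 (and the 'X' bucket) are neutral with undefined z.
    """
    if denominator not in ("poisson", "binomial"):
        raise ValueError(f"unknown denominator: {denominator!r}")
    obs = table.n_obs.loc[[s for s in table.n_obs.index if s != "X"]].astype(float)
    totals = table.n_obs.sum(axis=0)  # position totals include every counted symbol
    f = table.background.reindex(obs.index, fill_value=0.0)
    exp = pd.DataFrame(np.outer(f.values, totals.values),
                       index=obs.index, columns=obs.columns)
    if denominator == "poisson":
        denom = np.sqrt(exp)
    else:
        denom = np.sqrt(exp.mul(1.0 - f, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - exp) / denom
    z = z.where(exp > 0)
    tier = z.map(lambda v: classify_representation(None if pd.isna(v) else float(v)))
    return PropensityTable(table.turn_type, obs, exp, z, tier)
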