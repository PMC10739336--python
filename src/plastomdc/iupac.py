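"""IUPAC nucleotide codes, gap/missing semantics, and the bitmask encoding.

Every alignment cell is reduced to a 5-bit mask over the canonical states
``{A, C, G, T, -}``.  Ambiguity codes expand to the union of their
nucleotides; ``-`` is a *bona fide* character state (gap-as-state
convention), while ``N`` and ``?`` are *missing data* under the default
policy — the specimen simply contributes nothing at that column.  A strict
policy instead expands ``N``/``?`` to ``{A,C,G,T}``, which makes a single
low-coverage genome able to veto diagnostic sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

A, C, G, T, GAP = 1, 2, 4, 8, 16
ACGT = A | C | G | T
MISSING = 0  # mask value for a cell that contributes nothing

#: canonical one-letter state for each single-bit mask
_BIT_TO_CHAR = {A: "A", C: "C", G: "G", T: "T", GAP: "-"}

#: IUPAC code -> bitmask (uppercase keys only; callers normalise case)
CODE_TO_MASK: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T, "U": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "-": GAP,
}

MISSING_CODES = frozenset("N?")

VALID_CODES = frozenset(CODE_TO_MASK) | MISSING_CODES


class SymbolError(ValueError):
    """An alignment contains a character outside the IUPAC/gap/missing set."""


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    ignore = np.full(256, -1, dtype=np.int16)
    strict = np.full(256, -1, dtype=np.int16)
    for code, mask in CODE_TO_MASK.items():
        for ch in (code, code.lower()):
            ignore[ord(ch)] = mask
            strict[ord(ch)] = mask
    for code in MISSING_CODES:
        for ch in (code, code.lower()):
            ignore[ord(ch)] = MISSING
            strict[ord(ch)] = ACGT
    return ignore, strict


_TABLE_IGNORE, _TABLE_STRICT = _build_tables()


def encoding_table(policy: str = "ignore") -> np.ndarray:
    """Return the 256-entry char->mask lookup table for a missing policy.

    ``ignore``: N/? are missing; ``strict``: N/? expand to {A,C,G,T}.
    Unknown characters map to -1 so callers can detect them.
    """
    if policy == "ignore":
        return _TABLE_IGNORE
    if policy == "strict":
        return _TABLE_STRICT
    raise ValueError(f"unknown missing-data policy: {policy!r}")


def mask_of(symbol: str, policy: str = "ignore") -> int:
    """Bitmask of one alignment symbol under the given missing policy."""
    m = int(encoding_table(policy)[ord(symbol)]) if len(symbol) == 1 else -1
    if m < 0:
        raise SymbolError(f"invalid alignment symbol {symbol!r}")
    return m


def mask_to_states(mask: int) -> frozenset[str]:
    """Decode a bitmask into its set of canonical states."""
    return frozenset(ch for bit, ch in _BIT_TO_CHAR.items() if mask & bit)


@dataclass(frozen=True)
class StateSet:
    """Character states of one alignment cell (or a union of cells).

    ``missing`` is True when the cell carries no information (N/? under the
    default policy); a non-missing StateSet always has at least one state.
    """

    states: frozenset[str]
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing and not self.states:
            raise ValueError("non-missing StateSet must have at least one state")
        bad = self.states - {"A", "C", "G", "T", "-"}
        if bad:
            raise ValueError(f"invalid canonical states: {sorted(bad)}")

    @classmethod
    def from_symbol(cls, symbol: str, policy: str = "ignore") -> "StateSet":
        m = mask_of(symbol.upper(), policy)
        if m == MISSING:
            return cls(frozenset(), missing=True)
        return cls(mask_to_states(m))

    @classmethod
    def from_mask(cls, mask: int) -> "StateSet":
        if mask == MISSING:
            return cls(frozenset(), missing=True)
        return cls(mask_to_states(mask))

    @property
    def mask(self) -> int:
        m = 0
        for s in self.states:
            m |= CODE_TO_MASK[s]
        return m

    def union(self, other: "StateSet") -> "StateSet":
        return StateSet(self.states | other.states,
                        missing=self.missing and other.missing)

    def isdisjoint(self, other: "StateSet") -> bool:
        return self.states.isdisjoint(other.states)

    def __contains__(self, state: str) -> bool:
        return state in self.states


def union_mask(masks: Iterable[int]) -> int:
    out = 0
    for m in masks:
        out |= m
    return out
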