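"""Shared fixtures and the independent brute-force diagnostic-site oracle.

The oracle re-derives pure diagnostic sites cell-by-cell with its own
IUPAC table and set logic, deliberately sharing no code with the vectorised
scanner it validates.
"""

from __future__ import annotations

import numpy as np
import pytest

from plastomdc import MultipleAlignment, from_species_dict

# --- independent IUPAC semantics (do not import from the package) ---------

_ORACLE_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "-": {"-"},
}


def _oracle_expand(symbol: str, policy: str):
    """None means the cell is missing and contributes nothing."""
    s = symbol.upper()
    if s in ("N", "?"):
        return {"A", "C", "G", "T"} if policy == "strict" else None
    return set(_ORACLE_IUPAC[s])


def _oracle_category(q: frozenset, r: frozenset) -> str:
    if q == {"-"} and "-" not in r:
        return "deletion"
    if r == {"-"} and "-" not in q:
        return "insertion"
    if "-" not in q and "-" not in r:
        return "substitution"
    return "mixed"


def oracle_sites(records: list[tuple[str, str]], query_species: str,
                 policy: str = "ignore") -> list[tuple]:
    """Exhaustive per-column scan: (column, query states, ref union, category).

    A column is diagnostic when every non-missing query cell expands to one
    identical state set, that set is disjoint from the union of all
    non-missing reference cells, and both sides have a non-missing cell.
    """
    n_cols = len(records[0][1])
    out = []
    for col in range(n_cols):
        q_sets, r_sets = [], []
        for sp, seq in records:
            expanded = _oracle_expand(seq[col], policy)
            if expanded is None:
                continue
            (q_sets if sp == query_species else r_sets).append(
                frozenset(expanded))
        if not q_sets or not r_sets:
            continue
        if len(set(q_sets)) != 1:
            continue  # query-polymorphic
        q = q_sets[0]
        r_union = frozenset().union(*r_sets)
        if q & r_union:
            continue
        out.append((col, q, r_union, _oracle_category(q, r_union)))
    return out


def scanner_sites_as_tuples(alignment: MultipleAlignment, species: str,
                            policy: str = "ignore") -> list[tuple]:
    """The implementation's sites in the oracle's tuple form."""
    from plastomdc import SpeciesPartition, find_diagnostic_sites

    part = SpeciesPartition.for_query(alignment, species)
    return [
        (s.column, frozenset(s.query_state.states),
         frozenset(s.reference_union.states), s.category)
        for s in find_diagnostic_sites(alignment, part, policy=policy)
    ]


def random_alignment(rng: np.random.Generator,
                     max_species: int = 6, max_specimens: int = 4,
                     max_columns: int = 200,
                     alphabet: str = "ACGT-NRYSW?") -> MultipleAlignment:
    """A random small alignment mixing bases, gaps, ambiguity and missing."""
    n_species = int(rng.integers(2, max_species + 1))
    n_cols = int(rng.integers(1, max_columns + 1))
    symbols = np.array(list(alphabet))
    # bias towards plain bases so diagnostic sites actually occur
    weights = np.array([10.0] * 4 + [2.0] + [1.0] * (len(alphabet) - 5))
    weights /= weights.sum()
    species_seqs = {}
    for i in range(n_species):
        n_spec = int(rng.integers(1, max_specimens + 1))
        seqs = ["".join(rng.choice(symbols, size=n_cols, p=weights))
                for _ in range(n_spec)]
        species_seqs[f"sp{i + 1}"] = seqs
    return from_species_dict("Genus", species_seqs)


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    """3 species x 2 specimens; sp1 diagnosable at known columns."""
    return from_species_dict("Toy", {
        "sp1": ["ACGTACGTAA", "ACGTACGTAA"],
        "sp2": ["ACCTACGTAA", "ACCTACGTAA"],
        "sp3": ["ACTTACGTAA", "ACTTACGTAA"],
    })
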