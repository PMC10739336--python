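"""Mean pairwise sequence identity and consensus for genus alignments.

Identity of a pair is the percentage of identical symbols over the
comparable columns.  Columns gapped in *both* sequences are not comparable
(default ``gap_mode='mismatch'``: a gap against a residue counts as a
mismatch); ``gap_mode='exclude'`` drops every column touching a gap.
Columns with N/? in either sequence are never compared.

The consensus is a plurality vote per column over the literal states
{A, C, G, T, -}; missing and ambiguity symbols do not vote.  Ties break by
the fixed order A < C < G < T < -; columns won by the gap are dropped from
the emitted sequence (their support is still recorded).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .alignment import MultipleAlignment
from .iupac import A, C, G, GAP, T

_VOTE_ORDER = ((A, "A"), (C, "C"), (G, "G"), (T, "T"), (GAP, "-"))


@dataclass
class IdentityResult:
    genus: str
    mean_identity_pct: float
    n_pairs: int
    per_pair: Optional[np.ndarray] = None  # symmetric %, 100 on the diagonal


@dataclass
class ConsensusSequence:
    genus: str
    seq: str
    column_support: np.ndarray  # majority fraction per alignment column


class IdentityError(ValueError):
    pass


def _encode(seq: str) -> np.ndarray:
    # identity compares literal residues, so ambiguity codes are compared
    # verbatim (R vs R matches, R vs A does not); N/? are excluded.
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    arr[(arr == ord("N")) | (arr == ord("?")) | (arr == ord("n"))] = 0
    return arr


def pairwise_identity(a: str, b: str, gap_mode: str = "mismatch") -> float:
    """Percent identity of two aligned sequences."""
    if len(a) != len(b):
        raise IdentityError(f"length mismatch: {len(a)} vs {len(b)}")
    if gap_mode not in ("mismatch", "exclude"):
        raise ValueError("gap_mode must be 'mismatch' or 'exclude'")
    xa, xb = _encode(a.upper()), _encode(b.upper())
    gap = ord("-")
    comparable = (xa != 0) & (xb != 0)
    if gap_mode == "mismatch":
        comparable &= ~((xa == gap) & (xb == gap))
    else:
        comparable &= (xa != gap) & (xb != gap)
    n = int(comparable.sum())
    if n == 0:
        raise IdentityError("no comparable columns between the two sequences")
    matches = int(((xa == xb) & comparable).sum())
    return matches / n * 100.0


def mean_pairwise_identity(alignment: MultipleAlignment,
                           gap_mode: str = "mismatch",
                           keep_matrix: bool = False) -> IdentityResult:
    """Mean identity over all unordered specimen pairs of the alignment."""
    n = alignment.n_records
    if n < 2:
        raise IdentityError("need at least 2 records for pairwise identity")
    mat = None
    if keep_matrix:
        mat = np.full((n, n), 100.0)
    total, npairs = 0.0, 0
    seqs = [r.sequence for r in alignment.records]
    for i, j in combinations(range(n), 2):
        pid = pairwise_identity(seqs[i], seqs[j], gap_mode=gap_mode)
        total += pid
        npairs += 1
        if mat is not None:
            mat[i, j] = mat[j, i] = pid
    return IdentityResult(genus=alignment.genus,
                          mean_identity_pct=total / npairs,
                          n_pairs=npairs, per_pair=mat)


def consensus(alignment: MultipleAlignment) -> ConsensusSequence:
    """Plurality consensus of the alignment, gap-winning columns dropped."""
    mat = alignment.matrix("ignore")
    # only unambiguous cells vote; ambiguity codes abstain like N
    counts = np.stack([(mat == mask).sum(axis=0) for mask, _ in _VOTE_ORDER])
    voters = counts.sum(axis=0)
    winner = counts.argmax(axis=0)  # first max wins -> A<C<G<T<- tie order
    best_n = counts[winner, np.arange(mat.shape[1])]
    support = np.divide(best_n, voters, out=np.zeros(mat.shape[1]),
                        where=voters > 0)
    symbols = np.array([ch for _, ch in _VOTE_ORDER])
    col_char = symbols[winner]
    col_char[voters == 0] = "N"
    emit = (col_char != "-")
    return ConsensusSequence(genus=alignment.genus,
                             seq="".join(col_char[emit]),
                             column_support=support)
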