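"""Quadripartite plastome structure: inverted-repeat detection and removal.

Land-plant plastomes are typically quadripartite — a large single-copy
region (LSC), a small single-copy region (SSC) and two near-identical
inverted repeats (IRa/IRb, ~20-25 kb each).  Aligning genomes that retain
both IR copies double-counts every IR mutation, so comparative pipelines
excise one copy first.  Detection here is seed-and-extend: exact k-mer
seeds between the sequence and its reverse complement, deduplicated per
anti-diagonal and extended outward/inward under a mismatch budget; the
longest qualifying arm pair wins, ties broken by smallest start.

Coordinates are 0-based half-open and treated as circular (plastomes are
circular molecules): any region interval may wrap through the origin, in
which case end < start.  Removal rotates the genome to the LSC start so the
cyclic order LSC-IRb-SSC-IRa becomes linear, then drops the trailing IRa
(and optionally the retained IRb copy too).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import VALID_CODES

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeError(ValueError):
    pass


@dataclass(frozen=True)
class PlastomeSequence:
    """One plastome: id, uppercase nucleotide string, circularity flag."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))
        if not self.seq:
            raise PlastomeError(f"{self.id}: empty sequence")
        bad = set(self.seq) - VALID_CODES
        if bad:
            raise PlastomeError(f"{self.id}: non-nucleotide symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class QuadripartiteAnnotation:
    """LSC / IRb / SSC / IRa intervals, 0-based half-open, circular coords.

    An interval with end < start wraps through the origin.  IRb is the arm
    that follows the LSC in cyclic genome order; ir_length is the common
    arm length.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_length: int

    def region_length(self, region: str, n: int) -> int:
        s, e = getattr(self, region)
        return _cyc_len(s, e, n)


def _cyc_len(s: int, e: int, n: int) -> int:
    """Length of the (possibly wrapping) half-open interval; s == e is empty."""
    if s == e:
        return 0
    return e - s if e > s else n - s + e


def _seed_diagonals(s: str, k: int) -> list[tuple[int, int]]:
    """One exact-k-mer seed per anti-diagonal of the inverted self-match.

    A k-mer at ``i`` matching the reverse complement of a k-mer at ``j``
    satisfies ``s[i+t] == comp(s[j+k-1-t])``; every sub-seed of one repeat
    pairing shares the invariant ``i + j``.  One diagonal can still carry
    seeds of *distinct* pairings (images of the repeat in a doubled
    circular sequence), so all seeds are kept, sorted; the caller skips
    those already covered by an extended pair.
    """
    rc = revcomp(s)
    n = len(s)
    index: dict[str, list[int]] = {}
    for p in range(0, n - k + 1):
        index.setdefault(rc[p:p + k], []).append(p)
    diags: dict[int, list[tuple[int, int]]] = {}
    for i in range(0, n - k + 1):
        kmer = s[i:i + k]
        if "N" in kmer or "?" in kmer:
            continue
        for p in index.get(kmer, ()):
            j = n - p - k
            if j <= i:
                continue  # keep arm1 left of arm2; the mirror pair covers the rest
            diags.setdefault(i + j, []).append((i, j))
    for seeds in diags.values():
        seeds.sort()
    return diags


def _extend(s: str, i: int, j: int, k: int, max_mm: float) -> tuple[int, int, int]:
    """Greedily extend the arm pair ``[i,i+k) ~ revcomp([j,j+k))``.

    Outward first (arm1 left / arm2 right), then inward, keeping total
    mismatches within ``max_mm * length`` and the arms disjoint.
    Returns (arm1_start, arm2_start, length).
    """
    n = len(s)
    length, mm = k, 0
    # outward: prepend s[i-1], append pair at s[j+length]
    while i - 1 >= 0 and j + length < n:
        match = _COMP1.get(s[i - 1]) == s[j + length]
        new_mm = mm + (0 if match else 1)
        if new_mm > max_mm * (length + 1):
            break
        i, length, mm = i - 1, length + 1, new_mm
    # inward: append s[i+length], prepend pair at s[j-1]
    while j - 1 >= i + length + 1:
        match = _COMP1.get(s[i + length]) == s[j - 1]
        new_mm = mm + (0 if match else 1)
        if new_mm > max_mm * (length + 1):
            break
        j, length, mm = j - 1, length + 1, new_mm
    return i, j, length


def detect_inverted_repeat(seq: PlastomeSequence,
                           min_ir_length: int = 1000,
                           max_mismatch_frac: float = 0.02,
                           ) -> Optional[QuadripartiteAnnotation]:
    """Find the longest pair of near-exact inverted repeats, or None ("no-IR").

    Circular sequences are scanned doubled with coordinates reduced modulo
    the length, which makes detection invariant to rotation.  Returns None
    when no arm pair of at least ``min_ir_length`` exists.
    """
    if min_ir_length < 100:
        raise PlastomeError("min_ir_length must be >= 100")
    n = len(seq)
    if n < 2 * min_ir_length:
        raise PlastomeError(
            f"{seq.id}: length {n} < 2 x min_ir_length ({2 * min_ir_length})")

    s = seq.seq + seq.seq if seq.circular else seq.seq
    k = max(8, min(16, min_ir_length // 4))
    best: Optional[tuple[int, int, int]] = None  # (s1, s2, length)
    for seeds in _seed_diagonals(s, k).values():
        extents: list[tuple[int, int, int]] = []
        for i, j in seeds:
            # skip seeds inside a pair already extended on this diagonal
            if any(s1 <= i and i + k <= s1 + ln and s2 <= j and
                   j + k <= s2 + ln for s1, s2, ln in extents):
                continue
            s1, s2, length = _extend(s, i, j, k, max_mismatch_frac)
            extents.append((s1, s2, length))
            if length < min_ir_length:
                continue
            if seq.circular:
                # genuine pair, not a doubled-copy artefact: arms within one turn
                if s2 + length > s1 + n or 2 * length > n:
                    continue
            if (best is None or length > best[2]
                    or (length == best[2]
                        and (s1 % n, s2 % n) < (best[0] % n, best[1] % n))):
                best = (s1, s2, length)
    if best is None:
        return None

    s1, s2, length = best
    b1, b2 = (s1 % n, s2 % n) if seq.circular else (s1, s2)

    def _end(b: int) -> int:
        e = b + length
        return e if e <= n else e - n  # wraps on circular genomes

    e1, e2 = _end(b1), _end(b2)
    # cyclic order: arm1, inter-region, arm2, wrap-region
    inter = (e1 % n, b2)
    wrap = (e2 % n, b1)
    if _cyc_len(*wrap, n) >= _cyc_len(*inter, n):
        lsc, irb, ssc, ira = wrap, (b1, e1), inter, (b2, e2)
    else:
        lsc, irb, ssc, ira = inter, (b2, e2), wrap, (b1, e1)
    return QuadripartiteAnnotation(lsc=lsc, irb=irb, ssc=ssc, ira=ira,
                                   ir_length=length)


def remove_ir_copy(seq: PlastomeSequence,
                   ann: Optional[QuadripartiteAnnotation],
                   remove: str = "one") -> PlastomeSequence:
    """Excise the duplicated IR copy: keep LSC + IRb + SSC in genome order.

    ``remove='both'`` drops the retained copy as well.  A None annotation
    ("no-IR") returns the sequence unchanged with a warning.  The output is
    linear and starts at the LSC start.
    """
    if remove not in ("one", "both"):
        raise ValueError("remove must be 'one' or 'both'")
    if ann is None:
        log.warning("%s: no inverted repeat found; sequence left unchanged",
                    seq.id)
        return seq
    n = len(seq)
    for name in ("lsc", "irb", "ssc", "ira"):
        s, e = getattr(ann, name)
        if not (0 <= s < n and 0 <= e <= n):
            raise PlastomeError(f"{seq.id}: {name} interval {(s, e)} out of bounds")
    total = sum(ann.region_length(r, n) for r in ("lsc", "irb", "ssc", "ira"))
    if total != n:
        raise PlastomeError(
            f"{seq.id}: annotation does not partition the genome "
            f"({total} != {n})")
    start = ann.lsc[0] % n
    rotated = seq.seq[start:] + seq.seq[:start]
    if remove == "one":
        out = rotated[:n - ann.ir_length]
    else:
        lsc_len = ann.region_length("lsc", n)
        out = (rotated[:lsc_len]
               + rotated[lsc_len + ann.ir_length:n - ann.ir_length])
    return PlastomeSequence(seq.id, out, circular=False)


def prep_fasta(in_path: str | Path, out_path: str | Path,
               min_ir_length: int = 1000, max_mismatch_frac: float = 0.02,
               remove: str = "one", circular: bool = False,
               report_path: str | Path | None = None) -> list[dict]:
    """Detect and excise IRs for every record of a FASTA file.

    Writes the stripped FASTA and, optionally, a TSV annotation report
    (0-based half-open coordinates).  Returns the report rows.
    """
    rows = []
    out_records = []
    for rec in SeqIO.parse(str(in_path), "fasta"):
        ps = PlastomeSequence(rec.id, str(rec.seq), circular=circular)
        ann = detect_inverted_repeat(ps, min_ir_length, max_mismatch_frac)
        stripped = remove_ir_copy(ps, ann, remove=remove)
        out_records.append(SeqRecord(Seq(stripped.seq), id=rec.id, description=""))
        row: dict = {"id": rec.id,
                     "ir_length": 0 if ann is None else ann.ir_length}
        if ann is not None:
            for region in ("lsc", "irb", "ssc", "ira"):
                s, e = getattr(ann, region)
                row[f"{region}_start"], row[f"{region}_end"] = s, e
        rows.append(row)
    SeqIO.write(out_records, str(out_path), "fasta")
    if report_path is not None:
        import pandas as pd

        cols = ["id", "lsc_start", "lsc_end", "irb_start", "irb_end",
                "ssc_start", "ssc_end", "ira_start", "ira_end", "ir_length"]
        pd.DataFrame(rows).reindex(columns=cols).to_csv(
            report_path, sep="\t", index=False)
    return rows
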