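"""Per-genus multiple sequence alignments with genus/species/specimen labels.

The container wraps an equal-length set of aligned plastome sequences.  The
FASTA header convention is ``>Genus_species|specimen_id`` but any regex with
named groups ``genus``, ``species`` and (optionally) ``specimen`` can be
supplied.  Sequences are normalised to uppercase on ingest; ``?`` is kept
verbatim (it is synonymous with ``N`` downstream).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import SymbolError, encoding_table

DEFAULT_HEADER_REGEX = r"^(?P<genus>[^_\s]+)_(?P<species>[^|\s]+)\|(?P<specimen>\S+)$"


@dataclass(frozen=True)
class AlignmentRecord:
    genus: str
    species: str
    specimen_id: str
    sequence: str

    @property
    def label(self) -> str:
        return f"{self.genus}_{self.species}|{self.specimen_id}"


class AlignmentError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    """Equal-length aligned sequences for one genus.

    Invariants enforced at construction: all sequences share one length,
    every symbol is IUPAC/gap/missing, at least one record.  The study
    inclusion rule (>= 3 species per genus) is checked by callers that
    implement the genus-level pipeline, not here, so that small fixtures
    remain expressible.
    """

    records: list[AlignmentRecord]
    _matrix_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        normalised = []
        table = encoding_table("ignore")
        for r in self.records:
            seq = r.sequence.upper()
            codes = np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)
            bad = table[codes] < 0
            if bad.any():
                col = int(np.argmax(bad))
                raise SymbolError(
                    f"invalid symbol {seq[col]!r} at column {col} in {r.label}")
            normalised.append(AlignmentRecord(r.genus, r.species, r.specimen_id, seq))
        self.records = normalised

    # -- basic views ---------------------------------------------------

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        """Distinct species in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    @property
    def genus(self) -> str:
        return self.records[0].genus

    def rows_of(self, species: str) -> list[int]:
        rows = [i for i, r in enumerate(self.records) if r.species == species]
        if not rows:
            raise KeyError(f"species {species!r} not in alignment")
        return rows

    def specimens_of(self, species: str) -> list[AlignmentRecord]:
        return [self.records[i] for i in self.rows_of(species)]

    def matrix(self, policy: str = "ignore") -> np.ndarray:
        """(n_records, n_columns) int16 matrix of state bitmasks."""
        if policy not in self._matrix_cache:
            table = encoding_table(policy)
            rows = [
                table[np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)]
                for r in self.records
            ]
            self._matrix_cache[policy] = np.vstack(rows)
        return self._matrix_cache[policy]

    def subset(self, indices: Sequence[int]) -> "MultipleAlignment":
        return MultipleAlignment([self.records[i] for i in indices])

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def parse_header(header: str, header_regex: str = DEFAULT_HEADER_REGEX
                 ) -> tuple[str, str, str]:
    m = re.match(header_regex, header)
    if not m:
        raise AlignmentError(
            f"header {header!r} does not match pattern {header_regex!r}")
    groups = m.groupdict()
    genus = groups["genus"]
    species = groups["species"]
    specimen = groups.get("specimen") or header
    return genus, species, specimen


def read_alignment(path: str | Path,
                   header_regex: str = DEFAULT_HEADER_REGEX) -> MultipleAlignment:
    """Load one genus alignment from aligned FASTA."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genus, species, specimen = parse_header(rec.id, header_regex)
        records.append(AlignmentRecord(genus, species, specimen, str(rec.seq)))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return MultipleAlignment(records)


def write_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.label, description="")
        for r in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def from_species_dict(genus: str,
                      species_seqs: dict[str, Iterable[str]]) -> MultipleAlignment:
    """Convenience constructor: ``{species: [specimen sequences...]}``."""
    records = []
    for sp, seqs in species_seqs.items():
        for i, seq in enumerate(seqs, start=1):
            records.append(AlignmentRecord(genus, sp, f"{sp}{i}", seq))
    return MultipleAlignment(records)
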