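"""Molecular diagnostic characters (MDCs): site scan, classification, events.

An MDC is a "pure diagnostic site": an alignment column at which every
specimen of the query species carries one identical character state that no
specimen of any other species in the genus carries.  Columns where the
query species is itself polymorphic are excluded by definition; the gap
``-`` is a character state, so indels generate diagnostic columns too.

Consecutive diagnostic columns of one species are merged into a single
variation *event*.  Single-column events keep their site category
(substitution / deletion / insertion / mixed); runs of two or more columns
become the corresponding ``multi_*`` type, with heterogeneous runs (or runs
containing a mixed column) classified as ``multi_mixed``.

The per-cell character-state semantics (IUPAC expansion, gap-as-state,
N/? missing) live in :mod:`plastomdc.iupac`; the scan itself is vectorised
over the bitmask matrix of the alignment.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignment import MultipleAlignment
from .iupac import GAP, MISSING, StateSet

log = logging.getLogger(__name__)

SITE_CATEGORIES = ("substitution", "deletion", "insertion", "mixed")
EVENT_TYPES = (
    "substitution", "deletion", "insertion", "mixed",
    "multi_substitution", "multi_deletion", "multi_insertion", "multi_mixed",
)


@dataclass(frozen=True)
class SpeciesPartition:
    """One-vs-rest split of the species in a genus alignment."""

    query_species: str
    reference_species: frozenset[str]

    @classmethod
    def for_query(cls, alignment: MultipleAlignment, query: str
                  ) -> "SpeciesPartition":
        species = alignment.species
        if query not in species:
            raise KeyError(f"query species {query!r} not in alignment")
        return cls(query, frozenset(s for s in species if s != query))


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic column: query state, reference union, category."""

    column: int
    query_state: StateSet
    reference_union: StateSet
    category: str


@dataclass(frozen=True)
class MdcEvent:
    """A maximal run of consecutive diagnostic columns of one species."""

    start: int
    end: int  # half-open
    event_type: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpeciesProfile:
    """Per-species MDC result: site count, events, site tally per event type."""

    genus: str
    species: str
    n_specimens: int
    mdc_count: int
    events: list[MdcEvent]
    type_tally: Counter = field(default_factory=Counter)
    sites: list[DiagnosticSite] = field(default_factory=list)

    @property
    def event_counts(self) -> Counter:
        return Counter(e.event_type for e in self.events)


def column_states(alignment: MultipleAlignment, column: int, species: str,
                  policy: str = "ignore") -> list[StateSet]:
    """StateSets of every specimen of ``species`` at one column."""
    if not 0 <= column < alignment.n_columns:
        raise IndexError(f"column {column} out of range")
    mat = alignment.matrix(policy)
    return [StateSet.from_mask(int(mat[r, column]))
            for r in alignment.rows_of(species)]


def classify_site(query_state: StateSet, reference_union: StateSet) -> str:
    """Site category from the two disjoint state sets.

    deletion: query is the gap, references are gap-free; insertion: the
    mirror case; substitution: no gap on either side; mixed: gap and
    nucleotide signal co-occur across the two sides.
    """
    if not query_state.isdisjoint(reference_union):
        raise ValueError("query and reference states must be disjoint")
    q_gap = "-" in query_state
    r_gap = "-" in reference_union
    if query_state.states == {"-"} and not r_gap:
        return "deletion"
    if reference_union.states == {"-"} and not q_gap:
        return "insertion"
    if not q_gap and not r_gap:
        return "substitution"
    return "mixed"


def _classify_masks(qmask: int, rmask: int) -> str:
    if qmask == GAP and not rmask & GAP:
        return "deletion"
    if rmask == GAP and not qmask & GAP:
        return "insertion"
    if not (qmask | rmask) & GAP:
        return "substitution"
    return "mixed"


def find_diagnostic_sites(alignment: MultipleAlignment,
                          partition: SpeciesPartition,
                          policy: str = "ignore",
                          mask_terminal_gaps: bool = False,
                          ) -> list[DiagnosticSite]:
    """Scan every column for pure diagnostic sites of the query species.

    A column qualifies when (i) all non-missing query specimens share one
    identical state set, (ii) that set is disjoint from the union of all
    non-missing reference states, and (iii) both sides have at least one
    non-missing specimen.  Query-polymorphic columns are excluded.
    """
    q_rows = alignment.rows_of(partition.query_species)
    r_rows = [i for i, rec in enumerate(alignment.records)
              if rec.species in partition.reference_species]
    if not r_rows:
        raise KeyError("partition has no reference specimens in the alignment")

    mat = alignment.matrix(policy)
    if mask_terminal_gaps:
        mat = _mask_terminal_gaps(mat, alignment)
    q = mat[q_rows]  # (nq, L)
    r = mat[r_rows]  # (nr, L)

    # per-column union of non-missing query masks, and polymorphism check
    q_missing = q == MISSING
    q_any = ~q_missing.all(axis=0)
    r_union = np.bitwise_or.reduce(r, axis=0)
    r_any = (r != MISSING).any(axis=0)

    # query monomorphism: all non-missing cells carry the identical mask
    q_max = q.max(axis=0)
    q_filled = np.where(q_missing, q_max[None, :], q)
    q_mono = (q_filled == q_max[None, :]).all(axis=0)

    candidate = q_any & r_any & q_mono & ((q_max & r_union) == 0)
    n_skipped = int((~(q_any & r_any)).sum())
    if n_skipped:
        log.debug("%s: %d all-missing columns skipped for query %s",
                  alignment.genus, n_skipped, partition.query_species)

    sites = []
    for col in np.flatnonzero(candidate):
        qmask, rmask = int(q_max[col]), int(r_union[col])
        sites.append(DiagnosticSite(
            column=int(col),
            query_state=StateSet.from_mask(qmask),
            reference_union=StateSet.from_mask(rmask),
            category=_classify_masks(qmask, rmask),
        ))
    return sites


def _mask_terminal_gaps(mat: np.ndarray, alignment: MultipleAlignment
                        ) -> np.ndarray:
    """Turn leading/trailing gap runs of each record into missing cells."""
    mat = mat.copy()
    for i, rec in enumerate(alignment.records):
        seq = rec.sequence
        lead = len(seq) - len(seq.lstrip("-"))
        trail = len(seq) - len(seq.rstrip("-"))
        if lead:
            mat[i, :lead] = MISSING
        if trail:
            mat[i, len(seq) - trail:] = MISSING
    return mat


def merge_events(sites: Sequence[DiagnosticSite]) -> list[MdcEvent]:
    """Merge sorted diagnostic sites into maximal consecutive-column events."""
    cols = [s.column for s in sites]
    if any(b <= a for a, b in zip(cols, cols[1:])):
        raise ValueError("sites must be sorted by column without duplicates")
    events: list[MdcEvent] = []
    run: list[DiagnosticSite] = []
    for site in sites:
        if run and site.column != run[-1].column + 1:
            events.append(_close_run(run))
            run = []
        run.append(site)
    if run:
        events.append(_close_run(run))
    return events


def _close_run(run: list[DiagnosticSite]) -> MdcEvent:
    start, end = run[0].column, run[-1].column + 1
    cats = {s.category for s in run}
    if len(run) == 1:
        etype = run[0].category
    elif cats == {"substitution"}:
        etype = "multi_substitution"
    elif cats == {"deletion"}:
        etype = "multi_deletion"
    elif cats == {"insertion"}:
        etype = "multi_insertion"
    else:
        etype = "multi_mixed"
    return MdcEvent(start=start, end=end, event_type=etype)


def species_mdc_profile(alignment: MultipleAlignment, species: str,
                        policy: str = "ignore",
                        mask_terminal_gaps: bool = False,
                        keep_sites: bool = True) -> SpeciesProfile:
    """Full MDC profile of one species against its congeners.

    ``mdc_count`` counts diagnostic *columns* (sites); the tally partitions
    those sites by the type of the event containing them, so the tally sums
    to ``mdc_count``.
    """
    partition = SpeciesPartition.for_query(alignment, species)
    sites = find_diagnostic_sites(alignment, partition, policy=policy,
                                  mask_terminal_gaps=mask_terminal_gaps)
    events = merge_events(sites)
    tally: Counter = Counter()
    for ev in events:
        tally[ev.event_type] += ev.length
    return SpeciesProfile(
        genus=alignment.genus,
        species=species,
        n_specimens=len(alignment.rows_of(species)),
        mdc_count=len(sites),
        events=events,
        type_tally=tally,
        sites=sites if keep_sites else [],
    )


def genus_profiles(alignment: MultipleAlignment, policy: str = "ignore",
                   mask_terminal_gaps: bool = False,
                   min_species: int = 3) -> list[SpeciesProfile]:
    """MDC profiles for every species of a genus alignment.

    Enforces the study inclusion rule: the genus must contain at least
    ``min_species`` species.
    """
    species = alignment.species
    if len(species) < min_species:
        raise ValueError(
            f"genus {alignment.genus!r} has {len(species)} species; "
            f"at least {min_species} required")
    return [species_mdc_profile(alignment, sp, policy=policy,
                                mask_terminal_gaps=mask_terminal_gaps)
            for sp in species]


def profiles_table(profiles: Iterable[SpeciesProfile]):
    """Per-species MDC table (one row per species, 8 event-type site counts)."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {
            "genus": p.genus, "species": p.species,
            "n_specimens": p.n_specimens,
            "mdc_sites": p.mdc_count, "n_events": len(p.events),
        }
        for t in EVENT_TYPES:
            row[f"sites_{t}"] = p.type_tally.get(t, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def events_table(profiles: Iterable[SpeciesProfile]):
    """BED-like per-event table (0-based half-open columns)."""
    import pandas as pd

    rows = [
        {"genus": p.genus, "species": p.species, "start": e.start,
         "end": e.end, "length": e.length, "event_type": e.event_type}
        for p in profiles for e in p.events
    ]
    return pd.DataFrame(
        rows, columns=["genus", "species", "start", "end", "length",
                       "event_type"])
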