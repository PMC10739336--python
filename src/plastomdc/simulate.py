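"""Synthetic genus alignments and genus cohorts with planted ground truth.

The generator emulates the structure of per-genus whole-plastome
alignments: a random backbone shared by every specimen, species-specific
variation events planted at known coordinates (substitutions, deletions,
insertions, mixed columns), within-species polymorphism, injected N-runs
(assembly gaps), and optional "twin" species forced identical — species
that, by construction, can never be diagnosed.

Insertions are represented in alignment space (gap columns in every
*non-focal* species) because the pipeline consumes aligned input; no
realignment is simulated, which keeps the planted truth exact.

Everything is driven by a single integer seed and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentRecord, MultipleAlignment
from .iupac import StateSet

BASES = np.array(list("ACGT"))

EVENT_KINDS = ("substitution", "deletion", "insertion", "mixed")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth variation event planted for one species."""

    species: str
    start: int
    length: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if self.length < 1 or self.start < 0:
            raise ConfigError("event must have start >= 0 and length >= 1")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def expected_event_type(self) -> str:
        return self.kind if self.length == 1 else f"multi_{self.kind}"


@dataclass
class GenusSimConfig:
    genus: str = "Genus"
    n_species: int = 3
    specimens_per_species: int | Sequence[int] = 2
    backbone_length: int = 10_000
    planted: list[PlantedEvent] = field(default_factory=list)
    polymorphism_rate: float = 0.0
    missing_rate: float = 0.0
    missing_run_mean: float = 50.0
    twin_species: Optional[tuple[str, str]] = None
    seed: int = 0

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def specimens_of(self, idx: int) -> int:
        if isinstance(self.specimens_per_species, int):
            return self.specimens_per_species
        return int(self.specimens_per_species[idx])

    def validate(self) -> None:
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3 (study inclusion rule)")
        for r in (self.polymorphism_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must be in [0, 1]")
        names = set(self.species_names())
        twins = set(self.twin_species or ())
        by_species: dict[str, list[PlantedEvent]] = {}
        for ev in self.planted:
            if ev.species not in names:
                raise ConfigError(f"planted event for unknown species "
                                  f"{ev.species!r}")
            if ev.species in twins:
                raise ConfigError(
                    f"twin species {ev.species!r} cannot carry planted "
                    "events (twins are identical by definition)")
            if ev.end > self.backbone_length:
                raise ConfigError(f"event {ev} exceeds backbone length")
            if ev.kind == "mixed" and self.n_species < 5:
                raise ConfigError(
                    "mixed events need >= 5 species: two references share "
                    "the gap and two share the backbone base, so neither "
                    "side of the reference set becomes diagnosable itself")
            by_species.setdefault(ev.species, []).append(ev)
        for sp, evs in by_species.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start <= a.end:  # must be separated by >= 1 column
                    raise ConfigError(
                        f"{sp}: events {a} and {b} overlap or touch")
        # events of different species must not share columns, otherwise the
        # planted states interact and the truth list stops being exact
        all_evs = sorted(self.planted, key=lambda e: e.start)
        for a, b in zip(all_evs, all_evs[1:]):
            if b.start < a.end:
                raise ConfigError(
                    f"events {a} and {b} of different species overlap")
        if self.polymorphism_rate > 0:
            for i in range(self.n_species):
                if self.specimens_of(i) < 2:
                    raise ConfigError(
                        "polymorphism requires >= 2 specimens per species so "
                        "specimen-private changes stay below species level")
        if self.twin_species is not None:
            a, b = self.twin_species
            if a not in names or b not in names or a == b:
                raise ConfigError(f"invalid twin pair {self.twin_species}")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def generate_genus(config: GenusSimConfig
                   ) -> tuple[MultipleAlignment, list[PlantedEvent]]:
    """Build one genus alignment plus its planted truth.

    All specimens share a random backbone; each planted event is applied to
    every specimen of its species (insertions instead gap all *other*
    species; a mixed column changes the focal species and gaps one
    reference species).  Twin species are copied cell-for-cell after
    planting, so they are guaranteed indistinguishable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.backbone_length
    backbone = BASES[rng.integers(4, size=L)]
    species = config.species_names()

    # per-species base rows (species-level state before specimen copies)
    rows = {sp: backbone.copy() for sp in species}
    for ev in config.planted:
        focal = ev.species
        for col in range(ev.start, ev.end):
            if ev.kind == "substitution":
                rows[focal][col] = _other_base(rng, backbone[col])
            elif ev.kind == "deletion":
                rows[focal][col] = "-"
            elif ev.kind == "insertion":
                for sp in species:
                    if sp != focal:
                        rows[sp][col] = "-"
            else:  # mixed: focal differs, two other species gapped (two, so
                # the gapped references share the gap and stay undiagnosable)
                rows[focal][col] = _other_base(rng, backbone[col])
                others = [sp for sp in species if sp != focal]
                gapped = rng.choice(len(others), size=2, replace=False)
                for gi in gapped:
                    rows[others[int(gi)]][col] = "-"

    if config.twin_species is not None:
        a, b = config.twin_species
        rows[b] = rows[a].copy()

    # expand to specimens; add specimen-private polymorphism and N-runs
    records: list[AlignmentRecord] = []
    truth = sorted(config.planted, key=lambda e: (e.species, e.start))
    for si, sp in enumerate(species):
        n_spec = config.specimens_of(si)
        spec_rows = [rows[sp].copy() for _ in range(n_spec)]
        if config.polymorphism_rate > 0:
            hits = rng.random((n_spec, L)) < config.polymorphism_rate
            # never hit all specimens of a species at one column: a fully
            # shared private change would be a new species-level state
            full = hits.all(axis=0)
            hits[rng.integers(n_spec, size=int(full.sum())), np.flatnonzero(full)] = False
            for k in range(n_spec):
                for col in np.flatnonzero(hits[k]):
                    cur = spec_rows[k][col]
                    spec_rows[k][col] = (_other_base(rng, cur)
                                         if cur != "-" else "-")
        if config.missing_rate > 0:
            for k in range(n_spec):
                if rng.random() < config.missing_rate:
                    run = 1 + rng.geometric(1.0 / config.missing_run_mean)
                    start = int(rng.integers(L))
                    spec_rows[k][start:start + run] = "N"
        for k, row in enumerate(spec_rows, start=1):
            records.append(AlignmentRecord(config.genus, sp, f"{sp}-{k:02d}",
                                           "".join(row)))
    return MultipleAlignment(records), truth


def expected_tally(truth: Sequence[PlantedEvent], species: str) -> dict:
    """Planted site counts per event type for one species (rates 0)."""
    tally: dict[str, int] = {}
    for ev in truth:
        if ev.species == species:
            t = ev.expected_event_type
            tally[t] = tally.get(t, 0) + ev.length
    return tally


def surviving_truth(alignment: MultipleAlignment,
                    truth: Sequence[PlantedEvent],
                    policy: str = "ignore") -> dict[str, set[int]]:
    """Planted diagnostic columns still valid on the realised alignment.

    Re-evaluates the pure-diagnostic-site definition cell-by-cell at every
    planted column (an independent path from the vectorised scanner):
    polymorphism may break query monomorphism or re-introduce a query state
    into the references; N-runs may silence a side entirely.
    Returns ``{species: set of surviving planted columns}``.
    """
    out: dict[str, set[int]] = {}
    species_rows = {sp: alignment.rows_of(sp) for sp in alignment.species}
    for ev in truth:
        cols = out.setdefault(ev.species, set())
        q_rows = species_rows[ev.species]
        r_rows = [i for sp, rws in species_rows.items()
                  if sp != ev.species for i in rws]
        for col in range(ev.start, ev.end):
            q_states = [StateSet.from_symbol(alignment.records[i].sequence[col],
                                             policy) for i in q_rows]
            r_states = [StateSet.from_symbol(alignment.records[i].sequence[col],
                                             policy) for i in r_rows]
            q_live = [s for s in q_states if not s.missing]
            r_live = [s for s in r_states if not s.missing]
            if not q_live or not r_live:
                continue
            if len({s.states for s in q_live}) != 1:
                continue  # query-polymorphic
            r_union = frozenset().union(*(s.states for s in r_live))
            if q_live[0].states & r_union:
                continue
            cols.add(col)
    return out


@dataclass
class CohortTruth:
    intercept_species: float
    slope_species: float
    slope_identity: float


def generate_cohort(n_genera: int,
                    slope_species: float = 0.028,
                    slope_identity: float = -0.055,
                    intercept: float = 6.0,
                    seed: int = 0) -> tuple[pd.DataFrame, CohortTruth]:
    """Genus-level summary table drawn from a known Poisson log-link model.

    Each genus gets a species count (3..41, the observed range of the
    study system), a specimen count and a mean pairwise identity; its MDC
    sum is drawn Poisson with
    ``log mu = intercept + slope_species * log10(n_species)
               + slope_identity * identity``.
    Used for parameter-recovery tests of the GLM layer.
    """
    if n_genera < 10:
        raise ConfigError("n_genera must be >= 10")
    rng = np.random.default_rng(seed)
    n_species = rng.integers(3, 42, size=n_genera)
    n_specimens = n_species + rng.integers(0, 40, size=n_genera)
    identity = rng.uniform(97.0, 100.0, size=n_genera)
    habitat = rng.choice(["open", "woodland", "mixed"], size=n_genera)
    log_mu = (intercept + slope_species * np.log10(n_species)
              + slope_identity * identity)
    # centre the identity term so counts stay in a realistic range
    log_mu = log_mu - slope_identity * 98.5
    mdc_sum = rng.poisson(np.exp(log_mu))
    columns = rng.integers(9_000, 13_000, size=n_genera)
    mean = mdc_sum / n_species
    df = pd.DataFrame({
        "genus": [f"genus{i + 1:03d}" for i in range(n_genera)],
        "family": "FamilyA",
        "n_species_analyzed": n_species,
        "n_specimens": n_specimens,
        "alignment_columns": columns,
        "mdc_sum": mdc_sum,
        "mdc_mean": mean,
        "mdc_per_length_e4": mean / columns * 1e4,
        "mean_identity_pct": identity,
        "habitat": habitat,
    })
    return df, CohortTruth(intercept_species=intercept,
                           slope_species=slope_species,
                           slope_identity=slope_identity)


def random_planted_config(rng: np.random.Generator,
                          genus: str = "Genus",
                          polymorphism_rate: float = 0.0,
                          missing_rate: float = 0.0) -> GenusSimConfig:
    """Draw a random valid GenusSimConfig with random planted events."""
    n_species = int(rng.integers(3, 7))
    specimens = int(rng.integers(2, 4))
    length = int(rng.integers(500, 2_001))
    cfg = GenusSimConfig(
        genus=genus, n_species=n_species,
        specimens_per_species=specimens, backbone_length=length,
        polymorphism_rate=polymorphism_rate, missing_rate=missing_rate,
        seed=int(rng.integers(2 ** 31)),
    )
    planted: list[PlantedEvent] = []
    taken: list[tuple[int, int]] = []  # global: events never share columns
    kinds = EVENT_KINDS if n_species >= 5 else EVENT_KINDS[:3]
    for sp in cfg.species_names():
        n_events = int(rng.integers(0, 6))
        for _ in range(n_events):
            ln = int(rng.integers(1, 7))
            for _attempt in range(20):
                start = int(rng.integers(0, length - ln))
                if all(start + ln < s or start > e for s, e in taken):
                    taken.append((start, start + ln))
                    kind = kinds[int(rng.integers(len(kinds)))]
                    planted.append(PlantedEvent(sp, start, ln, kind))
                    break
    return replace(cfg, planted=planted)


def truth_table(truth: Sequence[PlantedEvent], genus: str) -> pd.DataFrame:
    """Planted events in the BED-like event-table schema."""
    return pd.DataFrame([
        {"genus": genus, "species": ev.species, "start": ev.start,
         "end": ev.end, "length": ev.length,
         "event_type": ev.expected_event_type}
        for ev in sorted(truth, key=lambda e: (e.species, e.start))
    ], columns=["genus", "species", "start", "end", "length", "event_type"])
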