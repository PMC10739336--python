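"""Per-genus aggregation of species MDC profiles.

Produces the master genus table: MDC sum/mean/min/max across the species of
a genus, the per-alignment-length normalisation (mean MDCs per 10 kb of
alignment, i.e. mean / columns x 1e4), mean pairwise identity, the share of
species with zero MDCs (species unidentifiable from the whole plastome),
and representativeness (species analysed as a percentage of species
described for the genus).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import MultipleAlignment
from .identity import IdentityResult
from .mdc import SpeciesProfile

log = logging.getLogger(__name__)

HABITATS = ("open", "woodland", "mixed")

#: per-species MDC count bins used in the diversity barplot
BIN_LABELS = ("0", "1-10", "11-100", ">100")


@dataclass
class GenusMetadata:
    genus: str
    family: str = ""
    habitat: str = ""  # one of HABITATS, or "" when unknown
    described_species: Optional[int] = None


@dataclass
class GenusSummary:
    genus: str
    family: str
    n_species_analyzed: int
    n_specimens: int
    alignment_columns: int
    mdc_sum: int
    mdc_mean: float
    mdc_min: int
    mdc_max: int
    mdc_per_length_e4: float
    mean_identity_pct: float
    zero_mdc_share_pct: float
    representativeness_pct: Optional[float]
    habitat: str


@dataclass
class SpeciesBinCounts:
    bins: tuple[int, int, int, int]  # {0, 1-10, 11-100, >100}

    @property
    def total(self) -> int:
        return sum(self.bins)


def summarize_genus(profiles: Sequence[SpeciesProfile],
                    identity: IdentityResult,
                    alignment_columns: int,
                    metadata: Optional[GenusMetadata] = None,
                    min_species: int = 3) -> GenusSummary:
    """Aggregate one genus (inclusion rule: >= ``min_species`` species)."""
    if len(profiles) < min_species:
        raise ValueError(f"genus needs >= {min_species} species, "
                         f"got {len(profiles)}")
    counts = np.array([p.mdc_count for p in profiles])
    genus = profiles[0].genus
    if metadata is None:
        log.warning("%s: no metadata; habitat/representativeness left blank",
                    genus)
        metadata = GenusMetadata(genus=genus)
    mean = float(counts.mean())
    rep = None
    if metadata.described_species:
        rep = len(profiles) / metadata.described_species * 100.0
    return GenusSummary(
        genus=genus,
        family=metadata.family,
        n_species_analyzed=len(profiles),
        n_specimens=sum(p.n_specimens for p in profiles),
        alignment_columns=alignment_columns,
        mdc_sum=int(counts.sum()),
        mdc_mean=mean,
        mdc_min=int(counts.min()),
        mdc_max=int(counts.max()),
        mdc_per_length_e4=mean / alignment_columns * 1e4,
        mean_identity_pct=identity.mean_identity_pct,
        zero_mdc_share_pct=float((counts == 0).mean() * 100.0),
        representativeness_pct=rep,
        habitat=metadata.habitat,
    )


def bin_species(profiles: Sequence[SpeciesProfile]) -> SpeciesBinCounts:
    """Histogram of per-species MDC counts over {0, 1-10, 11-100, >100}."""
    counts = [p.mdc_count for p in profiles]
    return SpeciesBinCounts(bins=(
        sum(c == 0 for c in counts),
        sum(1 <= c <= 10 for c in counts),
        sum(11 <= c <= 100 for c in counts),
        sum(c > 100 for c in counts),
    ))


def subsample_species(alignment: MultipleAlignment, max_specimens: int,
                      seed: int) -> MultipleAlignment:
    """Randomly cap the number of specimens per species (reproducible).

    Species at or below the cap are untouched; record order of the retained
    specimens is preserved.
    """
    if max_specimens < 1:
        raise ValueError("max_specimens must be >= 1")
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for sp in alignment.species:
        rows = alignment.rows_of(sp)
        if len(rows) > max_specimens:
            chosen = rng.choice(len(rows), size=max_specimens, replace=False)
            keep.update(rows[i] for i in sorted(chosen))
        else:
            keep.update(rows)
    return alignment.subset(sorted(keep))


def summaries_table(summaries: Sequence[GenusSummary]) -> pd.DataFrame:
    """Master per-genus TSV-ready table (one row per genus)."""
    rows = []
    for s in summaries:
        rows.append({
            "genus": s.genus, "family": s.family,
            "n_species_analyzed": s.n_species_analyzed,
            "n_specimens": s.n_specimens,
            "alignment_columns": s.alignment_columns,
            "mdc_sum": s.mdc_sum, "mdc_mean": s.mdc_mean,
            "mdc_min": s.mdc_min, "mdc_max": s.mdc_max,
            "mdc_per_length_e4": s.mdc_per_length_e4,
            "mean_identity_pct": s.mean_identity_pct,
            "zero_mdc_share_pct": s.zero_mdc_share_pct,
            "representativeness_pct": s.representativeness_pct,
            "habitat": s.habitat,
        })
    return pd.DataFrame(rows)


def read_metadata(path) -> dict[str, GenusMetadata]:
    """Genus metadata TSV: genus, family, habitat, described_species."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        ds = row.get("described_species")
        out[row["genus"]] = GenusMetadata(
            genus=row["genus"],
            family=str(row.get("family", "") or ""),
            habitat=str(row.get("habitat", "") or ""),
            described_species=None if pd.isna(ds) else int(ds),
        )
    return out
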