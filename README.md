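# plastomdc

Molecular diagnostic characters (MDCs) in per-genus plastome alignments:
identification, event classification, diversity summaries and association
tests.

## The problem

Whole chloroplast genomes ("super-barcodes") are increasingly used to tell
closely related plant species apart when short barcode loci fail.  The
operational question is simple: given a multiple sequence alignment of
plastomes from one genus, which alignment columns are *diagnostic* for a
species — and how many species have none at all, making them
unidentifiable from plastome sequence alone?

`plastomdc` implements that analysis end-to-end for anyone working with
per-genus whole-plastome alignments (or any long alignments with multiple
specimens per species):

* **Preprocessing** — detect the quadripartite plastome structure
  (LSC–IRb–SSC–IRa) by seed-and-extend inverted-repeat search and excise
  the duplicated IR copy, so IR mutations are not counted twice.
* **MDC scan** — for each species *q* in a genus alignment, find every
  *pure diagnostic site*: a column where all specimens of *q* share one
  state `S(q)` with `S(q) ∩ ⋃_{r≠q} S(r) = ∅`.  The gap `-` is a
  character state; IUPAC ambiguity codes expand to their nucleotide sets;
  `N`/`?` are missing data.  Columns polymorphic within *q* are excluded
  by definition.
* **Event classification** — maximal runs of consecutive diagnostic
  columns form one variation event with one of 8 types: substitution,
  deletion, insertion, mixed, and their `multi_*` counterparts for runs of
  length ≥ 2 (heterogeneous runs are `multi_mixed`).
* **Genus summaries** — MDC sum/mean/min/max per genus, MDCs per 10 kb of
  alignment (mean ÷ columns × 10⁴), mean pairwise identity, consensus
  sequence, share of zero-MDC species, representativeness versus the
  number of described species.
* **Inferential layer** — Shapiro–Wilk/skewness screening, log-link
  Poisson GLMs of the count summaries on log₁₀-scaled predictors
  (number of species, number of specimens, identity), and Kruskal–Wallis
  with Dunn–Bonferroni post-hoc tests across habitat categories
  (open / woodland / mixed).
* **Synthetic data** — a generator that plants species-specific events at
  known coordinates (plus within-species polymorphism, N-runs and
  identical "twin" species), so every stage is testable against exact
  ground truth without any downloads.

## Worked example

```python
from plastomdc import (GenusSimConfig, PlantedEvent, generate_genus,
                       species_mdc_profile, mean_pairwise_identity)

cfg = GenusSimConfig(
    genus="Stipa", n_species=4, specimens_per_species=2,
    backbone_length=10_000,
    planted=[
        PlantedEvent("sp1", 1200, 1, "substitution"),
        PlantedEvent("sp1", 4500, 3, "deletion"),
        PlantedEvent("sp2", 7300, 2, "insertion"),
    ],
    twin_species=("sp3", "sp4"),
    seed=11,
)
aln, truth = generate_genus(cfg)
print(f"alignment: {aln.n_records} specimens x {aln.n_columns} columns")
for sp in aln.species:
    p = species_mdc_profile(aln, sp)
    events = ", ".join(f"{e.event_type}[{e.start}:{e.end}]"
                       for e in p.events) or "none"
    print(f"{sp}: {p.mdc_count} MDC sites; events: {events}")
ident = mean_pairwise_identity(aln)
print(f"mean pairwise identity: {ident.mean_identity_pct:.3f}% "
      f"over {ident.n_pairs} pairs")
```

prints

```
alignment: 8 specimens x 10000 columns
sp1: 4 MDC sites; events: substitution[1200:1201], multi_deletion[4500:4503]
sp2: 2 MDC sites; events: multi_insertion[7300:7302]
sp3: 0 MDC sites; events: none
sp4: 0 MDC sites; events: none
mean pairwise identity: 99.974% over 28 pairs
```

`sp1` is recovered with exactly the planted single substitution and the
3-column deletion (one `multi_deletion` event); `sp2` with its 2-column
insertion.  The twins `sp3`/`sp4` are sequence-identical, so neither has a
single diagnostic column — the "zero-MDC species" phenomenon that makes
some species unidentifiable even from a complete plastome.  Mean pairwise
identity is near 100% because only 6 of 10,000 columns vary.

## Command line

```bash
plastomdc prep genomes.fasta stripped.fasta --min-ir-length 1000 --circular
plastomdc simulate --config sim.yaml --out genus.fasta --truth truth.tsv
plastomdc mdc --alignment genus.fasta --missing ignore
plastomdc summarize --alignment genus.fasta --metadata meta.tsv --out row.tsv
plastomdc stats --summary genus_summary.tsv --out stats.json
plastomdc run-all --config run.yaml
```

Alignment headers follow `>Genus_species|specimen_id` (configurable via
`--header-regex`).  `run-all` consumes a YAML manifest (genus → aligned
FASTA) plus a metadata TSV (`genus, family, habitat, described_species`)
and writes per-species/per-event tables, the master genus TSV, a consensus
FASTA, a stats JSON and a run log; re-runs with the same config are
byte-identical.

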