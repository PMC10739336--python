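# Methods

## Diagnostic-site model

For a genus alignment with species set `S` and `n` columns, every cell is
reduced to a subset of the canonical states `{A, C, G, T, -}`.  IUPAC
ambiguity codes expand to their nucleotide sets (`R → {A,G}`, …); the gap
`-` is a first-class character state; `N` and `?` are missing data under
the default policy and contribute nothing at their column.  A column `c`
is a *pure diagnostic site* (MDC) for query species `q` when

1. every non-missing specimen of `q` carries one identical state set
   `S_q(c)` (columns where specimens of `q` disagree are
   *query-polymorphic* and excluded, so `{R, R}` is monomorphic while
   `{R, A}` is not),
2. `S_q(c)` is disjoint from the union of all non-missing reference
   cells, and
3. both sides have at least one non-missing specimen (otherwise the
   column is skipped and logged).

The site category follows from gap membership of the two sides: `deletion`
(query is the gap, references gap-free), `insertion` (the mirror case),
`substitution` (no gap on either side), `mixed` (gap and nucleotide signal
co-occur across the two sides).  Maximal runs of consecutive diagnostic
columns of one species are merged into a single *event*; runs of length
≥ 2 take the `multi_` prefix, and heterogeneous runs (or any run
containing a mixed column) are `multi_mixed`.  Site counts, not event
counts, are the primary "number of MDCs" statistic; the per-type tally
partitions sites by the type of the event containing them, so it always
sums to the site count.

An alternative `strict` missing policy expands `N`/`?` to `{A,C,G,T}`,
which lets a single low-coverage genome veto diagnostic sites; both
policies are exposed because the convention used by spreadsheet-style
diagnostic-character tools is rarely documented.  Terminal gap runs
(alignment end-trim artefacts) are ordinary gap states by default; a
`mask_terminal_gaps` switch converts them to missing for sensitivity
analysis.

The vectorised scanner is validated against an exhaustive per-column
brute-force implementation (independent code path, its own IUPAC table)
on hundreds of randomized alignments per test run, under both missing
policies.

## Inverted-repeat handling

Plastomes are circular and typically quadripartite (LSC–IRb–SSC–IRa, IR
arms ~20–25 kb and near-identical).  Keeping both IR copies in a
comparative alignment counts every IR mutation twice, so the default
preprocessing removes one copy (the arm following the SSC in cyclic
order); a `remove="both"` flag drops the retained copy as well.

Detection is seed-and-extend: exact k-mer matches (k = min(16,
min_ir_length/4), floor 8) between the sequence and its reverse
complement, grouped by the anti-diagonal invariant `i + j`, greedily
extended outward and inward under a mismatch budget
(`max_mismatch_frac`, default 0.02 of the current arm length).  The
longest qualifying arm pair wins; ties break by smallest start
coordinate.  Circular sequences are scanned doubled with coordinates
reduced modulo the length, which makes detection rotation-invariant; one
anti-diagonal of the doubled string can carry seeds of distinct image
pairings of the same repeat, so all seeds are kept and those already
covered by an extended pair are skipped.  Defaults: `min_ir_length`
1000 bp (real IRs are far larger; toys scale down), mismatch budget 2%.

Region naming: the longer single-copy region is LSC; intervals are
0-based half-open in circular coordinates (the LSC may wrap through the
origin).  Removal rotates the genome to the LSC start and drops the
trailing IRa, so output length = input − ir_length; removal then
re-detection finds nothing, and detect→remove is idempotent.  SSC
orientation is not normalised.  With a greedy extension and a nonzero
mismatch budget the reported arm can slightly overrun a "planted" repeat
by absorbing chance flanking complements — exact-recovery tests therefore
run with a zero budget and guard bases.

## Identity and consensus

Pairwise identity of two aligned sequences is the percentage of identical
symbols over comparable columns: columns gapped in both sequences are not
comparable, a gap against a residue is a mismatch (default
`gap_mode="mismatch"`), and columns with `N`/`?` in either sequence are
never compared; `gap_mode="exclude"` instead drops every gap-touching
column.  The genus value is the mean over all unordered *specimen* pairs
(the alignment is the unit of analysis, not species means).

The consensus is a per-column plurality vote over the literal states
`{A, C, G, T, -}`; missing and ambiguity symbols abstain.  Ties break by
the fixed order `A < C < G < T < -`; columns won by the gap are dropped
from the emitted sequence (support is recorded before dropping); an
all-abstaining column emits `N` with support 0.  Plurality (rather than a
strict 50% threshold) guarantees a fully resolved sequence for downstream
realignment and tree building.  Note that adding a single duplicated
record *can* legitimately change the consensus at tied columns; the
invariants that do hold — and are tested — are that duplicating the whole
alignment, or a record that agrees with every winner, changes nothing.

## Genus summaries

Per genus: MDC sum, mean, min, max over species; `mdc_per_length_e4` =
mean per-species MDC sites ÷ alignment columns × 10⁴ (MDCs per 10 kb of
alignment — the normalisation is a convention and trivially rescalable);
zero-MDC share = percentage of species with no diagnostic column
anywhere; representativeness = species analysed ÷ species described
× 100.  Genera need ≥ 3 species to be analysed (the study inclusion
rule).  Species are binned by MDC count into {0, 1–10, 11–100, > 100};
the middle edge (11–100) completes the named outer bins exhaustively.
Species with more than `max_specimens` specimens (default 50) are
randomly, reproducibly downsampled.

## Inferential layer

The genus-level count summaries are strongly right-skewed, so
associations are modelled as log-link Poisson regressions of the outcome
on a log₁₀-scaled predictor.  Reported per model: slope and its standard
error, the Wald statistic (squared z, χ²₁), its p-value, the model
log-likelihood, and the likelihood-ratio χ² against the intercept-only
model.  The log base is a reporting convention only (the slope rescales
by ln 10); the natural-log slope is included in the output.  Quasi-count
outcomes (per-genus means) are rounded to the nearest integer by default
so the Poisson likelihood is exact; `round_y=False` (CLI `--no-round`)
fits them verbatim.  Fitting is delegated to `statsmodels`; the test
suite checks it against an independent IRLS solver to 6 decimals and
verifies Wald-test calibration by null simulation.

Habitat categories are compared with a tie-corrected Kruskal–Wallis test
(scipy) followed by Dunn's pairwise z tests on the pooled ranks,

```
z_ab = (R̄_a − R̄_b) / sqrt((N(N+1)/12 − T/(12(N−1))) (1/n_a + 1/n_b)),
```

with `T = Σ(t³ − t)` over tied groups and Bonferroni-adjusted two-sided
p-values capped at 1 (the adjustment is what produces p = 1.000 for
clearly null pairs).  Dunn's test is implemented in-package because no
installed library provides it; it is cross-checked against an independent
rank computation in the tests.  Groups with fewer than 2 observations are
excluded with a warning.

Shapiro–Wilk and the adjusted Fisher–Pearson skewness (scipy, `bias=False`)
serve as the normality gate that motivates the GLM choice; a constant
vector is rejected as degenerate.

## Synthetic-data generator

`generate_genus` emulates the *structure* of a per-genus plastome
alignment: one random backbone shared by all specimens, species-level
planted events, specimen-level noise.  Event semantics in alignment
space:

* substitution — the focal species gets a different base at the column;
* deletion — the focal species is gapped;
* insertion — every *other* species is gapped (the pipeline consumes
  aligned input, so insertions live as gap columns in the references; no
  realignment is simulated, which keeps the planted truth exact);
* mixed — the focal species gets a new base while exactly two reference
  species are gapped.  Two on each side is the minimal geometry that
  keeps the references themselves non-diagnosable (a lone gapped — or
  lone base-carrying — reference would acquire a unique state), which is
  why mixed events require ≥ 5 species.

Planted events of one species are separated by ≥ 1 column (adjacent
events would merge into one run) and events of different species never
share columns (planted states would otherwise interact); both are
config-validation errors.  Twin species are copied cell-for-cell after
planting and may not carry planted events — they are the exact
construction of the zero-MDC phenomenon.

Within-species polymorphism flips specimen-private bases at a per-cell
rate.  It requires ≥ 2 specimens per species, and never hits all
specimens of a species at one column, so a private change can break a
planted site (query polymorphism, or re-introducing a query state into
the references) but can never *create* a new species-level diagnostic
state.  The surviving truth after polymorphism/missing injection is
recomputed per planted column by an independent cell-by-cell evaluation
(`surviving_truth`), and recovery tests assert exact agreement with it.
Missing data are injected as contiguous N-runs (assembly-gap style),
geometric length with mean 50.

Defaults emulate the study conditions at desk scale: ≥ 3 species per
genus, multiple specimens per species, a 10 kb backbone standing in for
~130 kb plastome alignments (configurable up to full scale), species
counts of 3–41 per genus and mean identities of 97–100% in the cohort
generator, and a planted species-count slope of 0.028 on the log₁₀ scale
— the magnitude the genus-level association analysis is expected to
recover.  What passing recovery tests show is that the *pipeline* is
exact on alignments whose truth is known by construction; the generator
deliberately does not model phylogenetic substitution processes,
realignment artefacts, rate heterogeneity, or mislabelled accessions, so
it says nothing about how often such artefacts produce spurious MDCs in
real GenBank data.

## Problem sizes and numerics

Test and acceptance runs use: 500 randomized alignments (≤ 6 species ×
≤ 4 specimens × ≤ 200 columns) for oracle equivalence; 100 random planted
configs (500–2000 columns) for exact recovery plus 25 with polymorphism;
1000 null replicates for Wald calibration (the rejection-rate estimate
then has Monte-Carlo sd ≈ 0.007 against the ±0.02 band) and 100 for
Kruskal–Wallis; n = 500 and a 96-genus cohort for slope recovery; 10–20
planted IR toys (~4 kb).  All randomness flows from explicit integer
seeds; reruns are byte-identical.

Known limitations: the IR detector is a greedy heuristic (no affine
gaps — arms with indel differences are truncated at the indel); the
consensus never emits ambiguity codes; Poisson GLMs ignore overdispersion
(no quasi-Poisson/negative-binomial option); the scan treats columns
independently, so codon structure and linkage are invisible; and external
alignment (e.g. MAFFT) and tree building are documented hand-off points,
not package responsibilities — `RunConfig.aligner_cmd` records the
command but the pipeline never invokes it.
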