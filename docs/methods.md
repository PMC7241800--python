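# Methods

This note documents the models, defaults and design choices behind
`barcodeqc`, in the order the pipeline runs them.

## Library assembly

Records are merged from any number of FASTA + metadata-TSV sources with
source tags preserved; duplicate `record_id`s across sources are a hard
error (the merge performs no silent reconciliation — records present in two
repositories under different identifiers are treated as distinct unless
their accessions match, since no reliable cross-identifier key exists).

Dereplication collapses records sharing an accession.  When duplicates
disagree on the species name, the name from the duplicate with the latest
`updated_date` wins — the rationale being that repository taxonomy is
corrected over time, so the newer annotation is the better bet.  When no
duplicate carries a date the first-seen name is kept and the conflict is
written to a conflicts report instead of being resolved silently.

The species-level filter removes open-nomenclature labels (`sp.`, `cf.`,
`aff.`, `nr.`, bare genus).  Trinomials pass: subspecies are legitimate,
separately diagnosable reference taxa (a curator can collapse them later
with the `collapse_subspecies` switch in the gap analysis).

Trimming anchors every record to a single ungapped reference barcode by
global pairwise alignment (match +1, mismatch −1, gap open −5, gap extend
−1, end gaps free; all configurable).  Columns outside the reference span
and insertions relative to the reference are discarded; uncovered reference
positions are padded with `-`.  This replaces a map-to-reference plus
multiple-alignment step; for a protein-coding, indel-poor marker like
*cox1* the reference-anchored pairwise route is deterministic,
dependency-free and yields the same fixed coordinate system.  Pre-aligned
input simply bypasses it.  The unmappable floor defaults to a score of
0.25 × reference length: a diverged but homologous fragment covering half
the barcode still scores well above it under the +1/−1 scheme, while
shuffled sequence scores near zero (the test suite calibrates this on
shuffled references).  The minimum-length filter counts informative
(A/C/G/T) columns and is strict: exactly 300 informative positions is kept.
Internally alignment coordinates are 0-based half-open; outputs are plain
1..L FASTA columns.

## K2P distances with pairwise deletion

For each pair, sites where either sequence carries anything outside
A/C/G/T are excluded; IUPAC ambiguity codes are treated as missing rather
than fractionally resolved, which matches the behaviour of the standard
distance implementations and keeps the per-site counting oracle exact.
Comparisons are case-insensitive and U equals T.  With P and Q the
transition and transversion proportions over the n surviving sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

The distance is *missing* (NaN) when n = 0 or either log argument is
non-positive (saturation).  Missing distances are excluded from density
estimation, gap statistics and neighbour searches, and are counted in the
matrix report; only the NJ stage imputes them (see below).  The engine is
vectorised row-against-remaining-rows, and is checked in the tests both
against a naive per-site Python oracle and against an independent
reference implementation (R's `ape::dist.dna`, model K80 with pairwise
deletion), which agree to output precision.

## Barcoding gap

Per sequence i: `max_intra(i)` is the largest defined distance to a
conspecific, `min_inter(i)` the smallest defined distance to an
allospecific; the gap is present iff `min_inter - max_intra > 0`.  A tie is
counted as absence — a query exactly equidistant from its own and another
species cannot be identified, so the conservative call is the meaningful
one; output headers state this convention.  Singletons default to
`max_intra = 0` (a species sampled once shows no intraspecific variation;
this is the convention of the standard distance-based gap analyses), with
an `exclude` policy available; singleton rows are always flagged.

The sampling-effect summary fits ordinary least squares of per-species
absence and presence counts on the number of sequences per species
(slope, intercept, adjusted R², p), with the all-absences-zero case
reported as the exact zero line, and estimates gaussian KDEs of the
sample-size distribution weighted by absence/presence counts.  Designs with
all species equally sampled are reported as degenerate rather than fitted.

## Threshold optimisation

All defined pairwise distances (after removing singleton species from the
library) enter a gaussian KDE with the R-`density()` default bandwidth
`0.9 min(sd, IQR/1.34) m^(-1/5)`, evaluated on a 512-point grid spanning
[min − 3 bw, max + 3 bw]; both bandwidth and grid size are configurable
because different density defaults shift the dip slightly.  Candidate
thresholds are grid points strictly below both neighbours; the default
selection is the smallest-distance minimum — the transition out of the
intraspecific mode — with a `deepest` alternative.  A unimodal density
raises an error directing the caller to a fixed threshold; the BOLD-style
1 % default is used whenever optimisation is disabled.

## Best close match

For query i, the best distance D is the minimum defined distance to any
other record.  D > threshold (or no defined neighbour) gives `no_id`.
Otherwise the species of the neighbours *tied at exactly D* form the match
set: `correct` if it equals {own species}, `incorrect` if the own species
is absent, `ambiguous` if present alongside others.  The strict tie set is
the default because it is the classical best-close-match definition; a
`within_threshold` variant widens the match set to every neighbour within
the threshold, for curators who prefer to flag near-ties as ambiguous.
Singletons are classifiable (never `correct`, having no conspecific),
which is deliberate: the fixed-threshold run keeps singletons and their
`no_id`/`incorrect` outcomes are informative.  The per-species summary
carries the minimum interspecific and maximum intraspecific distances
alongside the four category counts.

## Tree and cluster consistency

NJ is implemented with the rate-corrected Q criterion, deterministic
smallest-(row, column) tie-breaking and negative branch lengths clamped to
zero with the deficit moved to the sister edge (path lengths preserved).
On additive matrices it recovers the generating topology and branch
lengths exactly (tested on random 4–6-taxon trees).  Missing distances are
imputed at the matrix maximum for tree building only — they carry no
information beyond "far", and the imputation is logged; BCM and gap
statistics never see imputed values.

Monophyly is assessed on the unrooted tree via bipartitions (the libraries
have no outgroup): a species is monophyletic iff some edge separates
exactly its records.  Threshold clusters are single-linkage connected
components of the ≤-threshold graph (complete linkage available); a
cluster is heterogeneous when it mixes species labels.  Per species:
`tci` = full count if non-monophyletic; `cl_het` = its records in
heterogeneous clusters; `sp_split` = full count if it occupies ≥2 clusters
of which ≥1 is heterogeneous or the species is non-monophyletic;
`other_homog` = full count if it occupies ≥2 clusters that are all
homogeneous and it is monophyletic.  The last two are therefore mutually
exclusive: `other_homog` isolates deep-but-clean intraspecific structure
(e.g. geographic lineages) from patterns implicating label error.  The
exact combination rule is this package's own definition; published
tree-consistency tables do not print one.

## Revision and version comparison

Edits are applied as a batch: validation of every target precedes any
mutation (all-or-nothing), relabels to the current label are rejected, and
an audit frame maps each action to the pre-edit state.  Relabels are
invertible from the audit; removals are not.

Version comparison takes per-species correct ratios
(correct / total classified, species as the experimental unit), applies
the quotient transformation and runs a one-way fixed-effects ANOVA,
tolerating unbalanced designs.  One subtlety is documented prominently:
dividing each version's vector by *its own* mean forces every group mean
to exactly 1, so the between-version effect is absorbed and F ≈ 0 by
construction — useful only to demonstrate that pure scale differences
vanish.  Real cross-version inference therefore uses the pooled-mean
(`global`) normalisation, under which F is identical to the F of the raw
ratios.  Both variants are exposed; the degenerate all-equal case reports
F = 0, p = 1 rather than scipy's 0/0 artefact.

## Synthetic libraries

The simulator evolves a random root sequence along a star-of-stars
genealogy: one ancestor per species at depth `inter/2` from the root, tips
at depth `intra/2` from their ancestor, under the Kimura two-rate model
(closed-form transition/transversion substitution probabilities per
branch, κ = 2 by default).  Two conspecific tips are thus separated by an
expected `intra` substitutions/site and two allospecific tips by
`inter + intra`, and the K2P estimator is unbiased for these branch
lengths, enabling parameter-recovery tests.  Defaults follow the study
conditions the analyses assume: 20 species × 10 sequences × 658 bp, intra
0.01, inter 0.15 — a clearly bimodal distance distribution with a valley
an order of magnitude above the intraspecific mode, like a typical
single-genus *cox1* library.  Mislabeling swaps only the stored label
(sequences untouched), mirroring specimen misidentification; exactly
`round(f · N)` records are swapped, to another species uniformly at
random.  Ambiguous bases are injected per site with independent
probability to exercise pairwise deletion.  `heavy_tailed_counts`
generates geometric per-species sample sizes (singletons common, a long
right tail) emulating repository skew.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: rate variation among lineages and sites,
within-species population structure (every conspecific pair is exchangeable),
NUMTs, heteroplasmy, endosymbiont-mediated introgression, alignment error,
and the empirical messiness of repository metadata.  A star-of-stars
genealogy was chosen over a coalescent because the downstream analyses
consume only distances, for which the unimodal-intra/unimodal-inter
mixture is the relevant structure.

## Problem sizes

The test suite and the acceptance script run on simulated libraries of
50–200 records (up to 20 seeds for detection-rate averages and 100 seeds
for threshold placement); these sizes give stable averages for the
stochastic checks while keeping a full run in the low minutes.  The same
code paths scale to multi-thousand-record libraries — the distance stage
is the quadratic bottleneck and a 1502-record matrix takes on the order of
a minute.

## Known limitations

* Trimming assumes an indel-poor marker; for markers with frequent indels
  a true multiple alignment should be supplied pre-computed.
* The NJ stage is O(n³) in pure numpy; very large libraries (≫5k records)
  would want a dedicated implementation.
* `other_homog`/`sp_split` encode one defensible combination rule; other
  tree-consistency tools may partition the same pattern differently.
* Threshold optimisation inherits the KDE's sensitivity to bandwidth when
  the intra/inter modes are close; the candidate list, bandwidth and grid
  are all reported so the dip can be audited.
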