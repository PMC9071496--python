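# Methods

This note documents the statistical conventions, parameter defaults and design
choices of the `rbptm` pipeline, and what its synthetic cohort does and does
not demonstrate.

## Coordinates and identity

Residue positions are 1-based on the canonical (SwissProt-style) sequence;
isoform-specific positions are out of scope and inputs are assumed pre-mapped.
Genomic intervals (eCLIP peaks, gene models) are 0-based half-open, following
BED. A PTM site's identity is the key *(accession, position, PTM type)* — the
same residue carrying two modification types counts as two sites, matching
per-type counting throughout the analyses.

## Harmonization

Source catalogs are read through declared dialects (column mapping plus the
column/values that flag computational predictions, which are always dropped).
Modification labels pass through a versioned synonym table
(`rbptm/data/vocabulary.yaml`); labels that map to nothing are dropped with a
logged count, never passed silently. Merging is idempotent and independent of
catalog order: provenance records are deduplicated and stored sorted, and when
catalogs disagree on the residue letter with no sequence to arbitrate, the
lexicographically smallest reported residue is kept. When the proteome carries
a sequence, a site whose stated residue conflicts with it is dropped by default
(`residue_conflicts="keep"` trusts the catalog instead) — dropping is the safer
default because neither source can be verified. The atlas export writes the
published 11-column layout with `source` as the header name; a strict mode
reproduces the legacy header spelling (`Ssource`) verbatim. Both one-row-per-
evidence and one-row-per-site export modes exist because public PTM atlases
count entries either way; the per-evidence mode is the default and is the one
with a lossless re-import.

## Enrichment tests

For each PTM type with ≥1 modified protein, a 2×2 χ² test contrasts
"carries ≥1 site of the type" between RBPs and non-RBPs. The groups are
disjoint by default; a variant contrasting RBPs against *all* proteins (groups
then overlap) is behind a flag, since published analyses sometimes phrase the
contrast that way. The χ² statistic is computed without continuity correction
(the intended regime is thousands of proteins per margin); a Yates flag exists
for small tables. Bonferroni family size m is the number of PTM types tested;
a degenerate table (any zero margin) yields an undefined-flagged result rather
than an exception. Modification density uses the full protein length as
denominator, modified or not, and the RBP/non-RBP density contrast is a Welch
t-test.

## Conservation contrast

Scores are consumed per residue in [0, 1]; collapsing nucleotide-level tracks
(e.g. mean over the codon's three nucleotides) happens upstream of the package.
For each protein the background is 100 positions sampled uniformly from the
protein's scored residues excluding all PTM positions — without replacement
when the pool allows, with replacement (logged) otherwise. Ties between the
PTM mean and background mean count as *not* more conserved. Per-protein seeds
derive from (global seed, accession) by hashing, so cohort results do not
depend on processing order. The cohort KS test pools PTM scores and background
scores across proteins and uses the asymptotic two-sample statistic.

## ME/M/E classification

An enzyme "matches" a PTM type when annotated for it in either role — writer
(kinase-like) or eraser (phosphatase-like) — because downstream counts cover
both; a writer-only mode exists. Edges are undirected, deduplicated across
source databases by unordered pair, and self-loops are dropped, making all
counts invariant to direction flips and cross-database duplication. PTM types
deposited by direct chemistry rather than an enzyme (oxidation,
glutathionylation, sulfenylation in the shipped vocabulary) are excluded from
the E/ME logic; their cells can only be M or none. Interaction counts are
(modified RBP, matching enzyme neighbour) pairs, so one protein with three
kinase neighbours contributes three phosphorylation interactions.

## Proximity conventions

"Within k residues" is inclusive and symmetric (|Δ| ≤ k, default k = 10; the
boundary case distance 10 is in, 11 is out). Mutation results carry three
tallies — (mutation, site) pairs, deduplicated mutations, deduplicated
proteins — because published counts of the "N mutations in M proteins" form do
not state the counting unit.

Crosslink windows: center c = ⌊(start+end)/2⌋ (left-of-middle for even-length
ranges); the window is [c−10, c+10] intersected with [1, L] — clipped, never
shifted, so the center stays at the reported range's midpoint even at protein
ends. A PTM inside two overlapping windows contributes one record per window
to the distance bins but a single nearest-center distance to group contrasts.

The distance–frequency Spearman correlation is computed over the 11 distance
bins 0..10 (average ranks for ties), not over per-site records. A 21-residue
window offers one residue at distance 0 but two at every other distance, so
raw uniform placement would produce a structural positive correlation
(ρ = +0.5 in expectation) from the half-sized bin 0 alone. The package
therefore normalizes each bin count by its opportunity — the number of window
positions at that distance, summed over windows, which also accounts for
boundary clipping — before correlating; raw counts are reported alongside, and
passing `opportunities=None` correlates raw counts. All observations in a
single bin make ρ undefined (flagged); identical frequencies in every bin
yield the all-ties convention ρ = 0, flagged.

eCLIP: a replicate supports an (RBP, gene) pair when ≥1 of its peaks overlaps
the gene on the same strand with overlap/peak-length ≥ f (default 0.5, the
peak's own length as denominator); a call requires both replicates
independently — their peaks need not overlap each other.

## Analysis parameters

| parameter | default | units | role |
|---|---|---|---|
| `window_size` | 21 | residues | standardized crosslink window width (odd) |
| `proximity_k` | 10 | residues | mutation/PTM proximity radius, inclusive |
| `background_n` | 100 | positions | conservation background sample per protein |
| `overlap_fraction` | 0.5 | — | eCLIP peak-over-gene fraction threshold |
| `high_conservation_threshold` | 0.9 | score | "highly conserved" PTM-mean cutoff |
| `alpha` | 0.05 | — | significance level after Bonferroni |
| `seed` | 0 | — | master seed for all sampling |

## Synthetic cohort

The generator emulates the statistical structure the analyses assume, not real
biology: log-normal protein lengths (median ≈ 490 residues, floored at 50);
25% RBPs with 8% of them tagged "hnRNP"; per-type site rates (phosphorylation
0.010/residue down to sumoylation 0.001) multiplied by 5 on RBPs; five enzymes
per type with writer/eraser roles and enzyme–substrate edges at 0.3 when the
protein carries the type vs 0.02 otherwise; mutation rates of 0.02/residue
within 10 of a PTM site vs 0.002 elsewhere (10× hotspot); Poisson(2) crosslink
ranges per RBP with 70% of crosslink-study PTMs (95% on hnRNP-tagged proteins,
emulating the family's reported interface proximity) placed at geometric
offsets from window centers — offset d with P(d) = p(1−p)^d, p = 0.7, sign
uniform, redrawn up to 100 times if outside the protein — and the rest uniform;
Beta(2, 2) conservation scores with +0.2 at PTM sites (clipped to [0, 1]); and
a toy two-chromosome genome whose eCLIP replicates each carry one qualifying
peak per truly-bound gene plus 50 noise peaks. Sites are split into two
overlapping catalog files (with a 2% admixture of prediction-flagged rows) to
exercise deduplication and filtering.

These magnitudes were chosen once as clearly-detectable planted effects at
desk-scale cohort sizes; the default bundle (2000 proteins) generates in a few
seconds and the full pipeline completes in well under a minute on one CPU.
Sub-seeds derive from hash(master seed, module name), so regenerating one
module never perturbs another and bundles are byte-reproducible.

What passing tests on this cohort shows: the implementations are exact against
brute-force oracles, the test statistics are calibrated under the null
(type-I error ≈ 0.05; more-conserved fraction ≈ 0.5; |ρ| small under uniform
placement) and recover planted effects of the stated sizes. What it does not
show: behaviour on real catalogs — the generator has no sequence motifs, no
PPI degree heterogeneity, no correlated evidence between sources, no
mutational signatures, and uniform site placement outside the planted effects —
so absolute counts from real data will differ even though the contracts hold.

## Known limitations

- Conservation requires pre-collapsed per-residue scores; no genome alignment,
  liftover or exon-model parsing is performed.
- Mutation input is a residue-level table; genomic MAF parsing and consequence
  re-annotation are upstream concerns.
- Enzyme–substrate direction is not inferred; an interaction with a matching
  enzyme is co-occurrence evidence only.
- The Spearman correlation over 11 bins has low resolution; a per-site mode
  (`per_site=True`) correlates over individual site records instead, but the
  binned statistic is the default report.
- Headline counts from the published curated resources are not reproducible
  here by construction: they depend on the versions of the many source
  databases, and the package deliberately reports its own computed values
  instead.
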