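# rbptm

Posttranslational modifications (PTMs) are dense on RNA-binding proteins (RBPs),
and where they sit — relative to cancer mutations, to conserved residues, to the
enzymes that write and erase them, and to the RNA-binding interface itself —
carries most of the biology. `rbptm` is a Python package for researchers who
curate PTM-site catalogs and want to run that whole integrative analysis
reproducibly: it harmonizes multi-source site tables onto a canonical proteome
and then drives six analysis stages plus a flat-file atlas export, with a seeded
synthetic-data generator so the complete pipeline is testable end to end without
any external downloads.

## What it computes

- **Catalog harmonization** — per-source dialect readers; computational
  predictions dropped; PTM labels normalized through a versioned controlled
  vocabulary; sites deduplicated on the key *(accession, position, PTM type)*
  with provenance merged; sites that do not fit the proteome (unknown accession,
  position > length, residue conflicting with the canonical sequence) dropped
  with logged counts.
- **Landscape statistics** — per-protein type-count profiles, modification
  density (sites per residue over the full protein length), per-type 2×2
  χ² enrichment of RBPs vs non-RBPs with Bonferroni correction
  (p_adj = min(1, m·p), m = number of PTM types tested), multi-site fractions,
  per-type cumulative site-count distributions, and ranked PTM-type
  combinations.
- **Conservation contrast** — for each protein, mean per-residue conservation
  (phastCons-style scores in [0, 1]) at PTM positions vs *n* = 100 randomly
  sampled non-PTM positions of the same protein; cohort summary reports the
  fraction of proteins where PTM sites are more conserved and a two-sample
  Kolmogorov–Smirnov test on the pooled score distributions.
- **Enzyme pairing (ME/M/E)** — every (RBP, PTM type) cell labelled by
  co-occurrence of modification and interaction with a matching writer/eraser
  enzyme in the deduplicated, undirected PPI network; per-type interaction
  counts, per-enzyme RBP counts, and enzyme target-set overlaps.
- **Mutation proximity** — residue-level cancer mutation records intersected
  with PTM sites exactly (distance 0) and within ±k residues (k = 10,
  inclusive); ranked mutated sites by case count; per-position mutation tracks.
- **RNA-interface proximity** — UV-crosslink ranges standardized to 21-position
  windows centered on the reported range (expanded if shorter, truncated if
  longer, clipped at protein ends without shifting); PTM-to-center distances
  binned over 0..10 and rank-correlated with frequency (Spearman ρ,
  opportunity-normalized by default); nearest-center distance contrasts between
  protein families (e.g. hnRNPs vs other RBPs, Welch t-test).
- **eCLIP binding calls** — an (RBP, gene) pair is a hit when, in each of two
  replicates independently, ≥1 narrowPeak overlaps the gene on the same strand
  over ≥50% of the peak's own length.
- **Atlas export** — the 11-column flat file (UniProt ID, gene name, position,
  PMID, source, amino acid, modification type, cell line, sample type, body
  site, disease state), one row per (site × provenance record), losslessly
  re-importable.

## Worked example

Generate the default synthetic cohort (2000 proteins, 25% RBPs with 5× planted
site enrichment, mutation hotspots at PTM sites, geometric PTM decay around
crosslink centers, +0.2 conservation shift) and run every stage:

```bash
rbptm simulate --seed 1 --out bundle
rbptm run-all --seed 1 --bundle bundle --out results
```

All eight stages report `completed`, and the `results/` reports contain, for
this seed:

- `harmonize_report.tsv` — 68,260 input site records unify into an atlas of
  68,261 export rows (one header; duplicated provenance merged per site).
- `enrichment.tsv` — all five simulated PTM types are significantly more common
  in RBPs (e.g. acetylation p_adj ≈ 1.2 × 10⁻³³), recovering the planted
  enrichment.
- `conservation_summary.tsv` — PTM sites are the more conserved positions in
  100% of the 523 scored RBPs (KS statistic 0.295, p < machine precision),
  recovering the planted +0.2 shift.
- `mutation_summary.tsv` — of 12,828 simulated mutations, 1,033 coincide with a
  PTM site and 11,594 fall within 10 residues of one (in 1,871 proteins),
  reflecting the planted 10× hotspot rate.
- `distance_correlation.tsv` — PTM frequency falls off with distance from
  crosslink-window centers (ρ = −0.71 overall, diluted by the uniform
  background catalog).
- `eclip_hits.tsv` — 56 replicate-concordant RBP–gene binding calls.

Re-running either command with the same seed reproduces every file byte for
byte.

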