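"""Cancer-mutation proximity to PTM sites.

Residue-level mutation records (a minimal MAF-like dialect: accession,
position, ref/alt amino acids, consequence, cancer type, case count)
are intersected with the unified site set at the exact residue and
within a +/-k-residue window (k = 10 by default, inclusive and
symmetric). Hits are (mutation, site) pairs — a mutation matching sites
of two PTM types yields two hits — and deduplicated mutation/protein
tallies are reported alongside, mirroring the "N mutations in M RBPs"
counting style.
"""
from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MutationRecord, ProximityHit

logger = logging.getLogger(__name__)


@dataclass
class ProximityResult:
    hits: list
    n_unique_mutations: int
    n_unique_proteins: int
    nearest: dict = field(default_factory=dict)  # MutationRecord -> min distance


def _sites_by_protein(sites):
    index = defaultdict(list)
    for site in sites:
        index[site.accession].append(site)
    for acc in index:
        index[acc].sort(key=lambda s: (s.position, s.ptm_type))
    return index


def mutations_near_sites(mutations, sites, k):
    """All (mutation, site) pairs on the same protein with
    |mutation position - site position| <= k.

    Also reports each hit mutation's nearest-site distance and the
    deduplicated mutation and protein counts.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    index = _sites_by_protein(sites)
    hits = []
    nearest = {}
    for mutation in mutations:
        protein_sites = index.get(mutation.accession)
        if not protein_sites:
            continue
        positions = [s.position for s in protein_sites]
        lo = bisect_left(positions, mutation.position - k)
        hi = bisect_right(positions, mutation.position + k)
        best = None
        for site in protein_sites[lo:hi]:
            distance = abs(mutation.position - site.position)
            hits.append(ProximityHit(mutation, site, distance))
            best = distance if best is None else min(best, distance)
        if best is not None:
            nearest[mutation] = best
    return ProximityResult(
        hits=hits,
        n_unique_mutations=len({h.mutation for h in hits}),
        n_unique_proteins=len({h.mutation.accession for h in hits}),
        nearest=nearest,
    )


def mutations_at_sites(mutations, sites):
    """Exact-position intersection (distance 0 only)."""
    return mutations_near_sites(mutations, sites, k=0)


def per_position_mutation_track(mutations, protein):
    """Length-L vector of summed case counts per residue (index p-1 holds
    position p); mutations beyond the protein are dropped and logged."""
    track = np.zeros(protein.length, dtype=int)
    dropped = 0
    for mutation in mutations:
        if mutation.accession != protein.accession:
            continue
        if mutation.position > protein.length:
            dropped += 1
            continue
        track[mutation.position - 1] += mutation.case_count
    if dropped:
        logger.warning("%s: dropped %d mutations beyond protein length",
                       protein.accession, dropped)
    return track


def rank_site_mutations(hits):
    """Rank mutated PTM sites by total case count (descending), ties by
    accession then position. Takes distance-0 hits; returns
    (accession, position, ptm_type, total_cases, cancer_types) tuples."""
    totals = defaultdict(int)
    cancers = defaultdict(set)
    for hit in hits:
        if hit.distance != 0:
            continue
        key = (hit.site.accession, hit.site.position, hit.site.ptm_type)
        totals[key] += hit.mutation.case_count
        cancers[key].add(hit.mutation.cancer_type)
    ranked = sorted(totals, key=lambda key: (-totals[key], key[0], key[1]))
    return [(acc, pos, ptm, totals[(acc, pos, ptm)], frozenset(cancers[(acc, pos, ptm)]))
            for acc, pos, ptm in ranked]


# ---------------------------------------------------------------------------
# IO

MUTATION_COLUMNS = ("accession", "position", "ref_aa", "alt_aa", "consequence",
                    "cancer_type", "case_count")


def read_mutations(path, proteome=None):
    """Read the residue-level mutation table. With a proteome given,
    mutations on unknown accessions are dropped with a logged count."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    dropped = 0
    for row in frame.to_dict("records"):
        if proteome is not None and row["accession"] not in proteome:
            dropped += 1
            continue
        records.append(MutationRecord(
            accession=row["accession"], position=int(row["position"]),
            ref_aa=row["ref_aa"], alt_aa=row["alt_aa"],
            consequence=row["consequence"], cancer_type=row["cancer_type"],
            case_count=int(row["case_count"]),
        ))
    if dropped:
        logger.warning("mutations: dropped %d records on accessions absent from proteome",
                       dropped)
    return records


def write_mutations(records, path):
    with open(path, "w") as fh:
        fh.write("\t".join(MUTATION_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.accession, r.position, r.cancer_type,
                                                r.ref_aa, r.alt_aa)):
            fh.write(f"{r.accession}\t{r.position}\t{r.ref_aa}\t{r.alt_aa}\t"
                     f"{r.consequence}\t{r.cancer_type}\t{r.case_count}\n")
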