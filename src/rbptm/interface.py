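"""PTM proximity to the RNA-protein interface.

Crosslink residue ranges reported by UV-crosslinking mass spectrometry
come at varying resolutions, so every range is standardized to a
21-position window centered on the reported range: the center is the
floor of the range midpoint, shorter ranges are expanded and longer
ones truncated around it, and the window is clipped to the protein
without re-centering. PTM sites falling inside a window are classified
by their distance to its center (0..10), and the distance-frequency
relation is summarized with a Spearman rank correlation over the
distance bins. A 21-residue window offers one residue at distance 0 but
two at every other distance, so by default bin counts are normalized by
that per-distance opportunity before correlating (raw counts are also
reported; pass ``opportunities=None`` to correlate raw counts).

The module also performs the strand-aware eCLIP peak-gene intersection:
an (RBP, gene) pair is a binding hit when, in each replicate
independently, at least one peak overlaps the gene on the same strand
over at least half of the peak's own length.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import CatalogFormatError, RbptmError
from .types import CrosslinkRange, GeneModel, NarrowPeak, StandardWindow

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# window standardization

def standardize_window(crosslink, protein_length, w=21):
    """Standardize a reported crosslink range to a <=w window centered on
    the range midpoint and clipped to [1, protein length]."""
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window size must be odd and positive, got {w}")
    if crosslink.end > protein_length:
        raise RbptmError(
            f"{crosslink.accession}: crosslink range ({crosslink.start}, {crosslink.end}) "
            f"outside protein of length {protein_length}"
        )
    center = (crosslink.start + crosslink.end) // 2
    half = (w - 1) // 2
    return StandardWindow(
        accession=crosslink.accession,
        center=center,
        start=max(1, center - half),
        end=min(protein_length, center + half),
        source=crosslink,
    )


def standardize_all(crosslinks, proteome, w=21):
    """Standardize every range whose protein is known; out-of-proteome or
    out-of-bounds ranges are dropped with a logged count."""
    windows = []
    dropped = 0
    for crosslink in crosslinks:
        protein = proteome.get(crosslink.accession)
        if protein is None or crosslink.end > protein.length:
            dropped += 1
            continue
        windows.append(standardize_window(crosslink, protein.length, w))
    if dropped:
        logger.warning("crosslinks: dropped %d ranges outside the proteome", dropped)
    return windows


@dataclass(frozen=True)
class DistanceAssignment:
    site: object
    window: StandardWindow
    distance: int


def assign_ptm_distances(sites, windows):
    """For each PTM site inside any standardized window, one record per
    containing window with the distance to the window center."""
    by_protein = defaultdict(list)
    for window in windows:
        by_protein[window.accession].append(window)
    assignments = []
    for site in sites:
        for window in by_protein.get(site.accession, ()):
            if site.position in window:
                assignments.append(
                    DistanceAssignment(site, window, abs(site.position - window.center))
                )
    return assignments


def distance_opportunities(windows, h=10):
    """Number of residue positions at each distance 0..h from a window
    center, summed over windows (2 per distance for an unclipped window,
    fewer at protein boundaries)."""
    opportunities = np.zeros(h + 1, dtype=int)
    for window in windows:
        opportunities[0] += int(window.start <= window.center <= window.end)
        for d in range(1, h + 1):
            opportunities[d] += int(window.center - d >= window.start)
            opportunities[d] += int(window.center + d <= window.end)
    return opportunities


@dataclass
class DistanceStats:
    counts: np.ndarray            # raw per-distance counts, bins 0..h
    frequencies: np.ndarray       # counts / opportunities (== counts when raw)
    rho: float
    p: float
    flag: str = ""                # "", "all_ties", "undefined"


def distance_frequency_stats(assignments, ptm_type=None, h=10, opportunities=None,
                             per_site=False):
    """Bin PTM-to-center distances and rank-correlate frequency with
    distance (Spearman, average ranks for ties).

    With ``opportunities`` given, counts are divided by the per-distance
    opportunity before correlating; otherwise raw counts are used.
    The correlation runs over the h+1 distance bins by default;
    ``per_site=True`` instead correlates over the individual assignment
    records (each site contributes its distance paired with its bin's
    frequency). All observations in a single bin make the correlation
    undefined (flagged); identical frequencies in every bin yield the
    all-ties convention rho = 0 (flagged).
    """
    if ptm_type is not None:
        assignments = [a for a in assignments if a.site.ptm_type == ptm_type]
    counts = np.zeros(h + 1, dtype=int)
    for a in assignments:
        if a.distance <= h:
            counts[a.distance] += 1
    if opportunities is not None:
        opportunities = np.asarray(opportunities, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(opportunities > 0, counts / opportunities, 0.0)
    else:
        freq = counts.astype(float)
    if (counts > 0).sum() <= 1:
        return DistanceStats(counts, freq, float("nan"), float("nan"), flag="undefined")
    if np.all(freq == freq[0]):
        return DistanceStats(counts, freq, 0.0, 1.0, flag="all_ties")
    if per_site:
        distances = np.array([a.distance for a in assignments if a.distance <= h])
        rho, p = stats.spearmanr(distances, freq[distances])
    else:
        rho, p = stats.spearmanr(np.arange(h + 1), freq)
    return DistanceStats(counts, freq, float(rho), float(p))


def nearest_center_distances(sites, windows):
    """Per site, the distance to the nearest window center of its protein
    (unbounded); sites on proteins without any window are excluded."""
    centers = defaultdict(list)
    for window in windows:
        centers[window.accession].append(window.center)
    out = {}
    for site in sites:
        if site.accession in centers:
            out[site] = min(abs(site.position - c) for c in centers[site.accession])
    return out


@dataclass
class GroupContrast:
    mean_a: float
    mean_b: float
    t_statistic: float
    p: float
    n_a: int
    n_b: int


def group_contrast(distances, proteome, tag):
    """Welch t-test of nearest-center distances between sites on proteins
    carrying a family tag (e.g. "hnRNP") and all other proteins."""
    group_a, group_b = [], []
    for site, distance in distances.items():
        protein = proteome.get(site.accession)
        if protein is None:
            continue
        (group_a if tag in protein.family_tags else group_b).append(distance)
    if len(group_a) < 2 or len(group_b) < 2:
        raise RbptmError(
            f"group contrast needs >= 2 sites per group, got {len(group_a)} tagged "
            f"{tag!r} and {len(group_b)} others"
        )
    t, p = stats.ttest_ind(group_a, group_b, equal_var=False)
    return GroupContrast(float(np.mean(group_a)), float(np.mean(group_b)),
                         float(t), float(p), len(group_a), len(group_b))


# ---------------------------------------------------------------------------
# eCLIP peak-gene intersection

def _gene_trees(genes):
    trees = defaultdict(IntervalTree)
    for gene in genes:
        trees[(gene.chrom, gene.strand)].addi(gene.start, gene.end, gene)
    return trees


def _replicate_hits(peaks, trees, f):
    hits = set()
    for peak in peaks:
        for interval in trees.get((peak.chrom, peak.strand), IntervalTree()).overlap(
                peak.start, peak.end):
            gene = interval.data
            overlap = min(peak.end, gene.end) - max(peak.start, gene.start)
            if overlap / peak.length >= f:
                hits.add((peak.rbp, gene.gene_id))
    return hits


def eclip_gene_hits(peaks_rep1, peaks_rep2, genes, f=0.5):
    """(RBP, gene) pairs supported by both eCLIP replicates.

    A replicate supports the pair when >=1 of its peaks overlaps the
    gene on the same strand with overlap length / peak length >= f; the
    two replicates' peaks need not overlap each other. Symmetric in
    replicate order.
    """
    trees = _gene_trees(genes)
    return _replicate_hits(peaks_rep1, trees, f) & _replicate_hits(peaks_rep2, trees, f)


# ---------------------------------------------------------------------------
# IO

def read_crosslinks(path):
    frame = pd.read_csv(path, sep="\t", dtype={"accession": str, "study": str})
    return [CrosslinkRange(row["accession"], int(row["start"]), int(row["end"]),
                           str(row.get("study", "")))
            for row in frame.to_dict("records")]


def write_crosslinks(crosslinks, path):
    with open(path, "w") as fh:
        fh.write("accession\tstart\tend\tstudy\n")
        for c in sorted(crosslinks, key=lambda c: (c.accession, c.start, c.end, c.study)):
            fh.write(f"{c.accession}\t{c.start}\t{c.end}\t{c.study}\n")


def read_narrowpeak(path, rbp="", replicate=""):
    """Read a BED6+4 narrowPeak file; malformed lines raise with the
    line number."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CatalogFormatError(
                    f"{path}: narrowPeak line has {len(fields)} fields, expected >= 6",
                    row=lineno)
            try:
                peaks.append(NarrowPeak(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    name=fields[3], score=float(fields[4]), strand=fields[5],
                    rbp=rbp or fields[3].split("_")[0], replicate=replicate,
                ))
            except Exception as exc:  # re-raised with the line number
                raise CatalogFormatError(f"{path}: {exc}", row=lineno) from exc
    return peaks


def write_narrowpeak(peaks, path):
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{int(p.score)}\t"
                     f"{p.strand}\t0\t-1\t-1\t-1\n")


def read_genes_bed(path):
    """6-column BED of gene intervals (name column = gene id)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CatalogFormatError(f"{path}: BED line has {len(fields)} fields",
                                         row=lineno)
            genes.append(GeneModel(gene_id=fields[3], chrom=fields[0],
                                   start=int(fields[1]), end=int(fields[2]),
                                   strand=fields[5]))
    return genes


def write_genes_bed(genes, path):
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_gtf(path):
    """Gene features from a GTF annotation (gene_id attribute), converted
    to 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="merge", disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for feature in db.features_of_type("gene"):
        genes.append(GeneModel(gene_id=feature.attributes["gene_id"][0],
                               chrom=feature.seqid, start=feature.start - 1,
                               end=feature.end, strand=feature.strand))
    return genes
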