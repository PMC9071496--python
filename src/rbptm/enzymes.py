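"""Enzyme-substrate pairing through the protein-protein interaction network.

Each (protein, PTM type) cell is labelled by co-occurrence of the
modification and interaction with an enzyme of the matching class:
``ME`` = modified and neighbouring a matching enzyme, ``M`` = modified
only, ``E`` = enzyme-neighbouring only, ``none`` = neither. An enzyme
"matches" a PTM type when it carries an annotation for that type in
either role (writer or eraser) — the writer-only variant is a flag.
PTM types deposited non-enzymatically (oxidation and kin) can be listed
in an exclusion set; their cells are restricted to {M, none}.

Edges are undirected and deduplicated across source databases; self
loops are dropped. All counts are therefore invariant to edge direction
and to duplication between sources.
"""
from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd

from .errors import RbptmError
from .types import EnzymeAnnotation, MEClassification, PPIEdge

logger = logging.getLogger(__name__)


def build_adjacency(edges):
    """Canonical undirected adjacency: edges deduplicated by unordered
    pair, self-loops dropped."""
    adjacency = defaultdict(set)
    for edge in edges:
        a, b = edge.accession_a, edge.accession_b
        if a == b:
            continue
        adjacency[a].add(b)
        adjacency[b].add(a)
    return dict(adjacency)


def enzymes_by_type(enzymes, writer_only=False):
    """Map PTM type -> set of enzyme accessions annotated for it."""
    index = defaultdict(set)
    for ann in enzymes:
        if writer_only and ann.role != "writer":
            continue
        index[ann.ptm_type].add(ann.accession)
    return dict(index)


def modified_types_by_protein(sites):
    index = defaultdict(set)
    for site in sites:
        index[site.accession].add(site.ptm_type)
    return dict(index)


def _matching_neighbors(accession, ptm_type, adjacency, type_index):
    neighbors = adjacency.get(accession, set())
    return frozenset(neighbors & type_index.get(ptm_type, set()))


def classify(accession, ptm_type, sites, edges, enzymes, writer_only=False,
             nonenzymatic=frozenset()):
    """Label one (protein, PTM type) cell as ME / M / E / none."""
    adjacency = edges if isinstance(edges, dict) else build_adjacency(edges)
    type_index = enzymes if isinstance(enzymes, dict) else enzymes_by_type(enzymes, writer_only)
    modified = any(s.accession == accession and s.ptm_type == ptm_type for s in sites) \
        if not isinstance(sites, dict) else ptm_type in sites.get(accession, set())
    if ptm_type in nonenzymatic:
        supporting = frozenset()
    else:
        supporting = _matching_neighbors(accession, ptm_type, adjacency, type_index)
    if modified and supporting:
        label = "ME"
    elif modified:
        label = "M"
    elif supporting:
        label = "E"
    else:
        label = "none"
    return MEClassification(accession, ptm_type, label,
                            supporting if label in ("ME", "E") else frozenset())


def me_matrix(rbpome, sites, edges, enzymes, writer_only=False, nonenzymatic=frozenset()):
    """Complete label matrix, RBPs x PTM types (pandas DataFrame of
    strings). Columns cover every enzyme-annotated type plus every type
    observed on an RBP; a column with no enzyme annotation is emitted
    with labels restricted to {M, none} (logged)."""
    adjacency = build_adjacency(edges)
    type_index = enzymes_by_type(enzymes, writer_only)
    modified = modified_types_by_protein(sites)
    observed_types = {t for acc in rbpome for t in modified.get(acc, ())}
    columns = sorted(set(type_index) | observed_types)
    for ptm_type in columns:
        if ptm_type not in type_index and ptm_type not in nonenzymatic:
            logger.info("me_matrix: no enzyme annotation for %s; column limited to M/none",
                        ptm_type)
    rows = sorted(rbpome)
    data = {
        ptm_type: [
            classify(acc, ptm_type, modified, adjacency, type_index,
                     nonenzymatic=nonenzymatic).label
            for acc in rows
        ]
        for ptm_type in columns
    }
    return pd.DataFrame(data, index=rows, columns=columns)


def count_modifying_interactions(sites, edges, enzymes, rbpome, writer_only=False,
                                 nonenzymatic=frozenset()):
    """Per PTM type, the number of (modified RBP, matching enzyme
    neighbour) pairs — each enzyme interacting with a modified protein
    counts as a separate interaction."""
    adjacency = build_adjacency(edges)
    type_index = enzymes_by_type(enzymes, writer_only)
    modified = modified_types_by_protein(sites)
    counts = {ptm_type: 0 for ptm_type in type_index}
    for accession in rbpome:
        for ptm_type in modified.get(accession, ()):
            if ptm_type in nonenzymatic or ptm_type not in type_index:
                continue
            counts[ptm_type] = counts.get(ptm_type, 0) + len(
                _matching_neighbors(accession, ptm_type, adjacency, type_index)
            )
    return counts


def rbp_count_per_enzyme(sites, edges, enzymes, rbpome, writer_only=False):
    """Per enzyme, the number of RBPs that both carry the enzyme's PTM
    type and neighbour the enzyme in the interaction network."""
    return {acc: len(targets) for acc, targets
            in _targets_per_enzyme(sites, edges, enzymes, rbpome, writer_only).items()}


def _targets_per_enzyme(sites, edges, enzymes, rbpome, writer_only=False):
    adjacency = build_adjacency(edges)
    modified = modified_types_by_protein(sites)
    types_per_enzyme = defaultdict(set)
    for ann in enzymes:
        if writer_only and ann.role != "writer":
            continue
        types_per_enzyme[ann.accession].add(ann.ptm_type)
    targets = {}
    for enzyme, types in types_per_enzyme.items():
        neighbors = adjacency.get(enzyme, set())
        targets[enzyme] = {
            acc for acc in neighbors
            if acc in rbpome and modified.get(acc, set()) & types
        }
    return targets


def enzyme_target_overlap(enzyme_a, enzyme_b, sites, edges, enzymes, rbpome,
                          writer_only=False):
    """Modified-RBP target sets of two enzymes and their intersection
    (e.g. the kinase/phosphatase shared-substrate contrast)."""
    targets = _targets_per_enzyme(sites, edges, enzymes, rbpome, writer_only)
    for enzyme in (enzyme_a, enzyme_b):
        if enzyme not in targets:
            raise RbptmError(f"enzyme {enzyme!r} has no annotation")
    set_a, set_b = targets[enzyme_a], targets[enzyme_b]
    return set_a, set_b, set_a & set_b


# ---------------------------------------------------------------------------
# IO

def read_ppi_edges(path):
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    edges = set()
    for row in frame.to_dict("records"):
        if row["accession_a"] == row["accession_b"]:
            continue  # self-loops dropped on ingest
        edges.add(PPIEdge.canonical(row["accession_a"], row["accession_b"],
                                    row.get("source", "")))
    return edges


def write_ppi_edges(edges, path):
    with open(path, "w") as fh:
        fh.write("accession_a\taccession_b\tsource\n")
        for edge in sorted(edges, key=lambda e: (e.accession_a, e.accession_b, e.source)):
            fh.write(f"{edge.accession_a}\t{edge.accession_b}\t{edge.source}\n")


def read_enzyme_annotations(path):
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        EnzymeAnnotation(row["accession"], row["ptm_type"], row["role"])
        for row in frame.to_dict("records")
    }


def write_enzyme_annotations(annotations, path):
    with open(path, "w") as fh:
        fh.write("accession\tptm_type\trole\n")
        for ann in sorted(annotations, key=lambda a: (a.accession, a.ptm_type, a.role)):
            fh.write(f"{ann.accession}\t{ann.ptm_type}\t{ann.role}\n")
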