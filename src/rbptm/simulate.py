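"""Seeded synthetic input bundles with planted statistical structure.

The generator emulates the statistical shape of the curated inputs the
analyses consume — a proteome with an RBP subset, multi-source PTM
catalogs, a PPI network with enzyme annotations, residue-level cancer
mutations, crosslink ranges with PTMs decaying around their centers,
per-residue conservation tracks, and a paired eCLIP fixture — so every
pipeline stage is testable without downloads. Each planted effect
(RBP modification enrichment, enzyme-substrate edges, mutation
hotspots at PTM sites, geometric distance decay at crosslink centers,
a conservation shift at PTM sites, replicate-concordant eCLIP binding)
is recoverable by the corresponding analysis stage.

All randomness flows from one master seed through hash-derived
per-module sub-seeds, so regeneration is order-independent and every
artifact is byte-identical across reruns.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._util import derive_seed, ensure_dir, sha256_file
from .catalog import write_proteome
from .conservation import ConservationProfile, write_conservation
from .enzymes import write_enzyme_annotations, write_ppi_edges
from .errors import RbptmError, ValidationError
from .interface import write_crosslinks, write_genes_bed, write_narrowpeak
from .mutations import write_mutations
from .types import (CrosslinkRange, EnzymeAnnotation, GeneModel, MutationRecord,
                    NarrowPeak, PPIEdge, ProteinRecord, PTMSite, SiteEvidence)
from .vocabulary import default_vocabulary

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _default_rates():
    # sites per residue per type; RBPs get these times the enrichment factor
    return {
        "phosphorylation": 0.010,
        "ubiquitination": 0.004,
        "acetylation": 0.003,
        "methylation": 0.002,
        "sumoylation": 0.001,
    }


@dataclass
class SimulationSpec:
    """All knobs of the synthetic cohort; defaults give a ~2000-protein
    bundle that generates in well under two minutes on one CPU."""

    n_proteins: int = 2000
    rbp_fraction: float = 0.25
    hnrnp_fraction: float = 0.08          # of RBPs, tagged "hnRNP"
    length_log_mean: float = 6.2          # log-normal residue length, median ~490
    length_log_sd: float = 0.6
    min_length: int = 50
    base_rates: dict = field(default_factory=_default_rates)
    rbp_enrichment_factor: float = 5.0
    n_enzymes_per_type: int = 5
    p_planted: float = 0.3                # enzyme-substrate edge prob. when modified
    p_background: float = 0.02
    n_background_edges: int = 2000
    predicted_row_fraction: float = 0.02  # rows flagged computational in catalogs
    hotspot_rate: float = 0.02            # mutations/residue within k of a PTM site
    background_rate: float = 0.002
    mutation_k: int = 10
    cancer_types: tuple = ("BRCA", "LUAD", "COAD", "UCEC", "PRAD")
    case_count_p: float = 0.5             # geometric case counts, mean 1/p
    crosslinks_per_protein: float = 2.0   # Poisson mean per RBP
    crosslink_len_min: int = 5
    crosslink_len_max: int = 40
    crosslink_sites_per_protein: float = 4.0
    decayed_share: float = 0.7            # share of crosslink-study PTMs placed by decay
    decayed_share_tagged: float = 0.95    # same, for "hnRNP"-tagged proteins
    ptm_decay: float = 0.7                # geometric success prob.; 1 => all at center
    conservation_delta: float = 0.2       # PTM-site score shift
    conservation_beta_a: float = 2.0
    conservation_beta_b: float = 2.0
    n_genes: int = 60
    n_eclip_rbps: int = 5
    eclip_bound_fraction: float = 0.3
    n_noise_peaks: int = 50               # per replicate, on top of bound-gene peaks
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    seed: int = 0

    def validate(self):
        problems = []
        if self.n_proteins < 1:
            problems.append(f"n_proteins must be >= 1, got {self.n_proteins}")
        for name in ("rbp_fraction", "hnrnp_fraction", "decayed_share",
                     "decayed_share_tagged", "predicted_row_fraction",
                     "eclip_bound_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must be in [0, 1], got {v}")
        for name in ("hotspot_rate", "background_rate", "crosslinks_per_protein",
                     "crosslink_sites_per_protein", "rbp_enrichment_factor"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if any(r < 0 for r in self.base_rates.values()):
            problems.append("base_rates must be >= 0")
        if self.rbp_enrichment_factor < 1:
            problems.append("rbp_enrichment_factor must be >= 1")
        if not (self.p_background <= self.p_planted):
            problems.append("p_planted must be >= p_background")
        for name in ("p_planted", "p_background", "case_count_p"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                problems.append(f"{name} must be in [0, 1]")
        if not (0.0 < self.ptm_decay <= 1.0):
            problems.append(f"ptm_decay must be in (0, 1], got {self.ptm_decay}")
        if self.min_length < 1:
            problems.append("min_length must be >= 1")
        if not (1 <= self.crosslink_len_min <= self.crosslink_len_max):
            problems.append("crosslink length bounds must satisfy 1 <= min <= max")
        if problems:
            raise ValidationError(problems)
        return self

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["cancer_types"] = list(self.cancer_types)
        return d


# ---------------------------------------------------------------------------
# generators

def generate_proteome(spec):
    spec.validate()
    rng = np.random.default_rng(derive_seed(spec.seed, "proteome"))
    lengths = np.maximum(
        spec.min_length,
        np.exp(rng.normal(spec.length_log_mean, spec.length_log_sd, spec.n_proteins))
        .astype(int),
    )
    is_rbp = rng.random(spec.n_proteins) < spec.rbp_fraction
    is_hnrnp = is_rbp & (rng.random(spec.n_proteins) < spec.hnrnp_fraction)
    proteome = {}
    for i in range(spec.n_proteins):
        accession = f"P{i:05d}"
        proteome[accession] = ProteinRecord(
            accession=accession,
            gene_name=f"GENE{i}",
            length=int(lengths[i]),
            is_rbp=bool(is_rbp[i]),
            family_tags={"hnRNP"} if is_hnrnp[i] else set(),
        )
    return proteome


_CELL_LINES = ("HeLa", "K562", "HEK293", None)
_SAMPLE_TYPES = ("cell line", "tissue", None)
_BODY_SITES = ("blood", "liver", "brain", None)
_DISEASES = ("none", "cancer", None)


def _random_evidence(rng, source):
    return SiteEvidence(
        source=source,
        pmid=str(10_000_000 + int(rng.integers(0, 100_000))),
        cell_line=_CELL_LINES[rng.integers(len(_CELL_LINES))],
        sample_type=_SAMPLE_TYPES[rng.integers(len(_SAMPLE_TYPES))],
        body_site=_BODY_SITES[rng.integers(len(_BODY_SITES))],
        disease_state=_DISEASES[rng.integers(len(_DISEASES))],
    )


def _draw_residue(rng, vocabulary, ptm_type):
    compatible = vocabulary.compatible_residues(ptm_type)
    pool = sorted(compatible) if compatible else list(_AA)
    return pool[rng.integers(len(pool))]


def generate_ptm_catalog(proteome, spec, vocabulary=None, source="synthetic"):
    """Plant per-type site counts at rate x length (x enrichment factor
    for RBPs); positions unique within a protein-type pair."""
    spec.validate()
    if vocabulary is None:
        vocabulary = default_vocabulary()
    rng = np.random.default_rng(derive_seed(spec.seed, "catalog"))
    sites = []
    for accession in sorted(proteome):
        protein = proteome[accession]
        factor = spec.rbp_enrichment_factor if protein.is_rbp else 1.0
        for ptm_type in sorted(spec.base_rates):
            rate = spec.base_rates[ptm_type]
            n = int(rng.poisson(rate * factor * protein.length))
            if n == 0:
                continue
            if n > protein.length:
                raise RbptmError(
                    f"{accession}: site rate exhausts the {protein.length} available "
                    f"positions for {ptm_type} (drew {n})"
                )
            positions = rng.choice(protein.length, size=n, replace=False) + 1
            for position in sorted(int(p) for p in positions):
                sites.append(PTMSite(
                    accession=accession, position=position,
                    residue=_draw_residue(rng, vocabulary, ptm_type),
                    ptm_type=ptm_type,
                    evidence=(_random_evidence(rng, source),),
                ))
    return sites


def generate_interactions(proteome, sites, spec):
    """Enzymes per PTM type with writer/eraser roles; enzyme-protein
    edges at p_planted when the protein carries the type, else
    p_background; plus random background protein-protein edges."""
    spec.validate()
    rng = np.random.default_rng(derive_seed(spec.seed, "ppi"))
    modified = {}
    for site in sites:
        modified.setdefault(site.accession, set()).add(site.ptm_type)
    accessions = sorted(proteome)
    enzymes = set()
    edges = set()
    for ptm_type in sorted(spec.base_rates):
        for j in range(spec.n_enzymes_per_type):
            enzyme = f"ENZ_{ptm_type}_{j}"
            role = "writer" if j % 2 == 0 else "eraser"
            enzymes.add(EnzymeAnnotation(enzyme, ptm_type, role))
            draws = rng.random(len(accessions))
            for accession, u in zip(accessions, draws):
                p = (spec.p_planted if ptm_type in modified.get(accession, ())
                     else spec.p_background)
                if u < p:
                    edges.add(PPIEdge.canonical(accession, enzyme,
                                                source=f"ppidb{1 + j % 2}"))
    for _ in range(spec.n_background_edges):
        i, j = rng.integers(0, len(accessions), size=2)
        if i != j:
            edges.add(PPIEdge.canonical(accessions[int(i)], accessions[int(j)],
                                        source="ppidb1"))
    return edges, enzymes


def generate_mutations(proteome, sites, spec):
    """Per-residue Bernoulli mutation presence: hotspot_rate within
    mutation_k residues of a PTM site, background_rate elsewhere."""
    spec.validate()
    rng = np.random.default_rng(derive_seed(spec.seed, "mutations"))
    positions_by_protein = {}
    for site in sites:
        positions_by_protein.setdefault(site.accession, []).append(site.position)
    records = []
    for accession in sorted(proteome):
        protein = proteome[accession]
        hot = np.zeros(protein.length, dtype=bool)
        for position in positions_by_protein.get(accession, ()):
            lo = max(0, position - 1 - spec.mutation_k)
            hi = min(protein.length, position + spec.mutation_k)
            hot[lo:hi] = True
        rates = np.where(hot, spec.hotspot_rate, spec.background_rate)
        mutated = np.flatnonzero(rng.random(protein.length) < rates)
        for idx in mutated:
            ref, alt = rng.choice(len(_AA), size=2, replace=False)
            records.append(MutationRecord(
                accession=accession, position=int(idx) + 1,
                ref_aa=_AA[int(ref)], alt_aa=_AA[int(alt)],
                consequence="missense",
                cancer_type=spec.cancer_types[rng.integers(len(spec.cancer_types))],
                case_count=int(rng.geometric(spec.case_count_p)),
            ))
    return records


def generate_crosslink_study(proteome, spec, vocabulary=None):
    """Crosslink ranges on RBPs plus a PTM site set in which a
    ``decayed_share`` of sites sit at geometric offsets from window
    centers (sign uniform) and the remainder are uniform over the
    protein. Offsets falling outside the protein are redrawn up to 100
    times, then the site is skipped with a log entry."""
    spec.validate()
    if vocabulary is None:
        vocabulary = default_vocabulary()
    rng = np.random.default_rng(derive_seed(spec.seed, "crosslink"))
    type_labels = sorted(spec.base_rates)
    type_weights = np.array([spec.base_rates[t] for t in type_labels], dtype=float)
    type_weights /= type_weights.sum()
    crosslinks, sites = [], []
    skipped = 0
    for accession in sorted(proteome):
        protein = proteome[accession]
        if not protein.is_rbp:
            continue
        n_ranges = int(rng.poisson(spec.crosslinks_per_protein))
        centers = []
        for _ in range(n_ranges):
            length = int(rng.integers(spec.crosslink_len_min, spec.crosslink_len_max + 1))
            length = min(length, protein.length)
            start = int(rng.integers(1, protein.length - length + 2))
            end = start + length - 1
            crosslinks.append(CrosslinkRange(accession, start, end,
                                             study=f"study{1 + int(rng.integers(4))}"))
            centers.append((start + end) // 2)
        if not centers:
            continue
        share = (spec.decayed_share_tagged if "hnRNP" in protein.family_tags
                 else spec.decayed_share)
        n_sites = int(rng.poisson(spec.crosslink_sites_per_protein))
        for _ in range(n_sites):
            if rng.random() < share:
                position = None
                for _attempt in range(100):
                    center = centers[int(rng.integers(len(centers)))]
                    offset = int(rng.geometric(spec.ptm_decay)) - 1
                    sign = 1 if rng.random() < 0.5 else -1
                    candidate = center + sign * offset
                    if 1 <= candidate <= protein.length:
                        position = candidate
                        break
                if position is None:
                    skipped += 1
                    continue
            else:
                position = int(rng.integers(1, protein.length + 1))
            ptm_type = type_labels[int(rng.choice(len(type_labels), p=type_weights))]
            sites.append(PTMSite(
                accession=accession, position=position,
                residue=_draw_residue(rng, vocabulary, ptm_type),
                ptm_type=ptm_type,
                evidence=(_random_evidence(rng, "crosslink_study"),),
            ))
    if skipped:
        logger.info("crosslink study: skipped %d sites after 100 placement attempts",
                    skipped)
    return crosslinks, sites


def generate_conservation(proteome, sites, spec):
    """Beta-distributed background scores with PTM-site scores shifted by
    +delta (clipped to [0, 1])."""
    spec.validate()
    rng = np.random.default_rng(derive_seed(spec.seed, "conservation"))
    positions_by_protein = {}
    for site in sites:
        positions_by_protein.setdefault(site.accession, set()).add(site.position)
    profiles = {}
    for accession in sorted(proteome):
        protein = proteome[accession]
        scores = rng.beta(spec.conservation_beta_a, spec.conservation_beta_b,
                          protein.length)
        ptm_positions = sorted(positions_by_protein.get(accession, ()))
        if ptm_positions:
            idx = np.asarray(ptm_positions, dtype=int) - 1
            scores[idx] = np.clip(scores[idx] + spec.conservation_delta, 0.0, 1.0)
        profiles[accession] = ConservationProfile(accession, scores)
    return profiles


def generate_eclip(spec):
    """Toy-genome eCLIP fixture: gene intervals on a few chromosomes, a
    per-RBP bound-gene subset, and two replicates each carrying one
    qualifying peak per bound gene plus noise peaks."""
    spec.validate()
    rng = np.random.default_rng(derive_seed(spec.seed, "eclip"))
    genes = []
    for g in range(spec.n_genes):
        chrom = f"chr{1 + g % spec.n_chromosomes}"
        length = int(rng.integers(2_000, 20_000))
        start = int(rng.integers(0, spec.chromosome_length - length))
        genes.append(GeneModel(gene_id=f"GSYN{g:04d}", chrom=chrom,
                               start=start, end=start + length,
                               strand="+" if rng.random() < 0.5 else "-"))
    replicates = ([], [])
    bound = {}
    for r in range(spec.n_eclip_rbps):
        rbp = f"ECLIP_RBP{r}"
        mask = rng.random(spec.n_genes) < spec.eclip_bound_fraction
        bound[rbp] = {genes[i].gene_id for i in np.flatnonzero(mask)}
        for rep_idx, peaks in enumerate(replicates):
            counter = 0
            for i in np.flatnonzero(mask):
                gene = genes[i]
                length = int(rng.integers(100, 500))
                length = min(length, gene.end - gene.start)
                start = int(rng.integers(gene.start, gene.end - length + 1))
                peaks.append(NarrowPeak(
                    chrom=gene.chrom, start=start, end=start + length,
                    name=f"{rbp}_peak{counter}", score=int(rng.integers(100, 1000)),
                    strand=gene.strand, rbp=rbp, replicate=f"rep{rep_idx + 1}"))
                counter += 1
            for _ in range(spec.n_noise_peaks):
                chrom = f"chr{1 + int(rng.integers(spec.n_chromosomes))}"
                length = int(rng.integers(100, 500))
                start = int(rng.integers(0, spec.chromosome_length - length))
                peaks.append(NarrowPeak(
                    chrom=chrom, start=start, end=start + length,
                    name=f"{rbp}_peak{counter}", score=int(rng.integers(100, 1000)),
                    strand="+" if rng.random() < 0.5 else "-",
                    rbp=rbp, replicate=f"rep{rep_idx + 1}"))
                counter += 1
    return replicates[0], replicates[1], genes, bound


# ---------------------------------------------------------------------------
# bundle

BUNDLE_FILES = {
    "proteome": "proteome.tsv",
    "catalog_a": "catalog_a.tsv",
    "catalog_b": "catalog_b.tsv",
    "rbp_lists": ("rbp_list_1.txt", "rbp_list_2.txt", "rbp_list_3.txt"),
    "ppi_edges": "ppi_edges.tsv",
    "enzymes": "enzyme_annotations.tsv",
    "mutations": "mutations.tsv",
    "crosslinks": "crosslinks.tsv",
    "conservation": "conservation.tsv",
    "eclip_rep1": "eclip_rep1.narrowPeak",
    "eclip_rep2": "eclip_rep2.narrowPeak",
    "genes": "genes.bed",
    "manifest": "manifest.json",
}

_CATALOG_HEADER = ("accession\tposition\tresidue\tptm_type\tpmid\tevidence\t"
                   "cell_line\tsample_type\tbody_site\tdisease_state\n")


def _write_catalog_file(sites, path, rng, predicted_fraction, proteome):
    from .types import NULL_TOKEN

    def cell(v):
        return NULL_TOKEN if v is None else str(v)

    with open(path, "w") as fh:
        fh.write(_CATALOG_HEADER)
        for site in sites:
            ev = site.evidence[0]
            fh.write("\t".join([
                site.accession, str(site.position), site.residue, site.ptm_type,
                cell(ev.pmid), "experimental", cell(ev.cell_line),
                cell(ev.sample_type), cell(ev.body_site), cell(ev.disease_state),
            ]) + "\n")
        accessions = sorted(proteome)
        n_predicted = int(round(predicted_fraction * len(sites)))
        for _ in range(n_predicted):
            accession = accessions[int(rng.integers(len(accessions)))]
            position = int(rng.integers(1, proteome[accession].length + 1))
            fh.write("\t".join([
                accession, str(position), "S", "phosphorylation", NULL_TOKEN,
                "predicted", NULL_TOKEN, NULL_TOKEN, NULL_TOKEN, NULL_TOKEN,
            ]) + "\n")


def make_bundle(spec, out_dir, overwrite=False):
    """Generate every input file a pipeline run consumes, plus a manifest
    with the spec, seed and per-file checksums. Same spec + seed =>
    identical checksums."""
    spec.validate()
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise RbptmError(f"output directory {out} is not empty (pass overwrite=True)")
    ensure_dir(out)
    rng = np.random.default_rng(derive_seed(spec.seed, "bundle"))

    proteome = generate_proteome(spec)
    write_proteome(proteome, out / BUNDLE_FILES["proteome"])

    catalog = generate_ptm_catalog(proteome, spec)
    crosslinks, crosslink_sites = generate_crosslink_study(proteome, spec)
    all_sites = catalog + crosslink_sites
    # split into two overlapping source files to plant duplication
    in_a = rng.random(len(all_sites)) < 0.7
    in_b = rng.random(len(all_sites)) < 0.5
    in_a |= ~in_b  # every site lands in at least one catalog
    _write_catalog_file([s for s, a in zip(all_sites, in_a) if a],
                        out / BUNDLE_FILES["catalog_a"], rng,
                        spec.predicted_row_fraction, proteome)
    _write_catalog_file([s for s, b in zip(all_sites, in_b) if b],
                        out / BUNDLE_FILES["catalog_b"], rng,
                        spec.predicted_row_fraction, proteome)

    rbps = sorted(a for a, p in proteome.items() if p.is_rbp)
    memberships = rng.integers(0, 3, size=(len(rbps), 3)) > 0  # ~2/3 odds each
    for j, name in enumerate(BUNDLE_FILES["rbp_lists"]):
        member = [acc for acc, row in zip(rbps, memberships) if row[j] or not row.any()]
        (out / name).write_text("\n".join(member) + "\n")

    edges, enzymes = generate_interactions(proteome, all_sites, spec)
    write_ppi_edges(edges, out / BUNDLE_FILES["ppi_edges"])
    write_enzyme_annotations(enzymes, out / BUNDLE_FILES["enzymes"])

    write_mutations(generate_mutations(proteome, all_sites, spec),
                    out / BUNDLE_FILES["mutations"])
    write_crosslinks(crosslinks, out / BUNDLE_FILES["crosslinks"])

    rbp_proteome = {a: p for a, p in proteome.items() if p.is_rbp}
    write_conservation(generate_conservation(rbp_proteome, all_sites, spec),
                       out / BUNDLE_FILES["conservation"])

    rep1, rep2, genes, _bound = generate_eclip(spec)
    write_narrowpeak(rep1, out / BUNDLE_FILES["eclip_rep1"])
    write_narrowpeak(rep2, out / BUNDLE_FILES["eclip_rep2"])
    write_genes_bed(genes, out / BUNDLE_FILES["genes"])

    files = [BUNDLE_FILES[k] for k in ("proteome", "catalog_a", "catalog_b",
                                       "ppi_edges", "enzymes", "mutations",
                                       "crosslinks", "conservation", "eclip_rep1",
                                       "eclip_rep2", "genes")]
    files += list(BUNDLE_FILES["rbp_lists"])
    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "checksums": {name: sha256_file(out / name) for name in sorted(files)},
    }
    (out / BUNDLE_FILES["manifest"]).write_text(json.dumps(manifest, indent=2,
                                                           sort_keys=True) + "\n")
    return manifest


def spec_from_yaml(path):
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(SimulationSpec)}
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ValidationError([f"unknown simulation spec key: {k!r}" for k in unknown])
    if "cancer_types" in data:
        data["cancer_types"] = tuple(data["cancer_types"])
    return SimulationSpec(**data).validate()
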