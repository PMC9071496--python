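"""Core domain types shared across the pipeline.

Residue positions are 1-based throughout and refer to the canonical
(SwissProt-style) protein sequence; inputs are assumed pre-mapped to
canonical accessions. Genomic coordinates (eCLIP peaks, gene models) are
0-based half-open, following BED convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

#: token written for absent context fields in flat-file exports
NULL_TOKEN = "NA"


@dataclass
class ProteinRecord:
    """One canonical protein.

    ``family_tags`` carries free-form family labels such as ``"hnRNP"``
    used for group contrasts.
    """

    accession: str
    gene_name: str
    length: int
    sequence: Optional[str] = None
    is_rbp: bool = False
    family_tags: set = field(default_factory=set)

    def __post_init__(self):
        problems = []
        if self.length < 1:
            problems.append(f"{self.accession}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            problems.append(
                f"{self.accession}: sequence length {len(self.sequence)} != length {self.length}"
            )
        if problems:
            raise ValidationError(problems)


# A proteome is a dict mapping accession -> ProteinRecord; accession
# uniqueness is therefore structural.
Proteome = dict


@dataclass(frozen=True)
class SiteEvidence:
    """One provenance record attached to a PTM site: the source catalog,
    literature reference and biological context."""

    source: str
    pmid: Optional[str] = None
    cell_line: Optional[str] = None
    sample_type: Optional[str] = None
    body_site: Optional[str] = None
    disease_state: Optional[str] = None


@dataclass(frozen=True)
class PTMSite:
    """One experimentally determined modified residue.

    The identity key used for harmonization is ``(accession, position,
    ptm_type)``; the same residue carrying two modification types yields
    two distinct sites.
    """

    accession: str
    position: int
    residue: str
    ptm_type: str
    evidence: tuple = ()

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError([f"{self.accession}: position {self.position} < 1"])

    @property
    def key(self):
        return (self.accession, self.position, self.ptm_type)

    @property
    def sources(self):
        return {e.source for e in self.evidence}

    @property
    def pmids(self):
        return {e.pmid for e in self.evidence if e.pmid is not None}


@dataclass(frozen=True)
class PPIEdge:
    """Undirected protein-protein interaction, stored canonically with
    ``accession_a < accession_b``."""

    accession_a: str
    accession_b: str
    source: str = ""

    @classmethod
    def canonical(cls, a, b, source=""):
        if a == b:
            raise ValidationError([f"self-loop edge on {a}"])
        if a > b:
            a, b = b, a
        return cls(a, b, source)

    @property
    def pair(self):
        return (self.accession_a, self.accession_b)


@dataclass(frozen=True)
class EnzymeAnnotation:
    """An enzyme's PTM class and its role: ``writer`` deposits the
    modification (e.g. a kinase), ``eraser`` removes it (e.g. a
    phosphatase)."""

    accession: str
    ptm_type: str
    role: str

    def __post_init__(self):
        if self.role not in ("writer", "eraser"):
            raise ValidationError([f"{self.accession}: role {self.role!r} not writer/eraser"])


@dataclass(frozen=True)
class MEClassification:
    """Label of one (protein, PTM type) cell.

    ME = modified and interacting with a matching enzyme; M = modified
    only; E = enzyme-interacting only; none = neither.
    """

    accession: str
    ptm_type: str
    label: str
    supporting_enzymes: frozenset = frozenset()


@dataclass(frozen=True)
class MutationRecord:
    """A cancer mutation at a protein residue with its cohort case count."""

    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    consequence: str
    cancer_type: str
    case_count: int

    def __post_init__(self):
        problems = []
        if self.position < 1:
            problems.append(f"{self.accession}: mutation position {self.position} < 1")
        if self.case_count < 1:
            problems.append(f"{self.accession}: case_count {self.case_count} < 1")
        if problems:
            raise ValidationError(problems)


@dataclass(frozen=True)
class ProximityHit:
    """A (mutation, PTM site) pair on the same protein within the
    proximity window; ``distance`` is residues between them."""

    mutation: MutationRecord
    site: PTMSite
    distance: int


@dataclass(frozen=True)
class CrosslinkRange:
    """A residue interval reported by UV crosslinking mass spectrometry
    as an RNA-protein contact region (1-based, inclusive)."""

    accession: str
    start: int
    end: int
    study: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                [f"{self.accession}: invalid crosslink range ({self.start}, {self.end})"]
            )


@dataclass(frozen=True)
class StandardWindow:
    """A crosslink range standardized to at most ``w`` residues centered
    on the reported range's midpoint and clipped to the protein."""

    accession: str
    center: int
    start: int
    end: int
    source: CrosslinkRange = None

    def __contains__(self, position):
        return self.start <= position <= self.end


@dataclass(frozen=True)
class NarrowPeak:
    """One eCLIP peak from a BED6+4 narrowPeak file. ``start``/``end``
    are 0-based half-open genomic coordinates."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str
    rbp: str = ""
    replicate: str = ""

    def __post_init__(self):
        problems = []
        if not self.start < self.end:
            problems.append(f"peak {self.name}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            problems.append(f"peak {self.name}: strand {self.strand!r} not +/-")
        if problems:
            raise ValidationError(problems)

    @property
    def length(self):
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError([f"gene {self.gene_id}: start >= end"])
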