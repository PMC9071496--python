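"""PTM catalog ingestion, harmonization, RBP-ome construction and atlas export.

Source PTM catalogs arrive as delimited text in per-source dialects; a
dialect declares which columns hold the accession, position, residue and
modification type, and which column/values flag computational
predictions (always dropped — only experimentally determined sites are
kept). Harmonization deduplicates on the key ``(accession, position,
ptm_type)``, merges provenance, and drops sites that do not fit the
proteome (unknown accession, position beyond the protein, residue
conflicting with the canonical sequence).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import CatalogFormatError, ConfigurationError
from .types import NULL_TOKEN, ProteinRecord, PTMSite, SiteEvidence

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# dialects

@dataclass(frozen=True)
class CatalogDialect:
    """How one source catalog spells its columns.

    ``column_map`` maps the standard field names (accession, position,
    residue, ptm_type, pmid, cell_line, sample_type, body_site,
    disease_state) to the file's column headers; only the first four are
    required. ``evidence_column``/``predicted_values`` identify rows that
    are computational predictions rather than experimental observations.
    """

    name: str
    column_map: dict
    evidence_column: str = None
    predicted_values: frozenset = frozenset()
    delimiter: str = "\t"


_DIALECTS = {}


def register_dialect(dialect):
    _DIALECTS[dialect.name] = dialect
    return dialect


def get_dialect(name):
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown catalog dialect {name!r}; registered: {sorted(_DIALECTS)}"
        ) from None


register_dialect(
    CatalogDialect(
        name="generic",
        column_map={
            "accession": "accession",
            "position": "position",
            "residue": "residue",
            "ptm_type": "ptm_type",
            "pmid": "pmid",
            "cell_line": "cell_line",
            "sample_type": "sample_type",
            "body_site": "body_site",
            "disease_state": "disease_state",
        },
        evidence_column="evidence",
        predicted_values=frozenset({"predicted", "computational", "in silico"}),
    )
)

register_dialect(
    CatalogDialect(
        name="compact",
        column_map={
            "accession": "protein",
            "position": "site",
            "residue": "aa",
            "ptm_type": "modification",
            "pmid": "reference",
        },
        evidence_column="method",
        predicted_values=frozenset({"predicted", "prediction"}),
    )
)


# ---------------------------------------------------------------------------
# loading

@dataclass
class CatalogLoadReport:
    n_rows: int = 0
    n_loaded: int = 0
    n_dropped_predicted: int = 0
    n_dropped_unmapped_type: int = 0
    unmapped_labels: dict = field(default_factory=dict)


def _opt(row, col):
    if col is None or col not in row:
        return None
    value = str(row[col]).strip()
    return value if value and value != NULL_TOKEN else None


def load_ptm_catalog(path, dialect, vocabulary, source=None, report=None):
    """Read one source catalog into a list of PTM sites.

    Prediction-flagged rows are dropped; modification labels are
    normalized through the vocabulary, and rows whose label cannot be
    mapped are dropped with a logged count (never silently passed).
    Malformed rows raise :class:`CatalogFormatError` with the row number.
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    if source is None:
        source = dialect.name
    if report is None:
        report = CatalogLoadReport()

    frame = pd.read_csv(
        path, sep=dialect.delimiter, dtype=str, keep_default_na=False, comment="#"
    )
    cmap = dialect.column_map
    required = ["accession", "position", "residue", "ptm_type"]
    missing = [cmap[f] for f in required if cmap[f] not in frame.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing required columns {missing}")

    sites = []
    report.n_rows = len(frame)
    for idx, row in enumerate(frame.to_dict("records"), start=1):
        evidence_value = _opt(row, dialect.evidence_column)
        if evidence_value is not None and evidence_value.lower() in dialect.predicted_values:
            report.n_dropped_predicted += 1
            continue
        accession = str(row[cmap["accession"]]).strip()
        raw_pos = str(row[cmap["position"]]).strip()
        residue = str(row[cmap["residue"]]).strip().upper()
        raw_type = str(row[cmap["ptm_type"]]).strip()
        if not accession or not raw_pos or not raw_type:
            raise CatalogFormatError("missing accession, position or PTM type", row=idx)
        try:
            position = int(raw_pos)
        except ValueError:
            raise CatalogFormatError(f"non-integer position {raw_pos!r}", row=idx) from None
        if position < 1:
            raise CatalogFormatError(f"position {position} < 1", row=idx)
        ptm_type = vocabulary.normalize(raw_type)
        if ptm_type is None:
            report.n_dropped_unmapped_type += 1
            report.unmapped_labels[raw_type] = report.unmapped_labels.get(raw_type, 0) + 1
            continue
        ev = SiteEvidence(
            source=source,
            pmid=_opt(row, cmap.get("pmid")),
            cell_line=_opt(row, cmap.get("cell_line")),
            sample_type=_opt(row, cmap.get("sample_type")),
            body_site=_opt(row, cmap.get("body_site")),
            disease_state=_opt(row, cmap.get("disease_state")),
        )
        sites.append(
            PTMSite(accession=accession, position=position, residue=residue,
                    ptm_type=ptm_type, evidence=(ev,))
        )
    report.n_loaded = len(sites)
    if report.n_dropped_predicted or report.n_dropped_unmapped_type:
        logger.warning(
            "%s (%s): dropped %d predicted rows, %d rows with unmappable PTM labels %s",
            path, source, report.n_dropped_predicted, report.n_dropped_unmapped_type,
            dict(report.unmapped_labels),
        )
    return sites


# ---------------------------------------------------------------------------
# harmonization

def _evidence_sort_key(ev):
    return (ev.source, ev.pmid or "", ev.cell_line or "", ev.sample_type or "",
            ev.body_site or "", ev.disease_state or "")


@dataclass
class UnifyReport:
    n_input: int = 0
    n_unknown_accession: int = 0
    n_out_of_range: int = 0
    n_residue_conflict: int = 0
    n_unified: int = 0


def unify_catalogs(catalogs, proteome, residue_conflicts="drop", report=None):
    """Merge per-source site lists into one non-redundant site set.

    One site survives per ``(accession, position, ptm_type)`` key with
    provenance records merged and sorted (so the result is independent of
    catalog order — harmonization is idempotent). Sites on accessions
    absent from the proteome, or beyond the protein's length, are
    dropped and counted. When the proteome carries a sequence, a site
    whose stated residue conflicts with it is dropped
    (``residue_conflicts="keep"`` trusts the catalog instead).
    """
    if residue_conflicts not in ("drop", "keep"):
        raise ConfigurationError(f"residue_conflicts must be 'drop' or 'keep', got {residue_conflicts!r}")
    if report is None:
        report = UnifyReport()
    merged = {}  # key -> (set of residues, set of evidence)
    for catalog in catalogs:
        for site in catalog:
            report.n_input += 1
            protein = proteome.get(site.accession)
            if protein is None:
                report.n_unknown_accession += 1
                continue
            if site.position > protein.length:
                report.n_out_of_range += 1
                continue
            if protein.sequence is not None and residue_conflicts == "drop":
                expected = protein.sequence[site.position - 1].upper()
                if site.residue and site.residue != expected:
                    report.n_residue_conflict += 1
                    continue
            residues, evidence = merged.setdefault(site.key, (set(), set()))
            residues.add(site.residue)
            evidence.update(site.evidence)

    unified = set()
    for (accession, position, ptm_type), (residues, evidence) in merged.items():
        protein = proteome[accession]
        if protein.sequence is not None and residue_conflicts == "drop":
            residue = protein.sequence[position - 1].upper()
        else:
            # no sequence to arbitrate: deterministic choice independent
            # of catalog order
            residue = min(residues)
        unified.add(
            PTMSite(accession=accession, position=position, residue=residue,
                    ptm_type=ptm_type,
                    evidence=tuple(sorted(evidence, key=_evidence_sort_key)))
        )
    report.n_unified = len(unified)
    if report.n_unknown_accession or report.n_out_of_range or report.n_residue_conflict:
        logger.warning(
            "unify: dropped %d sites on unknown accessions, %d beyond protein length, "
            "%d residue conflicts",
            report.n_unknown_accession, report.n_out_of_range, report.n_residue_conflict,
        )
    return unified


def build_rbpome(lists, proteome=None):
    """Union of annotated-RBP accession lists into one non-redundant
    RBP-ome; flags ``is_rbp`` on matching proteome records."""
    rbpome = set()
    for accessions in lists:
        rbpome.update(accessions)
    if proteome is not None:
        unknown = {a for a in rbpome if a not in proteome}
        if unknown:
            logger.warning("rbpome: %d accessions absent from the proteome", len(unknown))
        for accession in rbpome:
            if accession in proteome:
                proteome[accession].is_rbp = True
    return rbpome


# ---------------------------------------------------------------------------
# atlas export

ATLAS_COLUMNS = (
    "uniprot_id", "gene_name", "position", "pmid", "source", "amino_acid",
    "modification_type", "cell_line", "sample_type", "body_site", "disease_state",
)

#: header of the published flat file, which spells the source column "Ssource"
ATLAS_COLUMNS_STRICT = tuple(
    "Ssource" if c == "source" else c for c in ATLAS_COLUMNS
)


def _cell(value):
    return NULL_TOKEN if value is None else str(value)


def export_atlas(sites, proteome, path, per_evidence=True, strict_header=False):
    """Write the atlas flat file: the 11 standard columns, one row per
    (site, provenance record) pair (or one row per site with provenance
    joined by ';' when ``per_evidence=False``). Returns rows written."""
    header = ATLAS_COLUMNS_STRICT if strict_header else ATLAS_COLUMNS
    rows = []
    for site in sorted(sites, key=lambda s: s.key):
        protein = proteome.get(site.accession)
        gene = protein.gene_name if protein is not None else None
        if per_evidence:
            for ev in sorted(site.evidence, key=_evidence_sort_key):
                rows.append((site.accession, _cell(gene), site.position, _cell(ev.pmid),
                             ev.source, site.residue, site.ptm_type, _cell(ev.cell_line),
                             _cell(ev.sample_type), _cell(ev.body_site), _cell(ev.disease_state)))
        else:
            evs = sorted(site.evidence, key=_evidence_sort_key)
            join = lambda vals: ";".join(vals) if vals else NULL_TOKEN
            rows.append((site.accession, _cell(gene), site.position,
                         join(sorted({e.pmid for e in evs if e.pmid})),
                         join(sorted({e.source for e in evs})),
                         site.residue, site.ptm_type,
                         join(sorted({e.cell_line for e in evs if e.cell_line})),
                         join(sorted({e.sample_type for e in evs if e.sample_type})),
                         join(sorted({e.body_site for e in evs if e.body_site})),
                         join(sorted({e.disease_state for e in evs if e.disease_state}))))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return len(rows)


def read_atlas(path):
    """Re-import a per-evidence atlas export, reconstructing the unified
    site set (inverse of :func:`export_atlas` with ``per_evidence=True``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.rename(columns={"Ssource": "source"})

    def opt(value):
        return None if value == NULL_TOKEN or value == "" else value

    grouped = {}
    for row in frame.to_dict("records"):
        key = (row["uniprot_id"], int(row["position"]), row["modification_type"])
        residue = row["amino_acid"]
        ev = SiteEvidence(source=row["source"], pmid=opt(row["pmid"]),
                          cell_line=opt(row["cell_line"]), sample_type=opt(row["sample_type"]),
                          body_site=opt(row["body_site"]), disease_state=opt(row["disease_state"]))
        grouped.setdefault(key, (residue, set()))[1].add(ev)
    return {
        PTMSite(accession=acc, position=pos, residue=residue, ptm_type=ptm,
                evidence=tuple(sorted(evidence, key=_evidence_sort_key)))
        for (acc, pos, ptm), (residue, evidence) in grouped.items()
    }


# ---------------------------------------------------------------------------
# proteome and list IO

def write_proteome(proteome, path):
    with open(path, "w") as fh:
        fh.write("accession\tgene_name\tlength\tsequence\tis_rbp\tfamily_tags\n")
        for accession in sorted(proteome):
            p = proteome[accession]
            fh.write("\t".join([
                p.accession, p.gene_name, str(p.length),
                p.sequence or NULL_TOKEN, "1" if p.is_rbp else "0",
                ";".join(sorted(p.family_tags)) or NULL_TOKEN,
            ]) + "\n")


def read_proteome(path):
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    proteome = {}
    for row in frame.to_dict("records"):
        tags = row.get("family_tags", NULL_TOKEN)
        seq = row.get("sequence", NULL_TOKEN)
        proteome[row["accession"]] = ProteinRecord(
            accession=row["accession"],
            gene_name=row.get("gene_name", row["accession"]),
            length=int(row["length"]),
            sequence=None if seq in (NULL_TOKEN, "") else seq,
            is_rbp=row.get("is_rbp", "0") == "1",
            family_tags=set() if tags in (NULL_TOKEN, "") else set(tags.split(";")),
        )
    return proteome


def read_accession_list(path):
    """One accession per line; '#' starts a comment."""
    accessions = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            accessions.add(line)
    return accessions
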