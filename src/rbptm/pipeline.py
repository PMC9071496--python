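"""End-to-end pipeline over a bundle directory.

Stages run in order: harmonize -> landscape -> conserve -> enzymes ->
mutations -> interface -> eclip -> export. Each stage reads the bundle
files it needs, writes tidy TSV reports into the output directory, and
records its status (completed / skipped / failed) in the run manifest;
a stage whose optional inputs are missing is skipped rather than
failing the run. Given the same inputs and seed, reruns produce
byte-identical reports.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._util import ensure_dir, sha256_file
from . import catalog as catalog_mod
from . import conservation as conservation_mod
from . import enzymes as enzymes_mod
from . import interface as interface_mod
from . import landscape as landscape_mod
from . import mutations as mutations_mod
from .errors import RbptmError
from .simulate import BUNDLE_FILES
from .vocabulary import default_vocabulary

logger = logging.getLogger(__name__)

STAGES = ("harmonize", "landscape", "conserve", "enzymes", "mutations",
          "interface", "eclip", "export")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    @property
    def all_completed(self):
        return all(s["status"] in ("completed", "skipped") for s in self.stages)

    def record(self, name, status, outputs=(), note=""):
        self.stages.append({"name": name, "status": status,
                            "outputs": sorted(str(o) for o in outputs), "note": note})
        logger.info("stage %s: %s %s", name, status, note)

    def to_json(self):
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


class _Context:
    """Shared state the stages hand each other."""

    def __init__(self, bundle, out, config):
        self.bundle = Path(bundle)
        self.out = ensure_dir(out)
        self.config = config
        self.vocabulary = default_vocabulary()
        self.proteome = None
        self.rbpome = None
        self.sites = None
        self.windows = None

    def path(self, key):
        return self.bundle / BUNDLE_FILES[key]

    def has(self, key):
        return self.path(key).exists()


def _write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# stages

def _stage_harmonize(ctx):
    ctx.proteome = catalog_mod.read_proteome(ctx.path("proteome"))
    lists = [catalog_mod.read_accession_list(ctx.bundle / name)
             for name in BUNDLE_FILES["rbp_lists"] if (ctx.bundle / name).exists()]
    ctx.rbpome = catalog_mod.build_rbpome(lists, ctx.proteome) if lists else {
        a for a, p in ctx.proteome.items() if p.is_rbp}
    catalogs = []
    for key, source in (("catalog_a", "catalog_a"), ("catalog_b", "catalog_b")):
        if ctx.has(key):
            catalogs.append(catalog_mod.load_ptm_catalog(
                ctx.path(key), "generic", ctx.vocabulary, source=source))
    if not catalogs:
        raise RbptmError("no PTM catalog files in bundle")
    report = catalog_mod.UnifyReport()
    ctx.sites = catalog_mod.unify_catalogs(catalogs, ctx.proteome, report=report)
    sites_path = ctx.out / "unified_sites.tsv"
    catalog_mod.export_atlas(ctx.sites, ctx.proteome, sites_path)
    report_path = _write_tsv(
        ctx.out / "harmonize_report.tsv",
        ("metric", "value"),
        [("n_input_sites", report.n_input),
         ("n_unknown_accession", report.n_unknown_accession),
         ("n_out_of_range", report.n_out_of_range),
         ("n_residue_conflict", report.n_residue_conflict),
         ("n_unified_sites", report.n_unified),
         ("n_rbps", len(ctx.rbpome))])
    return [sites_path, report_path]


def _stage_landscape(ctx):
    profiles = landscape_mod.type_count_profiles(ctx.sites, ctx.proteome)
    types = sorted({s.ptm_type for s in ctx.sites})
    profile_path = _write_tsv(
        ctx.out / "type_count_profiles.tsv",
        ("accession", "is_rbp", "total_sites", "n_types") + tuple(types),
        [(a, int(ctx.proteome[a].is_rbp), p.total, p.n_types)
         + tuple(p.counts.get(t, 0) for t in types)
         for a, p in sorted(profiles.items())])
    results = landscape_mod.ptm_enrichment_tests(ctx.sites, ctx.rbpome, ctx.proteome,
                                                 ctx.config)
    enrich_path = _write_tsv(
        ctx.out / "enrichment.tsv",
        ("ptm_type", "rbp_modified", "rbp_unmodified", "other_modified",
         "other_unmodified", "chi2", "p_raw", "p_adjusted", "direction",
         "significant", "undefined"),
        [(r.ptm_type, r.table[0][0], r.table[0][1], r.table[1][0], r.table[1][1],
          f"{r.statistic:.6g}", f"{r.p_raw:.6g}", f"{r.p_adjusted:.6g}",
          r.direction, int(r.significant), int(r.undefined)) for r in results])
    multi_rows = [(t, f"{landscape_mod.multi_site_fraction(ctx.sites, t):.6f}")
                  for t in types]
    multi_path = _write_tsv(ctx.out / "multi_site_fraction.tsv",
                            ("ptm_type", "fraction_multi"), multi_rows)
    combos = landscape_mod.top_type_combinations(profiles)
    combo_path = _write_tsv(
        ctx.out / "type_combinations.tsv", ("ptm_types", "n_proteins"),
        [("+".join(sorted(ts)), n) for ts, n in combos])
    return [profile_path, enrich_path, multi_path, combo_path]


def _stage_conserve(ctx):
    profiles = conservation_mod.read_conservation(ctx.path("conservation"), ctx.proteome)
    positions = {}
    for site in ctx.sites:
        positions.setdefault(site.accession, set()).add(site.position)
    contrasts = []
    for accession in sorted(profiles):
        if accession not in positions:
            continue
        contrast = conservation_mod.protein_contrast(
            profiles[accession], positions[accession], ctx.config)
        if contrast is not None:
            contrasts.append(contrast)
    summary = conservation_mod.cohort_summary(contrasts, ctx.config)
    contrast_path = _write_tsv(
        ctx.out / "conservation_contrasts.tsv",
        ("accession", "ptm_mean", "background_mean", "more_conserved", "n_background"),
        [(c.accession, f"{c.ptm_mean:.6f}", f"{c.background_mean:.6f}",
          int(c.more_conserved), c.n_background) for c in contrasts])
    summary_path = _write_tsv(
        ctx.out / "conservation_summary.tsv", ("metric", "value"),
        [("n_proteins", summary.n_proteins),
         ("frac_more_conserved", f"{summary.frac_more_conserved:.6f}"),
         ("frac_high_conservation", f"{summary.frac_high_conservation:.6f}"),
         ("ks_statistic", f"{summary.ks_statistic:.6f}"),
         ("ks_p", f"{summary.ks_p:.6g}")])
    return [contrast_path, summary_path]


def _stage_enzymes(ctx):
    edges = enzymes_mod.read_ppi_edges(ctx.path("ppi_edges"))
    annotations = enzymes_mod.read_enzyme_annotations(ctx.path("enzymes"))
    nonenzymatic = ctx.vocabulary.nonenzymatic
    matrix = enzymes_mod.me_matrix(ctx.rbpome, ctx.sites, edges, annotations,
                                   nonenzymatic=nonenzymatic)
    matrix_path = ctx.out / "me_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t", index_label="accession")
    counts = enzymes_mod.count_modifying_interactions(ctx.sites, edges, annotations,
                                                      ctx.rbpome,
                                                      nonenzymatic=nonenzymatic)
    counts_path = _write_tsv(ctx.out / "modifying_interactions.tsv",
                             ("ptm_type", "n_interactions"),
                             sorted(counts.items()))
    per_enzyme = enzymes_mod.rbp_count_per_enzyme(ctx.sites, edges, annotations,
                                                  ctx.rbpome)
    enzyme_path = _write_tsv(ctx.out / "rbps_per_enzyme.tsv",
                             ("enzyme", "n_rbps"), sorted(per_enzyme.items()))
    return [matrix_path, counts_path, enzyme_path]


def _stage_mutations(ctx):
    records = mutations_mod.read_mutations(ctx.path("mutations"), ctx.proteome)
    at = mutations_mod.mutations_at_sites(records, ctx.sites)
    near = mutations_mod.mutations_near_sites(records, ctx.sites, ctx.config.proximity_k)
    summary_path = _write_tsv(
        ctx.out / "mutation_summary.tsv", ("metric", "value"),
        [("n_mutations", len(records)),
         ("at_site_pairs", len(at.hits)),
         ("at_site_mutations", at.n_unique_mutations),
         ("at_site_proteins", at.n_unique_proteins),
         ("near_site_pairs", len(near.hits)),
         ("near_site_mutations", near.n_unique_mutations),
         ("near_site_proteins", near.n_unique_proteins),
         ("proximity_k", ctx.config.proximity_k)])
    ranked = mutations_mod.rank_site_mutations(at.hits)
    ranked_path = _write_tsv(
        ctx.out / "ranked_site_mutations.tsv",
        ("accession", "position", "ptm_type", "total_cases", "cancer_types"),
        [(a, p, t, n, ";".join(sorted(c))) for a, p, t, n, c in ranked])
    hits_path = _write_tsv(
        ctx.out / "mutation_hits.tsv",
        ("accession", "mutation_position", "site_position", "ptm_type", "distance",
         "cancer_type", "case_count"),
        sorted((h.mutation.accession, h.mutation.position, h.site.position,
                h.site.ptm_type, h.distance, h.mutation.cancer_type,
                h.mutation.case_count) for h in near.hits))
    return [summary_path, ranked_path, hits_path]


def _stage_interface(ctx):
    crosslinks = interface_mod.read_crosslinks(ctx.path("crosslinks"))
    windows = interface_mod.standardize_all(crosslinks, ctx.proteome,
                                            ctx.config.window_size)
    ctx.windows = windows
    assignments = interface_mod.assign_ptm_distances(sorted(ctx.sites, key=lambda s: s.key),
                                                     windows)
    h = ctx.config.half_window
    opportunities = interface_mod.distance_opportunities(windows, h)
    overall = interface_mod.distance_frequency_stats(assignments, h=h,
                                                     opportunities=opportunities)
    bins_path = _write_tsv(
        ctx.out / "distance_bins.tsv", ("distance", "count", "opportunity", "frequency"),
        [(d, int(overall.counts[d]), int(opportunities[d]), f"{overall.frequencies[d]:.6g}")
         for d in range(h + 1)])
    rows = [("all", f"{overall.rho:.6f}", f"{overall.p:.6g}", overall.flag)]
    for ptm_type in sorted({s.ptm_type for s in ctx.sites}):
        st = interface_mod.distance_frequency_stats(assignments, ptm_type=ptm_type, h=h,
                                                    opportunities=opportunities)
        rows.append((ptm_type, f"{st.rho:.6f}", f"{st.p:.6g}", st.flag))
    corr_path = _write_tsv(ctx.out / "distance_correlation.tsv",
                           ("ptm_type", "spearman_rho", "p", "flag"), rows)
    outputs = [bins_path, corr_path]
    distances = interface_mod.nearest_center_distances(
        sorted(ctx.sites, key=lambda s: s.key), windows)
    try:
        contrast = interface_mod.group_contrast(distances, ctx.proteome, "hnRNP")
        outputs.append(_write_tsv(
            ctx.out / "group_contrast.tsv", ("metric", "value"),
            [("tag", "hnRNP"), ("mean_tagged", f"{contrast.mean_a:.4f}"),
             ("mean_other", f"{contrast.mean_b:.4f}"),
             ("t_statistic", f"{contrast.t_statistic:.4f}"),
             ("p", f"{contrast.p:.6g}"),
             ("n_tagged", contrast.n_a), ("n_other", contrast.n_b)]))
    except RbptmError as exc:
        logger.info("group contrast skipped: %s", exc)
    return outputs


def _stage_eclip(ctx):
    rep1 = interface_mod.read_narrowpeak(ctx.path("eclip_rep1"), replicate="rep1")
    rep2 = interface_mod.read_narrowpeak(ctx.path("eclip_rep2"), replicate="rep2")
    genes = interface_mod.read_genes_bed(ctx.path("genes"))
    hits = interface_mod.eclip_gene_hits(rep1, rep2, genes, ctx.config.overlap_fraction)
    return [_write_tsv(ctx.out / "eclip_hits.tsv", ("rbp", "gene_id"), sorted(hits))]


def _stage_export(ctx):
    path = ctx.out / "atlas.tsv"
    n = catalog_mod.export_atlas(ctx.sites, ctx.proteome, path)
    logger.info("atlas: wrote %d rows", n)
    return [path]


_STAGE_FUNCS = {
    "harmonize": (_stage_harmonize, ("proteome",)),
    "landscape": (_stage_landscape, ()),
    "conserve": (_stage_conserve, ("conservation",)),
    "enzymes": (_stage_enzymes, ("ppi_edges", "enzymes")),
    "mutations": (_stage_mutations, ("mutations",)),
    "interface": (_stage_interface, ("crosslinks",)),
    "eclip": (_stage_eclip, ("eclip_rep1", "eclip_rep2", "genes")),
    "export": (_stage_export, ()),
}


def run_pipeline(config, bundle_dir, out_dir, stages=None):
    """Run the requested stages (all by default) over a bundle directory;
    returns the run manifest, also persisted as ``manifest.json``."""
    config.validate()
    ctx = _Context(bundle_dir, out_dir, config)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           version=__version__)
    for key in ("proteome", "catalog_a", "catalog_b", "ppi_edges", "enzymes",
                "mutations", "crosslinks", "conservation", "eclip_rep1",
                "eclip_rep2", "genes"):
        if ctx.has(key):
            manifest.input_checksums[BUNDLE_FILES[key]] = sha256_file(ctx.path(key))

    selected = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    for name in selected:
        func, required = _STAGE_FUNCS[name]
        missing = [BUNDLE_FILES[key] for key in required if not ctx.has(key)]
        if missing:
            manifest.record(name, "skipped", note=f"missing inputs: {missing}")
            continue
        if name != "harmonize" and ctx.sites is None:
            manifest.record(name, "skipped", note="harmonize did not run")
            continue
        try:
            outputs = func(ctx)
        except Exception as exc:  # recorded, remaining stages still attempted
            logger.exception("stage %s failed", name)
            manifest.record(name, "failed", note=str(exc))
            continue
        manifest.record(name, "completed", outputs=[Path(o).name for o in outputs])
    (ctx.out / "manifest.json").write_text(manifest.to_json())
    return manifest
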