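"""PTM landscape statistics: per-protein type profiles, modification
densities, RBP-vs-background enrichment tests, multi-site fractions and
per-type cumulative distributions.

The enrichment contrast is, for each PTM type, a 2x2 chi-squared test of
"carries >=1 site of the type" against RBP membership. By default the
groups are disjoint (RBPs vs non-RBPs); an overlapping variant (RBPs vs
all proteins) is available behind a flag. P-values are Bonferroni
adjusted with family size m = number of PTM types that modify at least
one protein.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = __import__("logging").getLogger(__name__)


@dataclass
class TypeCountProfile:
    accession: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self):
        return sum(self.counts.values())

    @property
    def n_types(self):
        return sum(1 for c in self.counts.values() if c > 0)

    @property
    def type_set(self):
        return frozenset(t for t, c in self.counts.items() if c > 0)


@dataclass
class EnrichmentResult:
    ptm_type: str
    table: tuple  # ((rbp_modified, rbp_unmodified), (other_modified, other_unmodified))
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # "rbp_higher" | "rbp_lower" | "equal"
    significant: bool
    undefined: bool = False


def type_count_profiles(sites, proteome):
    """One profile per protein in the proteome (a zero profile for
    unmodified proteins)."""
    per_protein = defaultdict(Counter)
    for site in sites:
        if site.accession in proteome:
            per_protein[site.accession][site.ptm_type] += 1
    return {
        accession: TypeCountProfile(accession, dict(per_protein.get(accession, {})))
        for accession in proteome
    }


def modification_density(protein, sites):
    """Sites on the protein divided by its length in residues (the
    denominator is the full length, modified or not)."""
    n = sum(1 for s in sites if s.accession == protein.accession)
    return n / protein.length


def density_group_comparison(sites, proteome):
    """Per-protein modification densities, RBPs versus non-RBPs, with a
    Welch two-sample t-test. Returns (mean_rbp, mean_other, t, p)."""
    counts = Counter(s.accession for s in sites)
    rbp = [counts.get(a, 0) / p.length for a, p in proteome.items() if p.is_rbp]
    other = [counts.get(a, 0) / p.length for a, p in proteome.items() if not p.is_rbp]
    t, p = stats.ttest_ind(rbp, other, equal_var=False)
    return float(np.mean(rbp)), float(np.mean(other)), float(t), float(p)


def ptm_enrichment_tests(sites, rbpome, proteome, config, overlapping=False, yates=False):
    """Chi-squared enrichment of each PTM type in RBPs, Bonferroni adjusted.

    ``overlapping=True`` contrasts RBPs against all proteins (the two
    groups then share the RBPs) instead of the default disjoint
    RBP/non-RBP split. A degenerate 2x2 table (zero margin) yields an
    undefined-flagged result rather than an exception.
    """
    modified_by_type = defaultdict(set)
    for site in sites:
        if site.accession in proteome:
            modified_by_type[site.ptm_type].add(site.accession)
    types = sorted(t for t, accs in modified_by_type.items() if accs)
    m = len(types)
    rbps = {a for a in rbpome if a in proteome}
    non_rbps = set(proteome) - rbps
    background = set(proteome) if overlapping else non_rbps

    results = []
    for ptm_type in types:
        modified = modified_by_type[ptm_type]
        a = len(modified & rbps)
        b = len(rbps) - a
        c = len(modified & background)
        d = len(background) - c
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            results.append(EnrichmentResult(ptm_type, ((a, b), (c, d)), math.nan,
                                            math.nan, math.nan, "equal", False, undefined=True))
            continue
        stat, p_raw, _, _ = stats.chi2_contingency(table, correction=yates)
        prop_rbp = a / (a + b)
        prop_bg = c / (c + d)
        direction = ("rbp_higher" if prop_rbp > prop_bg
                     else "rbp_lower" if prop_rbp < prop_bg else "equal")
        p_adj = min(1.0, p_raw * m)
        results.append(EnrichmentResult(ptm_type, ((a, b), (c, d)), float(stat),
                                        float(p_raw), float(p_adj), direction,
                                        bool(p_adj < config.alpha)))
    return results


def _per_protein_type_counts(sites, ptm_type):
    counts = Counter(s.accession for s in sites if s.ptm_type == ptm_type)
    if not counts:
        raise ValueError(f"no protein carries PTM type {ptm_type!r}")
    return counts


def multi_site_fraction(sites, ptm_type):
    """Of the proteins carrying >=1 site of the type, the fraction
    carrying >=2."""
    counts = _per_protein_type_counts(sites, ptm_type)
    return sum(1 for c in counts.values() if c >= 2) / len(counts)


def site_count_cdf(sites, ptm_type):
    """Empirical CDF of per-protein site counts for one PTM type, over
    integer thresholds 1..max; nondecreasing and terminating at 1.0."""
    counts = _per_protein_type_counts(sites, ptm_type)
    values = np.array(sorted(counts.values()))
    out = []
    for k in range(1, int(values.max()) + 1):
        out.append((k, float(np.mean(values <= k))))
    return out


def top_type_combinations(profiles):
    """Ranked (PTM-type set, protein count) list; each modified protein
    contributes its exact set of distinct types. Ties are broken
    lexicographically on the sorted type labels."""
    tally = Counter(p.type_set for p in profiles.values() if p.type_set)
    return sorted(tally.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0]))))
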