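"""Crosslink window standardization, distance statistics and eCLIP overlap."""
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbptm.errors import CatalogFormatError, RbptmError
from rbptm.interface import (assign_ptm_distances, distance_frequency_stats,
                             distance_opportunities, eclip_gene_hits,
                             group_contrast, nearest_center_distances,
                             read_genes_bed, read_genes_gtf, read_narrowpeak,
                             standardize_window, write_genes_bed, write_narrowpeak)
from rbptm.types import CrosslinkRange, GeneModel, NarrowPeak

from conftest import make_proteome, make_site


class TestStandardizeWindow:
    def test_range_already_21_kept(self):
        w = standardize_window(CrosslinkRange("P1", 40, 60), 200, 21)
        assert (w.start, w.center, w.end) == (40, 50, 60)

    def test_longer_range_truncated_around_center(self):
        w = standardize_window(CrosslinkRange("P1", 10, 60), 200, 21)
        assert (w.start, w.center, w.end) == (25, 35, 45)

    def test_short_range_near_boundary_clipped_without_shift(self):
        w = standardize_window(CrosslinkRange("P1", 1, 5), 100, 21)
        assert (w.start, w.center, w.end) == (1, 3, 13)

    def test_range_outside_protein_raises(self):
        with pytest.raises(RbptmError, match="P1"):
            standardize_window(CrosslinkRange("P1", 90, 120), 100, 21)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            standardize_window(CrosslinkRange("P1", 10, 20), 100, 20)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_window_invariants(self, data):
        length = data.draw(st.integers(30, 2000))
        start = data.draw(st.integers(1, length))
        end = data.draw(st.integers(start, length))
        w = 21
        window = standardize_window(CrosslinkRange("P", start, end), length, w)
        assert 1 <= window.start <= window.center <= window.end <= length
        assert window.end - window.start + 1 <= w
        # feasible length is attained: only protein boundaries shrink it
        half = (w - 1) // 2
        assert window.start == max(1, window.center - half)
        assert window.end == min(length, window.center + half)
        if end - start + 1 >= w:
            assert start <= window.start and window.end <= end  # truncation subset


class TestAssignDistances:
    def test_center_and_boundary(self):
        window = standardize_window(CrosslinkRange("P1", 40, 60), 200, 21)
        at = lambda p: assign_ptm_distances([make_site("P1", p)], [window])
        assert at(50)[0].distance == 0
        assert at(60)[0].distance == 10
        assert at(61) == []  # outside the 21-position window

    def test_multiset_matches_brute_force(self, rng):
        proteome = make_proteome({f"P{i}": 600 for i in range(100)})
        windows = []
        for _ in range(300):
            acc = f"P{rng.integers(100)}"
            start = int(rng.integers(1, 560))
            end = int(rng.integers(start, min(600, start + 50)))
            windows.append(standardize_window(CrosslinkRange(acc, start, end), 600))
        sites = [make_site(f"P{rng.integers(100)}", int(rng.integers(1, 601)))
                 for _ in range(2000)]
        sites = list({s.key: s for s in sites}.values())
        assignments = assign_ptm_distances(sites, windows)
        brute = Counter()
        for s in sites:
            for w in windows:
                if w.accession == s.accession and w.start <= s.position <= w.end:
                    brute[abs(s.position - w.center)] += 1
        assert Counter(a.distance for a in assignments) == brute
        assert all(a.distance <= 10 for a in assignments)


class TestDistanceStats:
    def _assignments(self, counts):
        """Build synthetic assignments with given per-distance counts."""
        window = standardize_window(CrosslinkRange("P1", 100, 120), 400, 21)
        out = []
        for d, n in enumerate(counts):
            for i in range(n):
                out.append(assign_ptm_distances(
                    [make_site("P1", window.center + d, "phosphorylation")],
                    [window])[0])
        return out

    def test_strictly_decreasing_counts_give_rho_minus_one(self):
        stats = distance_frequency_stats(self._assignments(range(22, 0, -2)))
        assert stats.rho == pytest.approx(-1.0)

    def test_equal_counts_all_ties_convention(self):
        stats = distance_frequency_stats(self._assignments([3] * 11))
        assert stats.rho == 0.0 and stats.flag == "all_ties"

    def test_per_site_mode_agrees_in_sign(self):
        assignments = self._assignments(range(22, 0, -2))
        binned = distance_frequency_stats(assignments)
        per_site = distance_frequency_stats(assignments, per_site=True)
        assert per_site.rho < 0 and binned.rho < 0
        assert per_site.p < 0.05

    def test_single_bin_undefined(self):
        stats = distance_frequency_stats(self._assignments([5] + [0] * 10))
        assert stats.flag == "undefined" and np.isnan(stats.rho)

    def test_opportunity_normalization_flattens_uniform(self):
        """An unclipped window offers 1 position at distance 0 and 2 at
        each other distance; uniform placement is flat only after
        normalization."""
        window = standardize_window(CrosslinkRange("P1", 100, 120), 400, 21)
        sites = [make_site("P1", p) for p in range(window.start, window.end + 1)]
        assignments = assign_ptm_distances(sites, [window])
        opp = distance_opportunities([window])
        np.testing.assert_array_equal(opp, [1] + [2] * 10)
        stats = distance_frequency_stats(assignments, opportunities=opp)
        assert stats.flag == "all_ties" and stats.rho == 0.0

    def test_planted_decay_recovered(self):
        """Geometric decay 0.7 over 5000 sites: strong negative rank
        correlation between distance and frequency."""
        from rbptm.simulate import SimulationSpec, generate_crosslink_study, generate_proteome
        spec = SimulationSpec(n_proteins=300, rbp_fraction=1.0, decayed_share=1.0,
                              decayed_share_tagged=1.0, ptm_decay=0.7,
                              crosslink_sites_per_protein=20.0, seed=42)
        proteome = generate_proteome(spec)
        crosslinks, sites = generate_crosslink_study(proteome, spec)
        assert len(sites) >= 5000
        from rbptm.interface import standardize_all
        windows = standardize_all(crosslinks, proteome)
        assignments = assign_ptm_distances(sites, windows)
        stats = distance_frequency_stats(
            assignments, opportunities=distance_opportunities(windows))
        assert stats.rho <= -0.8 and stats.p < 0.01

    def test_uniform_null_rho_small_and_decay_always_negative(self):
        """Property: |rho| < 0.5 in >= 95% of uniform replicates; rho < 0
        in all planted-decay replicates."""
        from rbptm.simulate import SimulationSpec, generate_crosslink_study, generate_proteome
        from rbptm.interface import standardize_all

        def rho_for(decayed_share, seed):
            spec = SimulationSpec(n_proteins=150, rbp_fraction=1.0,
                                  decayed_share=decayed_share,
                                  decayed_share_tagged=decayed_share,
                                  crosslink_sites_per_protein=30.0, seed=seed)
            proteome = generate_proteome(spec)
            crosslinks, sites = generate_crosslink_study(proteome, spec)
            windows = standardize_all(crosslinks, proteome)
            stats = distance_frequency_stats(
                assign_ptm_distances(sites, windows),
                opportunities=distance_opportunities(windows))
            return stats.rho

        null_rhos = [rho_for(0.0, seed) for seed in range(20)]
        assert np.mean(np.abs(null_rhos) < 0.5) >= 0.95
        decay_rhos = [rho_for(1.0, seed) for seed in range(20)]
        assert all(r < 0 for r in decay_rhos)


class TestGroupContrast:
    def test_nearest_distance_single_window(self):
        window = standardize_window(CrosslinkRange("P1", 95, 105), 400, 21)
        distances = nearest_center_distances([make_site("P1", 130)], [window])
        assert list(distances.values()) == [30]

    def test_sites_without_windows_excluded(self):
        window = standardize_window(CrosslinkRange("P1", 95, 105), 400, 21)
        distances = nearest_center_distances(
            [make_site("P1", 10), make_site("P2", 10)], [window])
        assert {s.accession for s in distances} == {"P1"}

    def test_identical_groups_t_zero(self):
        proteome = make_proteome({"P1": 400, "P2": 400}, tags={"P1": {"hnRNP"}})
        w1 = standardize_window(CrosslinkRange("P1", 95, 105), 400, 21)
        w2 = standardize_window(CrosslinkRange("P2", 95, 105), 400, 21)
        sites = [make_site(a, p) for a in ("P1", "P2") for p in (110, 120, 130)]
        distances = nearest_center_distances(sites, [w1, w2])
        contrast = group_contrast(distances, proteome, "hnRNP")
        assert contrast.t_statistic == pytest.approx(0.0)
        assert contrast.mean_a == contrast.mean_b

    def test_small_group_raises(self):
        proteome = make_proteome({"P1": 400}, tags={"P1": {"hnRNP"}})
        w = standardize_window(CrosslinkRange("P1", 95, 105), 400, 21)
        distances = nearest_center_distances([make_site("P1", 110)], [w])
        with pytest.raises(RbptmError):
            group_contrast(distances, proteome, "hnRNP")

    def test_tagged_proteins_with_planted_proximity(self):
        """Proteins whose PTMs are planted near window centers show a
        smaller mean nearest distance (recovery simulation)."""
        from rbptm.simulate import SimulationSpec, generate_crosslink_study, generate_proteome
        from rbptm.interface import standardize_all
        spec = SimulationSpec(n_proteins=400, rbp_fraction=1.0, hnrnp_fraction=0.5,
                              decayed_share=0.1, decayed_share_tagged=0.95,
                              crosslink_sites_per_protein=8.0, seed=17)
        proteome = generate_proteome(spec)
        crosslinks, sites = generate_crosslink_study(proteome, spec)
        windows = standardize_all(crosslinks, proteome)
        distances = nearest_center_distances(sites, windows)
        contrast = group_contrast(distances, proteome, "hnRNP")
        assert contrast.mean_a < contrast.mean_b
        assert contrast.p < 0.01


def gene(gene_id, chrom, start, end, strand):
    return GeneModel(gene_id, chrom, start, end, strand)


def peak(rbp, chrom, start, end, strand, name="pk"):
    return NarrowPeak(chrom, start, end, name, 100.0, strand, rbp=rbp)


class TestEclip:
    GENES = [gene("G1", "chr1", 1000, 2000, "+"), gene("G2", "chr1", 3000, 4000, "-")]

    def test_full_overlap_both_replicates_is_hit(self):
        p = [peak("R", "chr1", 1200, 1300, "+")]
        assert eclip_gene_hits(p, p, self.GENES) == {("R", "G1")}

    def test_forty_percent_overlap_rejected_at_half(self):
        p = [peak("R", "chr1", 940, 1040, "+")]  # 40 of 100 bases inside G1
        assert eclip_gene_hits(p, p, self.GENES) == set()
        assert eclip_gene_hits(p, p, self.GENES, f=0.4) == {("R", "G1")}

    def test_opposite_strand_rejected(self):
        p = [peak("R", "chr1", 1200, 1300, "-")]
        assert eclip_gene_hits(p, p, self.GENES) == set()

    def test_requires_both_replicates(self):
        p1 = [peak("R", "chr1", 1200, 1300, "+")]
        assert eclip_gene_hits(p1, [], self.GENES) == set()
        assert eclip_gene_hits([], p1, self.GENES) == set()

    def test_symmetric_and_order_invariant(self, rng):
        peaks1, peaks2, genes = self._random_fixture(rng)
        hits = eclip_gene_hits(peaks1, peaks2, genes)
        assert eclip_gene_hits(peaks2, peaks1, genes) == hits
        shuffled = list(peaks1)
        rng.shuffle(shuffled)
        assert eclip_gene_hits(shuffled, peaks2, genes) == hits

    def _random_fixture(self, rng, n_peaks=500, n_genes=50):
        genes = []
        for g in range(n_genes):
            start = int(rng.integers(0, 90_000))
            genes.append(gene(f"G{g}", f"chr{1 + g % 2}", start,
                              start + int(rng.integers(500, 5000)),
                              "+" if rng.random() < 0.5 else "-"))
        def peaks(rep):
            out = []
            for i in range(n_peaks):
                start = int(rng.integers(0, 99_000))
                out.append(peak(f"R{rng.integers(5)}", f"chr{1 + int(rng.integers(2))}",
                                start, start + int(rng.integers(50, 600)),
                                "+" if rng.random() < 0.5 else "-", name=f"{rep}_{i}"))
            return out
        return peaks("a"), peaks("b"), genes

    def test_matches_brute_force_all_pairs(self, rng):
        peaks1, peaks2, genes = self._random_fixture(rng)
        hits = eclip_gene_hits(peaks1, peaks2, genes)

        def brute(peaks):
            out = set()
            for p in peaks:
                for g in genes:
                    if p.chrom != g.chrom or p.strand != g.strand:
                        continue
                    overlap = min(p.end, g.end) - max(p.start, g.start)
                    if overlap > 0 and overlap / (p.end - p.start) >= 0.5:
                        out.add((p.rbp, g.gene_id))
            return out

        assert hits == brute(peaks1) & brute(peaks2)


class TestInterfaceIO:
    def test_narrowpeak_round_trip_and_line_errors(self, tmp_path):
        peaks = [peak("R1", "chr1", 100, 200, "+", name="R1_p0"),
                 peak("R1", "chr2", 300, 450, "-", name="R1_p1")]
        write_narrowpeak(peaks, tmp_path / "p.narrowPeak")
        back = read_narrowpeak(tmp_path / "p.narrowPeak", rbp="R1")
        assert [(p.chrom, p.start, p.end, p.strand) for p in back] == \
            [(p.chrom, p.start, p.end, p.strand) for p in peaks]
        bad = tmp_path / "bad.narrowPeak"
        bad.write_text("chr1\t100\t200\tx\t0\t+\t0\t-1\t-1\t-1\nchr1\tzz\n")
        with pytest.raises(CatalogFormatError, match="row 2"):
            read_narrowpeak(bad)

    def test_gene_bed_round_trip(self, tmp_path):
        genes = [gene("G1", "chr1", 10, 500, "+"), gene("G2", "chr2", 100, 900, "-")]
        write_genes_bed(genes, tmp_path / "g.bed")
        assert read_genes_bed(tmp_path / "g.bed") == genes

    def test_gtf_reader_converts_to_half_open(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\thavana\tgene\t11\t500\t.\t+\t.\tgene_id "G1"; gene_name "X";\n'
            'chr2\thavana\tgene\t101\t900\t.\t-\t.\tgene_id "G2";\n')
        genes = read_genes_gtf(gtf)
        assert genes == [gene("G1", "chr1", 10, 500, "+"),
                         gene("G2", "chr2", 100, 900, "-")]
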