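"""Neighbor windows, GC correlations, lengths, divergent pairs, TSS annotation."""

import numpy as np
import pytest

from circaparam.genesets import GeneLocus
from circaparam.genome import (
    BindingSite,
    LocusIndex,
    MethylationProbe,
    annotate_methylation_probes,
    annotate_sites_to_tss,
    correlate_group_gc,
    count_neighbors,
    find_divergent_pairs,
    length_statistics,
    neighbor_profile,
)


def locus(lid, start, end, strand="+", chrom="chr1", **kw):
    return GeneLocus(lid, chrom, strand, start, end, **kw)


def brute_force_neighbors(loci, target, window):
    """All-pairs interval-overlap oracle using the same edge rule."""
    same = sorted(
        (l for l in loci if l.chromosome == target.chromosome),
        key=lambda l: (l.start, l.end, l.locus_id),
    )
    first = same[0].locus_id == target.locus_id
    last = same[-1].locus_id == target.locus_id
    if first and last:
        lo, hi = target.start, target.end
    elif first:
        lo, hi = target.start, target.end + window
    elif last:
        lo, hi = max(0, target.start - window), target.end
    else:
        lo, hi = max(0, target.start - window / 2), target.end + window / 2
    return sum(
        1 for l in same if l.locus_id != target.locus_id and l.start < hi and l.end > lo
    )


class TestCountNeighbors:
    flank = [locus("c", 0, 1000), locus("d", 1_000_000, 1_001_000)]
    a = locus("a", 100_000, 101_000)
    b = locus("b", 150_000, 151_000)

    def test_sole_gene_zero(self):
        assert count_neighbors([self.a], self.a, 150_000) == 0

    def test_interior_window_overlap(self):
        loci = self.flank + [self.a, self.b]
        assert count_neighbors(loci, self.a, 150_000) == 1  # ext [25k, 176k)
        assert count_neighbors(loci, self.a, 60_000) == 0  # ext [70k, 131k)

    def test_edge_locus_extends_one_side_full_window(self):
        loci = [locus("first", 0, 1_000), locus("mid", 60_500, 61_500), locus("last", 500_000, 501_000)]
        # first: [0, 1000 + 60000) reaches mid
        assert count_neighbors(loci, loci[0], 60_000) == 1
        # interior mid at W=60k: [30.5k, 91.5k) misses both... first ends at 1000
        assert count_neighbors(loci, loci[1], 60_000) == 0

    def test_unknown_locus_rejected(self):
        with pytest.raises(ValueError, match="not in annotation"):
            count_neighbors([self.a], self.b, 10)

    def test_matches_brute_force_on_random_loci(self):
        rng = np.random.default_rng(3)
        loci = []
        for i in range(300):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 5_000_000))
            loci.append(locus(f"g{i}", start, start + int(rng.integers(500, 80_000)), chrom=chrom))
        index = LocusIndex(loci)
        for target in loci[::17]:
            for w in (0, 15_000, 150_000, 1_500_000):
                assert count_neighbors(index, target, w) == brute_force_neighbors(
                    loci, target, w
                )


class TestNeighborProfile:
    def test_isolated_gene_all_zero(self):
        prof = neighbor_profile([locus("a", 0, 1000)], ["a"], [0, 15_000, 150_000])
        assert (prof == 0).all()

    def test_window_zero_counts_body_overlaps_only(self):
        loci = [locus("a", 0, 1000), locus("b", 500, 1500), locus("c", 5000, 6000)]
        prof = neighbor_profile(loci, ["a"], [0])
        # a is the chromosome's first locus: at W=0 the extension is the body
        assert prof.iloc[0] == 1

    def test_monotone_in_window(self):
        rng = np.random.default_rng(8)
        loci = []
        for i in range(100):
            start = int(rng.integers(0, 2_000_000))
            loci.append(locus(f"g{i}", start, start + 10_000))
        prof = neighbor_profile(loci, [l.locus_id for l in loci], range(0, 600_000, 60_000))
        assert (np.diff(prof.values) >= 0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            neighbor_profile([locus("a", 0, 10)], [])


class TestGcCorrelation:
    def test_perfect_linear(self):
        gc = np.linspace(38, 50, 19)
        r, p = correlate_group_gc(gc, 2 * gc)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate_group_gc(np.linspace(38, 50, 10), np.full(10, 5.0))

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(12)
        x = rng.normal(45, 4, 19)
        y = 0.8 * (x - 45) / 4 + rng.normal(0, 0.6, 19)
        r, _ = correlate_group_gc(x, y)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)


class TestLengthStatistics:
    def test_single_gene(self):
        l = locus("a", 0, 10_000, cds_length=1200, utr3_length=900, utr5_length=150)
        stats = length_statistics([l])
        assert stats == {"genomic": 10_000, "utr5": 150, "utr3": 900, "cds": 1200}

    def test_odd_and_even_medians(self):
        loci = [locus(f"g{i}", 0, n * 10_000) for i, n in enumerate([1, 2, 3], 1)]
        assert length_statistics(loci)["genomic"] == 20_000
        loci.append(locus("g4", 0, 40_000))
        assert length_statistics(loci)["genomic"] == 25_000

    def test_missing_structures_excluded(self):
        loci = [
            locus("a", 0, 1000, utr3_length=500),
            locus("b", 0, 2000, utr3_length=None),
        ]
        assert length_statistics(loci)["utr3"] == 500

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            length_statistics([])


class TestDivergentPairs:
    def pair_loci(self, gap=500):
        left = locus("m", 1000, 5000, strand="-")
        right = locus("p", 5000 - 1 + gap, 9000 + gap, strand="+")
        return [left, right]

    def test_close_phases_pair(self):
        pairs = find_divergent_pairs(self.pair_loci(), {"m": 3.0, "p": 7.0})
        assert pairs == [("m", "p")]

    def test_distant_phases_do_not_pair(self):
        assert find_divergent_pairs(self.pair_loci(), {"m": 2.0, "p": 10.0}) == []

    def test_same_strand_never_pairs(self):
        loci = [locus("a", 1000, 5000, strand="+"), locus("b", 5400, 9000, strand="+")]
        assert find_divergent_pairs(loci, {"a": 3.0, "b": 4.0}) == []

    def test_gap_boundary(self):
        assert find_divergent_pairs(self.pair_loci(gap=1000), {"m": 1.0, "p": 1.0})
        assert not find_divergent_pairs(self.pair_loci(gap=1001), {"m": 1.0, "p": 1.0})

    def test_non_rhythmic_partner_blocks_pair(self):
        assert find_divergent_pairs(self.pair_loci(), {"m": 3.0}) == []


class TestSiteAnnotation:
    loci = [locus("a", 100_000, 120_000), locus("b", 400_000, 420_000)]

    def site(self, sid, pos, signal):
        return BindingSite(sid, "chr1", pos, (signal,) * 6)

    def test_site_beyond_50kb_dropped(self):
        retained, _ = annotate_sites_to_tss([self.site("s", 160_001, 5.0)], self.loci)
        assert retained == []

    def test_boundary_50kb_kept(self):
        retained, _ = annotate_sites_to_tss([self.site("s", 150_000, 5.0)], self.loci)
        assert retained[0].annotated_locus == "a"
        assert retained[0].distance_to_tss == 50_000

    def test_highest_signal_site_retained_per_locus(self):
        sites = [self.site("lo", 100_500, 5.0), self.site("hi", 101_000, 9.0)]
        retained, _ = annotate_sites_to_tss(sites, self.loci)
        assert [s.site_id for s in retained] == ["hi"]

    def test_group_percentages(self):
        sites = [self.site("s1", 100_100, 9.0), self.site("s2", 400_100, 5.0)]
        _, table = annotate_sites_to_tss(
            sites, self.loci, groups={"G": {"a"}}, top_ns=(1, None)
        )
        assert table.loc["1", "G"] == 100.0
        assert table.loc["all", "G"] == 50.0

    def test_unknown_chromosome_warns_and_drops(self):
        odd = BindingSite("x", "chrZ", 5, (1.0,) * 6)
        with pytest.warns(UserWarning, match="absent"):
            retained, _ = annotate_sites_to_tss([odd], self.loci)
        assert retained == []


class TestMethylationAnnotation:
    loci = [locus("a", 100_000, 120_000)]

    def probe(self, pid, center, m=0.5, cls="strong"):
        return MethylationProbe(pid, "chr1", center, m, cls)

    def test_beyond_2kb_unannotated(self):
        annotated, _ = annotate_methylation_probes([self.probe("p", 103_000)], self.loci)
        assert annotated == []

    def test_1kb_upstream_annotated(self):
        annotated, _ = annotate_methylation_probes([self.probe("p", 99_000)], self.loci)
        assert annotated[0].annotated_locus == "a"

    def test_multiple_probes_all_retained(self):
        probes = [self.probe("p1", 99_500, 0.1), self.probe("p2", 100_500, 0.9)]
        annotated, vectors = annotate_methylation_probes(
            probes, self.loci, groups={"G": {"a"}}
        )
        assert len(annotated) == 2
        np.testing.assert_allclose(sorted(vectors[("G", "strong")]), [0.1, 0.9])
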