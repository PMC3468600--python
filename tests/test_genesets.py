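"""Locus clustering, representative-probe selection, cutoff, partition, FPR."""

import numpy as np
import pytest

from circaparam.genesets import (
    GeneSetPartition,
    TranscriptFeature,
    cluster_features_to_loci,
    estimate_expression_cutoff,
    estimate_false_positive_rate,
    partition_gene_sets,
    select_representative_probe,
)
from circaparam.rhythm import RhythmCall, TimeCourseMatrix
from circaparam.utils import circular_phase_distance


def feature(tid, exons, strand="+", chrom="chr1", cds=None):
    return TranscriptFeature(tid, chrom, strand, exons, cds)


class TestLocusClustering:
    def test_shared_donor_site_joins(self):
        a = feature("a", [(0, 100), (200, 300)])
        b = feature("b", [(50, 100), (250, 320)])  # shares donor at 100
        assert len(cluster_features_to_loci([a, b])) == 1

    def test_disjoint_single_exon_features_stay_apart(self):
        a = feature("a", [(0, 100)])
        b = feature("b", [(500, 600)])
        assert len(cluster_features_to_loci([a, b])) == 2

    def test_transitive_closure_through_single_exon_overlap(self):
        a = feature("a", [(0, 100), (200, 300)])
        b = feature("b", [(50, 100), (250, 400)])  # shares donor 100 with a
        c = feature("c", [(350, 500)])  # single exon overlapping b only
        loci = cluster_features_to_loci([a, b, c])
        assert len(loci) == 1
        assert loci[0].members == ("a", "b", "c")

    def test_different_chromosomes_never_join(self):
        a = feature("a", [(0, 100), (200, 300)])
        b = feature("b", [(0, 100), (200, 300)], chrom="chr2")
        assert len(cluster_features_to_loci([a, b])) == 2

    def test_multi_exon_overlap_without_shared_site_stays_apart(self):
        a = feature("a", [(0, 100), (200, 300)])
        b = feature("b", [(10, 110), (210, 310)])
        assert len(cluster_features_to_loci([a, b])) == 2

    def test_representative_most_exons_then_longest(self):
        a = feature("a", [(0, 100), (200, 300)], cds=(50, 250))
        b = feature("b", [(0, 100), (200, 300), (400, 450)], cds=(50, 420))
        loci = cluster_features_to_loci([a, b])
        assert loci[0].representative_transcript == "b"

    def test_utr_lengths_follow_strand(self):
        plus = feature("p", [(0, 100), (200, 400)], cds=(40, 260), strand="+")
        (locus,) = cluster_features_to_loci([plus])
        assert locus.utr5_length == 40
        assert locus.cds_length == 60 + 60
        assert locus.utr3_length == 140
        minus = feature("m", [(0, 100), (200, 400)], cds=(40, 260), strand="-")
        (locus,) = cluster_features_to_loci([minus])
        assert locus.utr5_length == 140
        assert locus.utr3_length == 40
        assert locus.tss == 399


def call(rid, q, period=24.0, phase=0.0):
    return RhythmCall(rid, period, phase, 100.0, q / 2, q_value=q)


class TestRepresentativeProbe:
    def test_single_probe_is_representative(self):
        sel = select_representative_probe([call("p1", 1e-4)])
        assert not sel.excluded and sel.call.row_id == "p1"

    def test_lowest_q_wins(self):
        sel = select_representative_probe([call("p1", 5e-4), call("p2", 1e-4)])
        assert sel.call.row_id == "p2"

    def test_majority_inconsistency_excludes_locus(self):
        probes = [
            call("p1", 1e-4, phase=2.0),
            call("p2", 5e-4, phase=10.0),  # circular distance 8 > 6
            call("p3", 6e-4, phase=12.0),  # circular distance 10 > 6
        ]
        sel = select_representative_probe(probes)
        assert sel.excluded and sel.n_failing == 2

    def test_half_failing_is_not_excluded(self):
        probes = [call("p1", 1e-4, phase=2.0), call("p2", 5e-4, phase=10.0)]
        sel = select_representative_probe(probes)  # 1 of 2 fails: not > half
        assert not sel.excluded

    def test_period_boundary(self):
        ok = select_representative_probe([call("p1", 1e-4, period=24), call("p2", 5e-4, period=28)])
        assert not ok.excluded  # |delta| = 4 allowed
        sel = select_representative_probe(
            [call("p1", 1e-4, period=24), call("p2", 5e-4, period=28.5)]
        )
        assert sel.n_failing == 1

    def test_order_invariance(self):
        probes = [call(f"p{i}", q, phase=ph) for i, (q, ph) in
                  enumerate([(1e-4, 2.0), (3e-4, 4.0), (2e-4, 23.0)])]
        ids = set()
        for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            sel = select_representative_probe([probes[i] for i in perm])
            ids.add(sel.call.row_id)
        assert ids == {"p0"}

    def test_empty_input_is_exclusion(self):
        sel = select_representative_probe([])
        assert sel.excluded and sel.reason == "no rhythmic probes"

    def test_circular_distance_properties(self):
        assert circular_phase_distance(2.0, 23.0) == pytest.approx(3.0)
        assert circular_phase_distance(0.0, 12.0) == pytest.approx(12.0)
        rng = np.random.default_rng(0)
        for a, b in rng.uniform(0, 24, size=(50, 2)):
            assert circular_phase_distance(a, b) <= 12.0
            assert circular_phase_distance(a, b) == pytest.approx(
                circular_phase_distance(b, a)
            )


class TestExpressionCutoff:
    def test_known_mixture_midpoint(self):
        rng = np.random.default_rng(42)
        values = np.concatenate(
            [rng.normal(1.0, 0.1, 5000), rng.normal(2.0, 0.1, 5000)]
        )
        assert estimate_expression_cutoff(values) == pytest.approx(1.5, abs=0.05)

    def test_unimodal_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="bimodal"):
            estimate_expression_cutoff(rng.normal(2.0, 0.2, 2000))

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError, match="100"):
            estimate_expression_cutoff(np.ones(50))


def tiny_expression(rows: dict[str, list[float]]) -> TimeCourseMatrix:
    ids = sorted(rows)
    return TimeCourseMatrix(ids, np.arange(4.0), np.array([rows[i] for i in ids]))


class TestPartition:
    expr = {
        "g_rhy": [2.0, 2.5, 2.0, 1.8],      # circadian + expressed
        "g_gen": [2.0, 2.0, 2.0, 2.0],      # on general list, expressed
        "g_gen_off": [1.0, 1.1, 1.0, 1.0],  # on general list, silent
        "g_ctrl": [2.2, 2.1, 2.0, 2.0],     # off-list, expressed
        "g_off": [1.0, 1.2, 1.0, 1.0],      # off-list, silent
        "g_amb": [2.0, 2.0, 2.1, 2.0],      # filter-excluded, expressed
    }

    def partition(self) -> GeneSetPartition:
        return partition_gene_sets(
            circadian={"g_rhy"},
            expression=tiny_expression(self.expr),
            general_circadian_list={"g_rhy", "g_gen", "g_gen_off"},
            cutoff=1.45,
            ambiguous={"g_amb"},
        )

    def test_labels(self):
        p = self.partition()
        assert p.labels == {
            "g_rhy": "LCG",
            "g_gen": "LNLCG",
            "g_gen_off": "NLCG-unexpressed",
            "g_ctrl": "LNCG",
            "g_off": "unexpressed",
            "g_amb": "AL-only",
        }

    def test_partition_exhaustive_and_disjoint(self):
        p = self.partition()
        assert set(p.labels) == set(self.expr)
        assert p.al == {"g_rhy", "g_gen", "g_ctrl", "g_amb"}
        assert p.lncg == {"g_ctrl"}

    def test_missing_locus_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            partition_gene_sets({"nope"}, tiny_expression(self.expr), set(), 1.45)


class TestFalsePositiveRate:
    def test_printed_rates(self):
        controls_111 = [f"c{i}" for i in range(111)]
        assert estimate_false_positive_rate({"c0"}, controls_111) == 0.9
        controls_104 = [f"c{i}" for i in range(104)]
        assert estimate_false_positive_rate({"c0", "c1"}, controls_104) == 1.9

    def test_zero_hits(self):
        assert estimate_false_positive_rate({"x"}, ["a", "b"]) == 0.0

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            estimate_false_positive_rate({"x"}, [])
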