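"""Grouping, AS-class assignment, signed distances and gene regions."""

import numpy as np
import pytest

from yeastsplice import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    classify_event,
    classify_predicted,
    group_overlapping,
    locate_in_gene,
    match_annotated,
)
from yeastsplice.as_classification import (
    CLASS_ALT3,
    CLASS_ALT5,
    CLASS_ANNOTATED,
    CLASS_BOTH,
    CLASS_SINGLE,
)
from .conftest import make_predicted


def _gene(gene_id, chrom, start, end, strand, introns=()):
    return GeneModel(
        gene_id=gene_id,
        span=GenomicInterval(chrom, start, end, strand),
        cds_segments=[GenomicInterval(chrom, start, end, strand)],
        annotated_introns=[
            GenomicInterval(chrom, s, e, strand) for s, e in introns
        ],
    )


class TestMatchAnnotated:
    @pytest.fixture
    def annotation(self):
        gene = GeneModel(
            gene_id="G1",
            span=GenomicInterval("chrI", 1, 400, "+"),
            cds_segments=[GenomicInterval("chrI", 1, 400, "+")],
            annotated_introns=[GenomicInterval("chrI", 101, 200, "+")],
        )
        return AnnotationSet([gene])

    def test_exact_and_overlapping(self, annotation):
        assert match_annotated(make_predicted(start=101, end=200), annotation) == "exact-annotated"
        assert match_annotated(make_predicted(start=101, end=204), annotation) == "novel"
        assert match_annotated(make_predicted(chrom="chrII"), annotation) == "novel"


class TestGrouping:
    def test_overlapping_form_one_group_reference_by_support(self):
        a = make_predicted(start=100, end=200, support=50)
        b = make_predicted(start=100, end=230, support=5)
        (group,) = group_overlapping([a, b])
        assert group.reference is a
        assert len(group.members) == 2

    def test_disjoint_are_singletons(self):
        a = make_predicted(start=100, end=200)
        b = make_predicted(start=300, end=400)
        assert len(group_overlapping([a, b])) == 2

    def test_bookended_not_grouped(self):
        a = make_predicted(start=100, end=200)
        b = make_predicted(start=201, end=300)
        assert len(group_overlapping([a, b])) == 2

    def test_different_strand_not_grouped(self):
        a = make_predicted(start=100, end=200, strand="+")
        b = make_predicted(start=150, end=250, strand="-")
        assert len(group_overlapping([a, b])) == 2

    def test_tie_breaks_shorter_then_leftmost(self):
        short = make_predicted(start=120, end=200, support=5)
        long = make_predicted(start=100, end=230, support=5)
        (group,) = group_overlapping([short, long])
        assert group.reference is short
        left = make_predicted(start=100, end=200, support=5)
        right = make_predicted(start=120, end=220, support=5)
        (group,) = group_overlapping([left, right])
        assert group.reference is left

    def test_transitive_closure(self):
        a = make_predicted(start=100, end=200)
        b = make_predicted(start=190, end=300)
        c = make_predicted(start=290, end=400)
        (group,) = group_overlapping([a, b, c])  # a-c linked through b
        assert len(group.members) == 3


class TestClassifyEvent:
    def test_mtr2_minus_strand_alt3(self):
        """YKL186C (MTR2), minus strand: the annotated intron 93312-93465
        gains an alternative acceptor 9 bases further (published +9) and one
        55 bases nearer (published distance 55)."""
        reference = make_predicted(chrom="XI", start=93312, end=93465, strand="-", support=100)
        extended = make_predicted(chrom="XI", start=93303, end=93465, strand="-", support=24)
        shortened = make_predicted(chrom="XI", start=93367, end=93465, strand="-", support=55)
        cls, (dist,) = classify_event(extended, reference, "-")
        assert cls == CLASS_ALT3 and dist.side == "3'" and dist.distance == 9
        cls, (dist,) = classify_event(shortened, reference, "-")
        assert cls == CLASS_ALT3 and dist.distance == -55

    def test_bmh2_nagnag_plus_three(self):
        """YDR099W (BMH2): NAGNAG acceptor 3 bases past the canonical site."""
        reference = make_predicted(chrom="IV", start=652781, end=653523, strand="+", support=500)
        member = make_predicted(chrom="IV", start=652781, end=653526, strand="+", support=81)
        cls, (dist,) = classify_event(member, reference, "+")
        assert cls == CLASS_ALT3 and dist.distance == 3

    def test_both_ends_differ(self):
        reference = make_predicted(start=100, end=200, support=50)
        member = make_predicted(start=94, end=203, support=5)
        cls, distances = classify_event(member, reference, "+")
        assert cls == CLASS_BOTH
        assert {(d.side, d.distance) for d in distances} == {("5'", 6), ("3'", 3)}

    def test_non_overlapping_raises(self):
        with pytest.raises(ValueError):
            classify_event(
                make_predicted(start=300, end=400),
                make_predicted(start=100, end=200),
                "+",
            )

    def test_strand_mirror_flips_alt3_alt5(self):
        """Mirroring coordinates and strand exchanges donor- and
        acceptor-side variation but keeps the signed distance."""
        rng = np.random.default_rng(17)
        L = 10_000
        for _ in range(25):
            s = int(rng.integers(1000, 5000))
            e = s + int(rng.integers(50, 400))
            delta = int(rng.integers(1, 30))
            ref_plus = make_predicted(start=s, end=e, support=50)
            mem_plus = make_predicted(start=s, end=e + delta, support=5)
            cls_plus, (d_plus,) = classify_event(mem_plus, ref_plus, "+")
            # mirror: position p -> L - p + 1, strand flips
            ref_minus = make_predicted(
                start=L - e + 1, end=L - s + 1, strand="-", support=50
            )
            mem_minus = make_predicted(
                start=L - (e + delta) + 1, end=L - s + 1, strand="-", support=5
            )
            cls_minus, (d_minus,) = classify_event(mem_minus, ref_minus, "-")
            assert cls_plus == cls_minus == CLASS_ALT3
            assert d_plus.distance == d_minus.distance == delta


class TestLocateInGene:
    @pytest.fixture
    def annotation(self):
        # plus-strand gene with CDS 501-1400 (stop codon 1398-1400)
        g1 = _gene("G1", "chrI", 501, 1400, "+")
        g1.transcript_span = GenomicInterval("chrI", 301, 1400, "+")
        g2 = _gene("G2", "chrI", 2001, 2600, "+")
        return AnnotationSet([g1, g2])

    def test_terminal_contains_stop_codon(self, annotation):
        call = locate_in_gene(GenomicInterval("chrI", 1380, 1450), annotation)
        assert (call.region, call.gene_id) == ("terminal", "G1")

    def test_cds(self, annotation):
        call = locate_in_gene(GenomicInterval("chrI", 600, 700), annotation)
        assert (call.region, call.gene_id) == ("CDS", "G1")

    def test_utr5_window(self, annotation):
        call = locate_in_gene(GenomicInterval("chrI", 350, 450), annotation)
        assert (call.region, call.gene_id) == ("5'UTR", "G1")

    def test_intergenic(self, annotation):
        call = locate_in_gene(GenomicInterval("chrI", 1600, 1700), annotation)
        assert call.region == "intergenic"

    def test_straddles_two_genes_is_multiple(self, annotation):
        # covers the tail of G1 (without the whole stop codon) and G2's head
        call = locate_in_gene(GenomicInterval("chrI", 1399, 2100), annotation)
        assert call.region == "multiple"


class TestClassifyPredictedOnSimulation:
    def test_classes_distances_and_regions_match_truth(self, sim, sim_predicted):
        classified = classify_predicted(
            sim_predicted.predicted, sim.annotation, sim.genome
        )
        assert len(classified) == len(sim_predicted.predicted)
        for item in classified:
            planted = sim.truth.junctions[item.intron.interval.key]
            assert item.as_class == planted.expected_class
            d3 = next((d.distance for d in item.distances if d.side == "3'"), None)
            d5 = next((d.distance for d in item.distances if d.side == "5'"), None)
            assert d3 == planted.distance_3p
            assert d5 == planted.distance_5p
            assert item.region.region == planted.region

    def test_classes_partition(self, sim, sim_predicted):
        """Each predicted intron gets exactly one class; singletons are never
        alternative-site classes."""
        classified = classify_predicted(
            sim_predicted.predicted, sim.annotation, sim.genome
        )
        groups = group_overlapping(sim_predicted.predicted)
        singleton_keys = {
            g.members[0].interval.key for g in groups if len(g.members) == 1
        }
        for item in classified:
            if item.intron.interval.key in singleton_keys:
                assert item.as_class in (CLASS_SINGLE, CLASS_ANNOTATED)
            assert item.as_class in (
                CLASS_ANNOTATED,
                CLASS_SINGLE,
                "reference",
                CLASS_ALT3,
                CLASS_ALT5,
                CLASS_BOTH,
            )
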