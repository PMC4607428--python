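"""Frame effects, transcript splicing and ORI/VAR protein isoforms."""

import pytest

from yeastsplice import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    frame_effect,
    protein_delta,
    splice_transcript,
    translate_isoform,
)
from yeastsplice.datasets import novel_cds_introns


class TestFrameEffect:
    @pytest.mark.parametrize(
        "basis, region, expected",
        [
            (126, "CDS", "preserving"),  # TDH3 novel intron
            (98, "CDS", "disruptive"),  # RPL30 novel intron
            (205, "5'UTR", "not-applicable"),  # frame irrelevant upstream
            (-18, "CDS", "preserving"),  # signed alt-site distance
            (47, "CDS", "disruptive"),
        ],
    )
    def test_mod3_rule(self, basis, region, expected):
        assert frame_effect(basis, region).value == expected

    def test_pooled_novel_introns_split_eight_four(self):
        """The 12 published protein-coding novel introns split 8 preserving /
        4 disruptive under the mod-3 rule."""
        effects = [
            frame_effect(int(row.length), "CDS").value
            for row in novel_cds_introns().itertuples(index=False)
        ]
        assert effects.count("preserving") == 8
        assert effects.count("disruptive") == 4


# a 21-base CDS containing a 9-base in-frame intron (GTATTTCAG)
_MINI_CHROM = "CC" + "ATGAAA" + "GTATTTCAG" + "TTTGGG" + "TAA" + "TT"


def _mini_gene(strand="+"):
    if strand == "+":
        span = GenomicInterval("c", 3, 26, "+")
        return GeneModel(
            gene_id="MINI",
            span=span,
            cds_segments=[span],
            annotated_introns=[],
        ), GenomeSequence({"c": _MINI_CHROM})
    from yeastsplice import reverse_complement

    seq = reverse_complement(_MINI_CHROM)
    n = len(seq)
    span = GenomicInterval("c", n - 26 + 1, n - 3 + 1, "-")
    return GeneModel(
        gene_id="MINI",
        span=span,
        cds_segments=[span],
        annotated_introns=[],
    ), GenomeSequence({"c": seq})


class TestSpliceTranscript:
    def test_identity_without_introns(self):
        gene, genome = _mini_gene()
        assert splice_transcript(gene, genome) == _MINI_CHROM[2:26]

    def test_internal_intron_removed(self):
        genome = GenomeSequence({"c": "ACGTACGTACGT"})
        product = splice_transcript(GenomicInterval("c", 1, 12, "+"), genome, [GenomicInterval("c", 4, 6)])
        assert product == "ACG" + "GTACGT"
        assert len(product) == 9

    def test_minus_strand_is_reverse_complement(self):
        from yeastsplice import reverse_complement

        genome = GenomeSequence({"c": "ACGTACGTACGT"})
        plus = splice_transcript(GenomicInterval("c", 1, 12, "+"), genome, [GenomicInterval("c", 4, 6)])
        minus = splice_transcript(GenomicInterval("c", 1, 12, "-"), genome, [GenomicInterval("c", 4, 6)])
        assert minus == reverse_complement(plus)

    def test_overlapping_introns_raise(self):
        genome = GenomeSequence({"c": "ACGTACGTACGT"})
        with pytest.raises(ValueError):
            splice_transcript(
                GenomicInterval("c", 1, 12, "+"),
                genome,
                [GenomicInterval("c", 4, 6), GenomicInterval("c", 5, 8)],
            )

    def test_round_trip_reinsertion(self):
        """Splicing an intron out and re-inserting its sequence reproduces
        the original transcript."""
        genome = GenomeSequence({"c": "ACGTACGTACGTACGT"})
        span = GenomicInterval("c", 1, 16, "+")
        intron = GenomicInterval("c", 5, 9)
        spliced = splice_transcript(span, genome, [intron])
        reinserted = (
            spliced[: intron.start - span.start]
            + genome.subsequence(intron)
            + spliced[intron.start - span.start :]
        )
        assert reinserted == splice_transcript(span, genome, [])


class TestTranslateIsoform:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_inframe_intron_removes_three_residues(self, strand):
        gene, genome = _mini_gene(strand)
        if strand == "+":
            intron = GenomicInterval("c", 9, 17, "+")
        else:
            n = len(genome["c"])
            intron = GenomicInterval("c", n - 17 + 1, n - 9 + 1, "-")
        cons = translate_isoform(gene, genome, intron)
        assert cons.protein_ori == "MKVFQFG*"
        assert cons.protein_var == "MKFG*"
        assert cons.length_delta == -9
        assert not cons.premature_stop
        assert protein_delta(cons.protein_ori, cons.protein_var) == (3, 0)

    def test_missing_start_codon_raises(self):
        genome = GenomeSequence({"c": "CCTTGAAATAGCC"})
        span = GenomicInterval("c", 3, 11, "+")
        gene = GeneModel("BAD", span, [span], [])
        with pytest.raises(ValueError, match="start codon"):
            translate_isoform(gene, genome, GenomicInterval("c", 5, 7))

    def test_simulation_truth_proteins(self, sim):
        """Pipeline ORI/VAR translation reproduces the independently composed
        proteins for every planted event, including fusion partners."""
        checked = 0
        for planted_gene in sim.truth.genes:
            if planted_gene.kind == "partner":
                continue
            gene = sim.annotation.gene(planted_gene.gene_id)
            for planted in planted_gene.planted:
                if planted.kind == "annotated":
                    continue
                cons = translate_isoform(
                    gene,
                    sim.genome,
                    planted.interval.with_strand(planted_gene.strand),
                    sim.annotation,
                )
                assert cons.protein_ori == planted_gene.protein_ori
                assert cons.protein_var == planted_gene.protein_var
                assert cons.fusion_partner == planted_gene.fusion_partner
                checked += 1
        assert checked >= 10

    def test_frameshift_novel_introns_truncate(self, sim):
        """Frame-disrupting novel CDS introns typically terminate early."""
        seen = 0
        for planted_gene in sim.truth.genes:
            if planted_gene.kind != "novel_cds_frameshift":
                continue
            gene = sim.annotation.gene(planted_gene.gene_id)
            planted = planted_gene.planted[0]
            cons = translate_isoform(
                gene, sim.genome, planted.interval.with_strand(planted_gene.strand)
            )
            assert cons.protein_var != cons.protein_ori
            assert cons.stop_found_var
            seen += 1
        assert seen >= 1


class TestProteinDelta:
    @pytest.mark.parametrize(
        "ori, var, expected",
        [
            ("MKYVL*", "MKTFC*", (3, 3)),
            ("MKYVL*", "MKYVL*", (0, 0)),
            ("MKAV*", "MKAAV*", (0, 1)),  # NAGNAG-style single-codon insertion
            ("MKAAV*", "MKAV*", (1, 0)),
        ],
    )
    def test_prefix_suffix_decomposition(self, ori, var, expected):
        assert protein_delta(ori, var) == expected
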