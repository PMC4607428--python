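"""Splice signals, junction slack/quality and the filter cascade."""

import numpy as np
import pytest

from yeastsplice import (
    FilterConfig,
    GenomeSequence,
    GenomicInterval,
    PotentialIntron,
    filter_potential_introns,
    intron_length,
    junction_quality,
    junction_shift_slack,
    splice_signal,
    valid_signal_set,
)

GT_AG = frozenset({("GT", "AG")})


def brute_force_slack(seq: str, start: int, end: int, max_shift: int = 10) -> int:
    """Independent oracle: re-splice the genome for every shift and count
    placements whose exon-flank concatenation matches the unshifted one."""
    ref = seq[: start - 1] + seq[end:]
    count = 0
    for j in range(-max_shift, max_shift + 1):
        if j == 0:
            continue
        s, e = start + j, end + j
        if s < 1 or e > len(seq):
            continue
        if seq[: s - 1] + seq[e:] == ref:
            count += 1
    return count


def make_pi(interval, support=10, anchors=(95, 60)):
    return PotentialIntron(
        interval=interval,
        read_support=support,
        fragment_support=support,
        supporting_read_ids=tuple(f"r{i}" for i in range(support)),
        anchor_left=anchors[0],
        anchor_right=anchors[1],
    )


@pytest.mark.parametrize(
    "start, end, expected",
    [
        (883015, 883140, 126),  # TDH3 novel intron
        (443706, 443833, 128),  # FES1 terminal intron
        (5, 5, 1),
    ],
)
def test_intron_length(start, end, expected):
    assert intron_length(GenomicInterval("c", start, end)) == expected


class TestSpliceSignal:
    @pytest.mark.parametrize(
        "seq, expected_strand, donor, acceptor",
        [
            ("CCGTAAAGCC", "+", "GT", "AG"),
            ("CCCTAAACCC", "-", "GT", "AG"),  # reverse complement orientation
            ("CCAAAAAACC", ".", "AA", "AA"),
        ],
    )
    def test_orientations(self, seq, expected_strand, donor, acceptor):
        genome = GenomeSequence({"c": seq})
        signal = splice_signal(genome, GenomicInterval("c", 3, 8), GT_AG)
        assert signal.inferred_strand == expected_strand
        assert (signal.donor, signal.acceptor) == (donor, acceptor)

    def test_too_short_raises(self):
        genome = GenomeSequence({"c": "ACGTACGT"})
        with pytest.raises(ValueError):
            splice_signal(genome, GenomicInterval("c", 3, 5), GT_AG)

    def test_strand_mirror_property(self):
        """The signal of an interval on the reverse-complemented genome is
        the strand mirror of the original."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            from yeastsplice import reverse_complement

            n = len(seq)
            start, end = 11, 40
            fwd = splice_signal(GenomeSequence({"c": seq}), GenomicInterval("c", start, end), GT_AG)
            mirrored = splice_signal(
                GenomeSequence({"c": reverse_complement(seq)}),
                GenomicInterval("c", n - end + 1, n - start + 1),
                GT_AG,
            )
            flip = {"+": "-", "-": "+", ".": "."}
            assert mirrored.inferred_strand == flip[fwd.inferred_strand]


class TestValidSignalSet:
    def test_extracted_from_annotation(self, sim):
        signals = valid_signal_set(sim.annotation, sim.genome)
        assert signals == GT_AG  # the generator plants canonical signals only

    def test_empty_intron_set_raises(self):
        from yeastsplice import AnnotationSet

        with pytest.raises(ValueError):
            valid_signal_set(AnnotationSet([]), GenomeSequence({"c": "ACGT"}))


class TestSlack:
    def test_unique_flanks_give_zero(self):
        genome = GenomeSequence({"c": "CCGTAAAGCC"})
        assert junction_shift_slack(genome, GenomicInterval("c", 3, 8)) == 0

    def test_homopolymer(self):
        genome = GenomeSequence({"c": "AAAAAAAAAA"})
        assert junction_shift_slack(genome, GenomicInterval("c", 4, 7), 2) == 4

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for i in range(300):
            n = int(rng.integers(60, 160))
            alphabet = 4 if rng.random() < 0.7 else 2  # low-complexity repeats
            seq = "".join("ACGT"[k] for k in rng.integers(0, alphabet, n))
            start = int(rng.integers(15, n - 40))
            end = int(rng.integers(start + 5, n - 12))
            genome = GenomeSequence({"c": seq})
            got = junction_shift_slack(genome, GenomicInterval("c", start, end))
            assert got == brute_force_slack(seq, start, end), (seq, start, end)

    def test_window_truncated_at_chromosome_bounds(self):
        genome = GenomeSequence({"c": "AAAA"})
        # does not raise; counts only in-bounds placements
        assert junction_shift_slack(genome, GenomicInterval("c", 2, 3), 10) == 2


class TestJunctionQuality:
    def test_scores_are_anchor_minus_slack(self):
        genome = GenomeSequence({"c": "CCGTAAAGCC"})  # unambiguous junction
        pi = make_pi(GenomicInterval("c", 3, 8), anchors=(90, 40))
        q = junction_quality(pi, genome)
        assert q.slack_n == 0
        assert (q.score_left, q.score_right) == (90, 40)

    def test_scores_with_slippery_junction(self):
        genome = GenomeSequence({"c": "CAGGTAAGGTCC"})
        iv = GenomicInterval("c", 4, 8)
        slack = junction_shift_slack(genome, iv)
        q = junction_quality(pi := make_pi(iv, anchors=(90, 40)), genome)
        assert q.slack_n == slack > 0
        assert (q.score_left, q.score_right) == (90 - slack, 40 - slack)

    def test_negative_scores_allowed(self):
        genome = GenomeSequence({"c": "A" * 40})
        pi = make_pi(GenomicInterval("c", 15, 25), anchors=(10, 5))
        q = junction_quality(pi, genome)
        assert q.score_left < 0 and q.score_right < 0


def _cascade_genome_and_introns():
    """One potential intron per failure stage plus one clean survivor."""
    rng = np.random.default_rng(5)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 4000)))

    def plant(start, end, donor="GT", acceptor="AG"):
        seq[start - 1 : start + 1] = list(donor)
        seq[end - 2 : end] = list(acceptor)
        # unique flanking bases: no alternative placements
        if seq[start - 2] == acceptor[1]:
            seq[start - 2] = "C"
        if seq[end] == donor[0]:
            seq[end] = "C"

    plant(100, 2099)  # long (2000 bases)
    plant(2200, 2209)  # short (10 bases)
    # 2300-2399: no signal planted, force non-matching ends
    seq[2299:2301] = list("AA")
    seq[2397:2399] = list("AA")
    plant(2500, 2599)  # valid but support 1
    plant(2700, 2799)  # survivor
    genome = GenomeSequence({"c": "".join(seq)})
    pis = [
        make_pi(GenomicInterval("c", 100, 2099), support=50),
        make_pi(GenomicInterval("c", 2200, 2209), support=50),
        make_pi(GenomicInterval("c", 2300, 2399), support=50),
        make_pi(GenomicInterval("c", 2500, 2599), support=1),
        make_pi(GenomicInterval("c", 2700, 2799), support=50, anchors=(95, 60)),
    ]
    return genome, pis


class TestFilterCascade:
    def test_each_stage_exercised_once(self):
        genome, pis = _cascade_genome_and_introns()
        predicted, tally = filter_potential_introns(pis, genome, FilterConfig())
        assert tally.introns == {
            "long": 1,
            "short": 1,
            "signal": 1,
            "support": 1,
            "quality": 0,
            "pass": 1,
        }
        assert len(predicted) == 1
        assert predicted[0].interval.key == ("c", 2700, 2799)
        assert predicted[0].strand == "+"

    def test_tally_conservation(self):
        genome, pis = _cascade_genome_and_introns()
        _, tally = filter_potential_introns(pis, genome, FilterConfig())
        assert tally.total_introns == len(pis)
        assert tally.total_reads == sum(p.read_support for p in pis)

    def test_empty_input(self):
        genome = GenomeSequence({"c": "ACGT" * 100})
        predicted, tally = filter_potential_introns([], genome, FilterConfig())
        assert predicted == [] and tally.total_introns == 0

    def test_thresholds_are_strict(self):
        """Scores exactly (85, 25) fail; (86, 26) pass ("must exceed")."""
        rng = np.random.default_rng(9)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 400)))
        seq[99:101] = list("GT")
        seq[198:200] = list("AG")
        if seq[98] == "G":
            seq[98] = "C"
        if seq[200] == "G":
            seq[200] = "C"
        genome = GenomeSequence({"c": "".join(seq)})
        exact = make_pi(GenomicInterval("c", 100, 200), support=10, anchors=(85, 25))
        above = make_pi(GenomicInterval("c", 100, 200), support=10, anchors=(86, 26))
        predicted, tally = filter_potential_introns([exact, above], genome)
        assert tally.introns["quality"] == 1 and tally.introns["pass"] == 1
        assert predicted[0].anchor_left == 86

    def test_monotone_under_support_tightening(self):
        genome, pis = _cascade_genome_and_introns()
        sizes = []
        for threshold in (1, 3, 10, 60):
            predicted, _ = filter_potential_introns(
                pis, genome, FilterConfig(min_read_support=threshold)
            )
            sizes.append(len(predicted))
        assert sizes == sorted(sizes, reverse=True)

    def test_predicted_subset_of_potential(self, sim_predicted):
        potential_keys = {p.interval.key for p in sim_predicted.potential}
        assert all(
            p.interval.key in potential_keys for p in sim_predicted.predicted
        )
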