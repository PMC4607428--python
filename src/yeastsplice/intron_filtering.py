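"""Filter cascade turning potential introns into predicted introns.

Stages, applied in order with each candidate removed at the first failing
stage:

1. ``long``    — longer than ``max_length`` (default 1002 bases).
2. ``short``   — shorter than ``min_length`` (default 40 bases).
3. ``signal``  — neither orientation of the terminal dinucleotides matches a
   valid donor/acceptor pair (canonically GT...AG); the matching orientation
   also infers the intron's strand.
4. ``support`` — fewer supporting split reads than ``min_read_support``
   (default 3).
5. ``quality`` — junction quality, per side ``anchor - n`` where *n* counts
   alternative genomic placements of the junction yielding an identical
   spliced sequence (repeat-induced slack).  The larger score must exceed
   ``quality_max_threshold`` (85) and the smaller must exceed
   ``quality_min_threshold`` (25); both inequalities are strict.

Survivors are predicted introns carrying their inferred strand, splice
signal and quality scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_models import GenomeSequence, GenomicInterval, reverse_complement
from .splitread_extraction import PotentialIntron

FILTER_STAGES = ("long", "short", "signal", "support", "quality")

#: Default window (bases, each direction) searched for equivalent junction
#: placements when computing slack.
DEFAULT_MAX_SHIFT = 10


@dataclass(frozen=True)
class SpliceSignal:
    """Terminal dinucleotides of an intron on the transcribed strand.

    ``inferred_strand`` is "+" or "-" for the orientation whose (donor,
    acceptor) pair is in the valid set, "." if neither matches ("+" is
    preferred when both orientations match).
    """

    donor: str
    acceptor: str
    inferred_strand: str


@dataclass(frozen=True)
class JunctionQuality:
    slack_n: int
    score_left: int
    score_right: int

    def __post_init__(self) -> None:
        if self.slack_n < 0:
            raise ValueError("slack must be non-negative")

    @property
    def max_score(self) -> int:
        return max(self.score_left, self.score_right)

    @property
    def min_score(self) -> int:
        return min(self.score_left, self.score_right)


@dataclass(frozen=True)
class FilterConfig:
    max_length: int = 1002
    min_length: int = 40
    min_read_support: int = 3
    quality_max_threshold: int = 85
    quality_min_threshold: int = 25
    valid_signals: frozenset[tuple[str, str]] = frozenset({("GT", "AG")})
    max_shift: int = DEFAULT_MAX_SHIFT

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if min(self.min_read_support, self.quality_max_threshold, 0) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterTally:
    """Per-stage removal counts for introns and their supporting reads."""

    introns: dict[str, int] = field(default_factory=dict)
    reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in (*FILTER_STAGES, "pass"):
            self.introns.setdefault(key, 0)
            self.reads.setdefault(key, 0)

    @property
    def total_introns(self) -> int:
        return sum(self.introns.values())

    @property
    def total_reads(self) -> int:
        return sum(self.reads.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": key, "introns": self.introns[key], "reads": self.reads[key]}
            for key in (*FILTER_STAGES, "pass")
        ]
        return pd.DataFrame(rows)


@dataclass
class PredictedIntron:
    """A potential intron that passed (or is being scored by) the cascade."""

    interval: GenomicInterval  # carries the inferred strand
    read_support: int
    fragment_support: int
    anchor_left: int
    anchor_right: int
    donor: str
    acceptor: str
    slack: int
    score_left: int
    score_right: int

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand


def intron_length(interval: GenomicInterval) -> int:
    """Intron length under 1-based inclusive coordinates: end - start + 1."""
    return interval.end - interval.start + 1


def valid_signal_set(annotation, genome: GenomeSequence) -> frozenset[tuple[str, str]]:
    """Distinct (donor, acceptor) dinucleotide pairs at annotated introns.

    Read on the transcribed strand, over nuclear, non-tRNA/snoRNA introns.
    """
    signals = set()
    for gene, intron in annotation.all_introns():
        if intron.length < 4:
            continue
        seq = genome.subsequence(intron.with_strand(gene.strand))
        signals.add((seq[:2], seq[-2:]))
    if not signals:
        raise ValueError("annotation contains no usable annotated introns")
    return frozenset(signals)


def splice_signal(
    genome: GenomeSequence,
    interval: GenomicInterval,
    valid_signals: Iterable[tuple[str, str]] = (("GT", "AG"),),
) -> SpliceSignal:
    """Evaluate the terminal dinucleotides of ``interval`` in both orientations.

    Forward reads the first and last two genomic bases; the reverse
    orientation reads their reverse complements (acceptor and donor swap
    ends).  The orientation whose pair is valid determines the inferred
    strand, "+" winning ties.
    """
    if interval.length < 4:
        raise ValueError("interval too short for a splice signal (length < 4)")
    valid = set(valid_signals)
    seq_fwd = genome.subsequence(interval.with_strand("+"))
    pair_fwd = (seq_fwd[:2], seq_fwd[-2:])
    pair_rev = (reverse_complement(seq_fwd[-2:]), reverse_complement(seq_fwd[:2]))
    if pair_fwd in valid:
        return SpliceSignal(pair_fwd[0], pair_fwd[1], "+")
    if pair_rev in valid:
        return SpliceSignal(pair_rev[0], pair_rev[1], "-")
    return SpliceSignal(pair_fwd[0], pair_fwd[1], ".")


def junction_shift_slack(
    genome: GenomeSequence,
    interval: GenomicInterval,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> int:
    """Number of shifted junction placements with an identical spliced product.

    A shift of +j (resp. -j) moves the whole intron j bases downstream
    (upstream); the spliced exon-flank concatenation is unchanged iff the j
    bases entering the intron equal the j bases leaving it.  Validity is
    therefore nested: shift +j requires +1..+(j-1) to be valid as well.  The
    search window is truncated at the chromosome ends.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    seq = genome[interval.chrom]
    n = len(seq)
    start, end = interval.start, interval.end

    def base(pos: int) -> str:
        return seq[pos - 1]

    slack = 0
    for j in range(1, max_shift + 1):  # rightward shifts
        if end + j > n or base(start + j - 1) != base(end + j):
            break
        slack += 1
    for j in range(1, max_shift + 1):  # leftward shifts
        if start - j < 1 or base(start - j) != base(end - j + 1):
            break
        slack += 1
    return slack


def junction_quality(
    potential_intron: PotentialIntron,
    genome: GenomeSequence,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> JunctionQuality:
    """Per-side junction quality: anchor length minus placement slack n."""
    n = junction_shift_slack(genome, potential_intron.interval, max_shift)
    return JunctionQuality(
        slack_n=n,
        score_left=potential_intron.anchor_left - n,
        score_right=potential_intron.anchor_right - n,
    )


def _evaluate(
    pi: PotentialIntron, genome: GenomeSequence, config: FilterConfig
) -> tuple[str, PredictedIntron | None]:
    """Return (failing stage or "pass", scored predicted intron if reached)."""
    length = intron_length(pi.interval)
    if length > config.max_length:
        return "long", None
    if length < config.min_length:
        return "short", None
    signal = splice_signal(genome, pi.interval, config.valid_signals)
    if signal.inferred_strand == ".":
        return "signal", None
    quality = junction_quality(pi, genome, config.max_shift)
    predicted = PredictedIntron(
        interval=pi.interval.with_strand(signal.inferred_strand),
        read_support=pi.read_support,
        fragment_support=pi.fragment_support,
        anchor_left=pi.anchor_left,
        anchor_right=pi.anchor_right,
        donor=signal.donor,
        acceptor=signal.acceptor,
        slack=quality.slack_n,
        score_left=quality.score_left,
        score_right=quality.score_right,
    )
    if pi.read_support < config.min_read_support:
        return "support", predicted
    passes = (
        quality.max_score > config.quality_max_threshold
        and quality.min_score > config.quality_min_threshold
    )
    return ("pass" if passes else "quality"), predicted


def filter_potential_introns(
    potential_introns: Iterable[PotentialIntron],
    genome: GenomeSequence,
    config: FilterConfig | None = None,
) -> tuple[list[PredictedIntron], FilterTally]:
    """Apply the full cascade; returns survivors and the per-stage tally."""
    config = config or FilterConfig()
    tally = FilterTally()
    predicted: list[PredictedIntron] = []
    for pi in potential_introns:
        stage, scored = _evaluate(pi, genome, config)
        tally.introns[stage] += 1
        tally.reads[stage] += pi.read_support
        if stage == "pass" and scored is not None:
            predicted.append(scored)
    return predicted, tally


def filter_stages(
    potential_introns: Iterable[PotentialIntron],
    genome: GenomeSequence,
    config: FilterConfig | None = None,
) -> list[tuple[PotentialIntron, str, PredictedIntron | None]]:
    """Per-candidate failing stage (or "pass") with scores where available.

    Used by reporting to build the support tiers without re-running the
    cascade from scratch per tier.
    """
    config = config or FilterConfig()
    return [(pi, *_evaluate(pi, genome, config)) for pi in potential_introns]


def predicted_to_frame(predicted: Sequence[PredictedIntron]) -> pd.DataFrame:
    """Predicted introns as a tidy table (1-based inclusive coordinates)."""
    rows = []
    for p in predicted:
        rows.append(
            {
                "chrom": p.interval.chrom,
                "strand": p.strand,
                "start": p.interval.start,
                "end": p.interval.end,
                "length": p.length,
                "read_support": p.read_support,
                "fragment_support": p.fragment_support,
                "donor": p.donor,
                "acceptor": p.acceptor,
                "anchor_left": p.anchor_left,
                "anchor_right": p.anchor_right,
                "slack": p.slack,
                "score_left": p.score_left,
                "score_right": p.score_right,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "strand",
            "start",
            "end",
            "length",
            "read_support",
            "fragment_support",
            "donor",
            "acceptor",
            "anchor_left",
            "anchor_right",
            "slack",
            "score_left",
            "score_right",
        ],
    )


def frame_to_predicted(frame: pd.DataFrame) -> list[PredictedIntron]:
    """Inverse of :func:`predicted_to_frame` (for TSV round-trips)."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            PredictedIntron(
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                read_support=int(row.read_support),
                fragment_support=int(row.fragment_support),
                anchor_left=int(row.anchor_left),
                anchor_right=int(row.anchor_right),
                donor=str(row.donor),
                acceptor=str(row.acceptor),
                slack=int(row.slack),
                score_left=int(row.score_left),
                score_right=int(row.score_right),
            )
        )
    return out
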