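"""Split-read extraction and potential-intron calling from SAM/BAM.

A split read is an alignment whose CIGAR contains at least one skipped-region
(``N``) operation; each ``N`` gap is a junction spanning a potential intron.
Only uniquely mapped primary alignments are used.  Ungapped reads covering an
exon-intron boundary provide evidence of the unspliced (intron-retaining)
transcript.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .io_models import GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)

# CIGAR op codes (BAM spec)
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)
_REF_CONSUMING_IN_BLOCK = {_OP_M, _OP_D, _OP_EQ, _OP_X}

#: Minimum aligned bases required on both flanks of an exon-intron boundary
#: for an ungapped read to count as retention evidence on the intron side.
DEFAULT_MIN_OVERHANG = 8


@dataclass(frozen=True)
class SplitReadAlignment:
    """A uniquely mapped alignment with >= 1 junction."""

    read_id: str
    chrom: str
    blocks: tuple[GenomicInterval, ...]
    junctions: tuple[GenomicInterval, ...]
    unique: bool = True

    @property
    def fragment_key(self) -> tuple:
        """Reads with identical chromosome and block layout are one fragment."""
        return (self.chrom, tuple((b.start, b.end) for b in self.blocks))

    def anchors(self, junction_index: int) -> tuple[int, int]:
        """(left, right) contiguous aligned bases flanking the junction."""
        return (
            self.blocks[junction_index].length,
            self.blocks[junction_index + 1].length,
        )


@dataclass
class PotentialIntron:
    """A distinct junction with its read/fragment support and max anchors."""

    interval: GenomicInterval
    read_support: int
    fragment_support: int
    supporting_read_ids: tuple[str, ...]
    anchor_left: int
    anchor_right: int

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")
        if self.fragment_support > self.read_support:
            raise ValueError("fragment_support cannot exceed read_support")
        if min(self.anchor_left, self.anchor_right) < 1:
            raise ValueError("anchors must be >= 1")


@dataclass
class RetentionEvidence:
    """Ungapped-read counts over the two splice sites of an intron."""

    intron: GenomicInterval
    reads_spanning_5p: int
    reads_spanning_3p: int


def _blocks_and_junctions(
    chrom: str, reference_start0: int, cigartuples: list[tuple[int, int]]
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    pos = reference_start0  # 0-based next reference position
    blocks: list[GenomicInterval] = []
    junctions: list[GenomicInterval] = []
    block_start = pos + 1  # 1-based
    block_len = 0
    for op, length in cigartuples:
        if op in _REF_CONSUMING_IN_BLOCK:
            pos += length
            block_len += length
        elif op == _OP_N:
            if block_len > 0:
                blocks.append(GenomicInterval(chrom, block_start, pos))
            junctions.append(GenomicInterval(chrom, pos + 1, pos + length))
            pos += length
            block_start = pos + 1
            block_len = 0
        # I/S/H/P consume no reference
    if block_len > 0:
        blocks.append(GenomicInterval(chrom, block_start, pos))
    return blocks, junctions


def _is_unique_primary(read: pysam.AlignedSegment) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.has_tag("NH") and read.get_tag("NH") > 1:
        return False
    return True


def _open_alignments(source) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(source), check_sq=False)


def iter_split_reads(source: str | Path) -> Iterator[SplitReadAlignment]:
    """Yield uniquely-mapped split reads from a SAM/BAM file."""
    with _open_alignments(source) as af:
        for read in af:
            if not _is_unique_primary(read):
                continue
            cig = read.cigartuples
            if cig is None:
                logger.warning("skipping read %s with unparsable CIGAR", read.query_name)
                continue
            if not any(op == _OP_N for op, _ in cig):
                continue
            blocks, junctions = _blocks_and_junctions(
                read.reference_name, read.reference_start, cig
            )
            if len(blocks) != len(junctions) + 1:
                logger.warning(
                    "skipping read %s with degenerate block layout", read.query_name
                )
                continue
            yield SplitReadAlignment(
                read_id=read.query_name,
                chrom=read.reference_name,
                blocks=tuple(blocks),
                junctions=tuple(junctions),
            )


def extract_split_reads(source: str | Path) -> list[SplitReadAlignment]:
    """Materialized form of :func:`iter_split_reads`."""
    return list(iter_split_reads(source))


def call_potential_introns(
    split_reads: Iterable[SplitReadAlignment],
) -> list[PotentialIntron]:
    """Aggregate split reads into one :class:`PotentialIntron` per junction.

    Read support counts every supporting split read; fragment support counts
    reads with identical chromosome and block layout only once.  A read with
    k junctions contributes to k potential introns.  Anchors are maxima over
    the supporting reads.
    """
    read_ids: dict[tuple, list[str]] = defaultdict(list)
    fragments: dict[tuple, set] = defaultdict(set)
    anchors: dict[tuple, list[int]] = {}
    for read in split_reads:
        for idx, junction in enumerate(read.junctions):
            key = junction.key
            read_ids[key].append(read.read_id)
            fragments[key].add(read.fragment_key)
            left, right = read.anchors(idx)
            if key not in anchors:
                anchors[key] = [left, right]
            else:
                anchors[key][0] = max(anchors[key][0], left)
                anchors[key][1] = max(anchors[key][1], right)
    out = []
    for key in sorted(read_ids):
        chrom, start, end = key
        out.append(
            PotentialIntron(
                interval=GenomicInterval(chrom, start, end),
                read_support=len(read_ids[key]),
                fragment_support=len(fragments[key]),
                supporting_read_ids=tuple(read_ids[key]),
                anchor_left=anchors[key][0],
                anchor_right=anchors[key][1],
            )
        )
    return out


def _ungapped_spans(source: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Aligned spans (1-based inclusive) of unique primary junction-free reads."""
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with _open_alignments(source) as af:
        for read in af:
            if not _is_unique_primary(read):
                continue
            cig = read.cigartuples
            if cig is None or any(op == _OP_N for op, _ in cig):
                continue
            spans[read.reference_name].append(
                (read.reference_start + 1, read.reference_end)
            )
    return spans


def _count_covering(spans: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(1 for s, e in spans if s <= lo and e >= hi)


def retention_evidence_batch(
    source: str | Path,
    introns: Iterable[GenomicInterval],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    genome: GenomeSequence | None = None,
) -> list[RetentionEvidence]:
    """Retention evidence for many introns in one pass over the alignments.

    An ungapped read supports the 5' (donor-side) boundary if its aligned
    span covers positions ``start-1 .. start+min_overhang-1`` and the 3'
    boundary if it covers ``end-min_overhang+1 .. end+1``.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    introns = list(introns)
    if genome is not None:
        for intron in introns:
            if intron.chrom not in genome or intron.end > genome.length(intron.chrom):
                raise ValueError(f"intron {intron} outside genome")
    spans = _ungapped_spans(source)
    out = []
    for intron in introns:
        chrom_spans = spans.get(intron.chrom, [])
        five = _count_covering(
            chrom_spans, intron.start - 1, intron.start + min_overhang - 1
        )
        three = _count_covering(
            chrom_spans, intron.end - min_overhang + 1, intron.end + 1
        )
        out.append(RetentionEvidence(intron, five, three))
    return out


def retention_evidence(
    source: str | Path,
    intron: GenomicInterval,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    genome: GenomeSequence | None = None,
) -> RetentionEvidence:
    """Single-intron form of :func:`retention_evidence_batch`."""
    return retention_evidence_batch(source, [intron], min_overhang, genome)[0]


def write_junction_bed(potential_introns: Iterable[PotentialIntron], path: str | Path) -> None:
    """Write junctions as BED (0-based half-open at this boundary only)."""
    with open(path, "w") as fh:
        for pi in potential_introns:
            iv = pi.interval
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tjunction\t{pi.read_support}\t.\n"
            )
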