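"""Reading-frame effects and in-silico protein isoforms (ORI vs VAR).

For each predicted event the gene is translated twice with the standard
nuclear genetic code, always from the annotated start codon: once with the
annotated splice pattern (ORI) and once with the predicted event applied
(VAR) — a novel intron spliced in addition, or an alternative-site intron
substituted for the annotated one.  If the event splices out the annotated
stop codon (a terminal intron), translation continues into downstream
genomic sequence to the next in-frame stop, bounded by ``extension_bound``;
an in-frame entry into a downstream gene's CDS on the same strand is
reported as a gene fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .io_models import (
    AnnotationSet,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
)

FRAME_PRESERVING = "preserving"
FRAME_DISRUPTIVE = "disruptive"
FRAME_NA = "not-applicable"

#: How far past the gene end the terminal-intron stop search extends (bases).
DEFAULT_EXTENSION_BOUND = 5000

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class FrameEffect:
    value: str  # preserving / disruptive / not-applicable
    basis: int | None  # intron length or |alt-site distance| taken mod 3


@dataclass
class IsoformConsequence:
    gene_id: str
    transcript_ori: str
    transcript_var: str
    protein_ori: str
    protein_var: str
    length_delta: int  # transcript VAR - ORI, in bases
    premature_stop: bool
    fusion_partner: str | None
    stop_found_var: bool = True


def frame_effect(basis: int, region: str) -> FrameEffect:
    """Mod-3 rule: a CDS event preserves the frame iff its basis is 0 mod 3.

    ``basis`` is the intron length for novel introns or the absolute
    alternative-site distance for alt-site events.  Outside the protein
    coding region (5'UTR, intergenic, terminal — where the stop codon itself
    is removed) the reading frame is not applicable.
    """
    if region != "CDS":
        return FrameEffect(FRAME_NA, None)
    basis = abs(basis)
    value = FRAME_PRESERVING if basis % 3 == 0 else FRAME_DISRUPTIVE
    return FrameEffect(value, basis % 3)


def _check_disjoint(introns: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    ordered = sorted(introns, key=lambda iv: iv.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end >= b.start:
            raise ValueError(f"introns {a} and {b} overlap")
    return ordered


def splice_transcript(
    gene: GeneModel | GenomicInterval,
    genome: GenomeSequence,
    introns_to_splice: Sequence[GenomicInterval] = (),
) -> str:
    """Transcribed sequence of the gene span minus the given introns.

    Returned on the coding strand (reverse complemented for minus-strand
    genes).  Introns must be mutually non-overlapping and within the span.
    """
    span = gene.span if isinstance(gene, GeneModel) else gene
    ordered = _check_disjoint(introns_to_splice)
    for intron in ordered:
        if not span.contains(intron):
            raise ValueError(f"intron {intron} outside span {span}")
    pieces = []
    cursor = span.start
    for intron in ordered:
        if intron.start > cursor:
            pieces.append(
                genome.subsequence(
                    GenomicInterval(span.chrom, cursor, intron.start - 1)
                )
            )
        cursor = intron.end + 1
    if cursor <= span.end:
        pieces.append(genome.subsequence(GenomicInterval(span.chrom, cursor, span.end)))
    product = "".join(pieces)
    if span.strand == "-":
        from .io_models import reverse_complement

        product = reverse_complement(product)
    return product


def _coding_positions(
    gene: GeneModel,
    introns: Sequence[GenomicInterval],
    genome: GenomeSequence,
    extension: int = 0,
) -> list[int]:
    """Genomic positions of coding bases in transcript order.

    Starts at the annotated start codon, walks along the transcribed strand
    to the 3' end of the CDS span plus ``extension`` bases, skipping any
    position inside a spliced-out intron.
    """
    span = gene.cds_span
    if span is None:
        raise ValueError(f"gene {gene.gene_id} has no CDS")
    chrom_len = genome.length(gene.chrom)
    excluded: list[tuple[int, int]] = [(iv.start, iv.end) for iv in introns]

    def in_intron(pos: int) -> bool:
        return any(s <= pos <= e for s, e in excluded)

    positions: list[int] = []
    if gene.strand == "-":
        stop_at = max(1, span.start - extension)
        pos = span.end
        while pos >= stop_at:
            if not in_intron(pos):
                positions.append(pos)
            pos -= 1
    else:
        stop_at = min(chrom_len, span.end + extension)
        pos = span.start
        while pos <= stop_at:
            if not in_intron(pos):
                positions.append(pos)
            pos += 1
    return positions


def _bases_at(genome: GenomeSequence, gene: GeneModel, positions: Sequence[int]) -> str:
    seq = genome[gene.chrom]
    if gene.strand == "-":
        return "".join(_COMPLEMENT_BASE.get(seq[p - 1], "N") for p in positions)
    return "".join(seq[p - 1] for p in positions)


def _translate_pattern(
    gene: GeneModel,
    genome: GenomeSequence,
    introns: Sequence[GenomicInterval],
    extension_bound: int,
) -> tuple[str, bool, int | None, list[int]]:
    """Translate the gene with the given spliced-out introns.

    Returns (protein with trailing '*' if a stop was reached, stop_found,
    genomic position of the stop codon's first base, codon-start positions).
    """
    positions = _coding_positions(gene, introns, genome, extension=extension_bound)
    bases = _bases_at(genome, gene, positions)
    if bases[:3] != "ATG":
        raise ValueError(
            f"gene {gene.gene_id} does not begin with a start codon (got {bases[:3]!r})"
        )
    protein_chars: list[str] = []
    codon_starts: list[int] = []
    stop_found = False
    stop_pos: int | None = None
    for i in range(0, len(bases) - 2, 3):
        codon = bases[i : i + 3]
        aa = str(Seq(codon).translate())
        codon_starts.append(positions[i])
        if aa == "*":
            protein_chars.append("*")
            stop_found = True
            stop_pos = positions[i]
            break
        protein_chars.append(aa)
    return "".join(protein_chars), stop_found, stop_pos, codon_starts


def _var_intron_pattern(
    gene: GeneModel, predicted: GenomicInterval
) -> list[GenomicInterval]:
    """Annotated pattern with the predicted intron substituted or added."""
    overlapping = [iv for iv in gene.annotated_introns if iv.overlaps(predicted)]
    if len(overlapping) > 1:
        raise ValueError(
            f"predicted intron {predicted} overlaps multiple annotated introns"
        )
    pattern = [iv for iv in gene.annotated_introns if iv not in overlapping]
    pattern.append(predicted)
    return _check_disjoint(pattern)


def translate_isoform(
    gene: GeneModel,
    genome: GenomeSequence,
    predicted_intron: GenomicInterval,
    annotation: AnnotationSet | None = None,
    extension_bound: int = DEFAULT_EXTENSION_BOUND,
) -> IsoformConsequence:
    """ORI vs VAR transcripts and proteins for one predicted event."""
    annotated = list(gene.annotated_introns)
    var_pattern = _var_intron_pattern(gene, predicted_intron)

    protein_ori, _, _, _ = _translate_pattern(gene, genome, annotated, 0)
    protein_var, stop_found, stop_pos, codon_starts = _translate_pattern(
        gene, genome, var_pattern, extension_bound
    )

    # transcripts over the hull of gene span and event, so the VAR/ORI delta
    # is well-defined even for terminal introns extending past the gene end
    hull = GenomicInterval(
        gene.chrom,
        min(gene.span.start, predicted_intron.start),
        max(gene.span.end, predicted_intron.end),
        gene.strand,
    )
    transcript_ori = splice_transcript(hull, genome, annotated)
    transcript_var = splice_transcript(hull, genome, var_pattern)

    stop = gene.stop_codon
    premature = False
    if stop_found and stop_pos is not None and stop is not None:
        if gene.strand == "-":
            premature = stop_pos > stop.end
        else:
            premature = stop_pos < stop.start

    fusion = _find_fusion_partner(gene, genome, annotation, codon_starts)

    return IsoformConsequence(
        gene_id=gene.gene_id,
        transcript_ori=transcript_ori,
        transcript_var=transcript_var,
        protein_ori=protein_ori,
        protein_var=protein_var,
        length_delta=len(transcript_var) - len(transcript_ori),
        premature_stop=premature,
        fusion_partner=fusion,
        stop_found_var=stop_found,
    )


def _find_fusion_partner(
    gene: GeneModel,
    genome: GenomeSequence,
    annotation: AnnotationSet | None,
    codon_starts: Sequence[int],
) -> str | None:
    """Downstream same-strand gene whose CDS the extension enters in frame.

    A codon start of the extended VAR reading frame must coincide with a
    codon start of the partner's own annotated reading frame.
    """
    if annotation is None or not codon_starts:
        return None
    span = gene.cds_span
    if gene.strand == "-":
        beyond = [p for p in codon_starts if p < span.start]
    else:
        beyond = [p for p in codon_starts if p > span.end]
    if not beyond:
        return None
    ext_region = GenomicInterval(gene.chrom, min(beyond), max(beyond))
    beyond_set = set(beyond)
    for other in annotation.genes_overlapping(ext_region):
        if other.gene_id == gene.gene_id or other.strand != gene.strand:
            continue
        if not other.cds_segments:
            continue
        other_positions = _coding_positions(other, other.annotated_introns, genome, 0)
        for idx in range(0, len(other_positions), 3):
            if other_positions[idx] in beyond_set:
                return other.gene_id
    return None


def protein_delta(protein_ori: str, protein_var: str) -> tuple[int, int]:
    """(residues removed, residues inserted) by longest common prefix/suffix."""
    p = 0
    limit = min(len(protein_ori), len(protein_var))
    while p < limit and protein_ori[p] == protein_var[p]:
        p += 1
    s = 0
    while (
        s < limit - p
        and protein_ori[len(protein_ori) - 1 - s] == protein_var[len(protein_var) - 1 - s]
    ):
        s += 1
    return len(protein_ori) - p - s, len(protein_var) - p - s


def consequence_report(consequence: IsoformConsequence, event: str = "") -> str:
    """Flat-text record: header, event, delta, then ORI/VAR sequences."""
    lines = [
        f"> {consequence.gene_id} {event}".rstrip(),
        f"length_delta_bases\t{consequence.length_delta}",
        f"premature_stop\t{consequence.premature_stop}",
        f"fusion_partner\t{consequence.fusion_partner or '-'}",
        f"ORI_transcript\t{consequence.transcript_ori}",
        f"VAR_transcript\t{consequence.transcript_var}",
        f"ORI_protein\t{consequence.protein_ori}",
        f"VAR_protein\t{consequence.protein_var}",
    ]
    return "\n".join(lines) + "\n"
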