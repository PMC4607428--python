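"""Grouping of predicted introns and alternative-splicing classification.

Predicted introns overlapping on the same chromosome and inferred strand are
grouped (connected components of the pairwise-overlap graph).  Within a
group the member with the highest read support is the reference; members are
classified by which transcribed-strand end differs from the comparison
reference: the acceptor side (``alt3``), the donor side (``alt5``) or both.
Exact matches of annotated introns keep class ``annotated``; isolated
non-annotated introns are ``single`` (no evidence of alternative splicing).

Signed alternative-site distances are positive when the member intron is
extended relative to the reference on the varying side and negative when
shortened.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_models import (
    DEFAULT_UTR_WINDOW,
    AnnotationSet,
    GenomeSequence,
    GenomicInterval,
)
from .intron_filtering import PredictedIntron

CLASS_ANNOTATED = "annotated"
CLASS_SINGLE = "single"
CLASS_REFERENCE = "reference"
CLASS_ALT3 = "alt3"
CLASS_ALT5 = "alt5"
CLASS_BOTH = "both"

AS_CLASSES = (
    CLASS_ANNOTATED,
    CLASS_SINGLE,
    CLASS_REFERENCE,
    CLASS_ALT3,
    CLASS_ALT5,
    CLASS_BOTH,
)

REGION_CDS = "CDS"
REGION_UTR5 = "5'UTR"
REGION_TERMINAL = "terminal"
REGION_INTERGENIC = "intergenic"
REGION_MULTIPLE = "multiple"


@dataclass(frozen=True)
class AltSiteDistance:
    """Signed offset of an alternative splice site from the reference site."""

    side: str  # "3'" or "5'"
    distance: int

    def __post_init__(self) -> None:
        if self.side not in ("3'", "5'"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.distance == 0:
            raise ValueError("alternative-site distance cannot be zero")


@dataclass
class IntronGroup:
    members: list[PredictedIntron]
    reference: PredictedIntron

    def __post_init__(self) -> None:
        if not any(m is self.reference for m in self.members):
            raise ValueError("reference must be a group member")


@dataclass(frozen=True)
class GeneRegionCall:
    region: str
    gene_id: str | None


@dataclass
class ClassifiedIntron:
    intron: PredictedIntron
    as_class: str
    distances: tuple[AltSiteDistance, ...]
    region: GeneRegionCall
    annotated_exact: bool


def match_annotated(
    predicted_intron: PredictedIntron, annotation: AnnotationSet
) -> str:
    """"exact-annotated" iff an annotated intron has identical coordinates."""
    if annotation.has_exact_intron(predicted_intron.interval):
        return "exact-annotated"
    return "novel"


def _reference_key(p: PredictedIntron) -> tuple[int, int, int]:
    # higher support first, then shorter intron, then leftmost start
    return (-p.read_support, p.length, p.interval.start)


def group_overlapping(
    predicted_introns: Iterable[PredictedIntron],
) -> list[IntronGroup]:
    """Connected components of the overlap graph per chromosome and strand.

    Overlap means at least one shared base; bookended introns are separate
    groups.  Singleton groups are allowed.
    """
    by_key: dict[tuple[str, str], list[PredictedIntron]] = {}
    for p in predicted_introns:
        by_key.setdefault((p.interval.chrom, p.strand), []).append(p)
    groups: list[IntronGroup] = []
    for _, members in sorted(by_key.items()):
        members.sort(key=lambda p: (p.interval.start, p.interval.end))
        current: list[PredictedIntron] = []
        reach = -1
        for p in members:
            if current and p.interval.start > reach:
                groups.append(_close_group(current))
                current = []
            current.append(p)
            reach = max(reach, p.interval.end)
        if current:
            groups.append(_close_group(current))
    return groups


def _close_group(members: list[PredictedIntron]) -> IntronGroup:
    reference = min(members, key=_reference_key)
    return IntronGroup(members=list(members), reference=reference)


def _ends(interval: GenomicInterval, strand: str) -> tuple[int, int]:
    """(5'-site, 3'-site) genomic coordinates on the given strand."""
    if strand == "-":
        return interval.end, interval.start
    return interval.start, interval.end


def classify_event(
    member: PredictedIntron,
    reference: PredictedIntron,
    strand: str,
) -> tuple[str, tuple[AltSiteDistance, ...]]:
    """AS class of ``member`` relative to ``reference`` on ``strand``.

    Returns the class and the signed distance(s).  Positive distance means
    the member intron extends past the reference splice site (longer intron
    on that side); negative means it is shortened.
    """
    if not member.interval.overlaps(reference.interval):
        raise ValueError("member and reference introns do not overlap")
    m5, m3 = _ends(member.interval, strand)
    r5, r3 = _ends(reference.interval, strand)
    distances: list[AltSiteDistance] = []
    if m5 != r5:
        # donor side: on "+" a smaller start extends the intron
        delta = (r5 - m5) if strand != "-" else (m5 - r5)
        distances.append(AltSiteDistance("5'", delta))
    if m3 != r3:
        delta = (m3 - r3) if strand != "-" else (r3 - m3)
        distances.append(AltSiteDistance("3'", delta))
    if not distances:
        raise ValueError("member and reference have identical coordinates")
    if len(distances) == 2:
        return CLASS_BOTH, tuple(distances)
    side = distances[0].side
    return (CLASS_ALT3 if side == "3'" else CLASS_ALT5), tuple(distances)


def locate_in_gene(
    interval: GenomicInterval,
    annotation: AnnotationSet,
    genome: GenomeSequence | None = None,
    utr_window: int = DEFAULT_UTR_WINDOW,
) -> GeneRegionCall:
    """Assign a predicted intron to a gene region.

    ``terminal`` (contains a gene's full stop codon) takes precedence, so a
    terminal intron running into a downstream gene is not demoted to
    ``multiple``.  Otherwise: ``CDS`` if fully inside one gene's CDS span,
    ``5'UTR`` if fully inside the 5'UTR search region, ``intergenic`` if no
    gene is touched, ``multiple`` for everything straddling boundaries.
    """
    overlapping = annotation.genes_overlapping(interval)
    coding = [g for g in overlapping if g.cds_segments]
    for gene in coding:
        stop = gene.stop_codon
        if stop is not None and interval.contains(stop):
            return GeneRegionCall(REGION_TERMINAL, gene.gene_id)
    candidates = list(overlapping)
    # 5'UTR windows may extend beyond the annotated gene span
    if not candidates:
        for gene in annotation.genes:
            if gene.chrom != interval.chrom or not gene.cds_segments:
                continue
            chrom_len = genome.length(interval.chrom) if genome is not None else None
            utr = gene.utr5_region(utr_window, chrom_len)
            if utr is not None and utr.contains(interval):
                candidates.append(gene)
    if not candidates:
        return GeneRegionCall(REGION_INTERGENIC, None)
    if len(candidates) > 1:
        return GeneRegionCall(REGION_MULTIPLE, None)
    gene = candidates[0]
    cds_span = gene.cds_span
    if cds_span is not None and cds_span.contains(interval):
        return GeneRegionCall(REGION_CDS, gene.gene_id)
    chrom_len = genome.length(interval.chrom) if genome is not None else None
    utr = gene.utr5_region(utr_window, chrom_len)
    if utr is not None and utr.contains(interval):
        return GeneRegionCall(REGION_UTR5, gene.gene_id)
    return GeneRegionCall(REGION_MULTIPLE, gene.gene_id)


def classify_predicted(
    predicted_introns: Sequence[PredictedIntron],
    annotation: AnnotationSet,
    genome: GenomeSequence | None = None,
    utr_window: int = DEFAULT_UTR_WINDOW,
) -> list[ClassifiedIntron]:
    """Group, classify and locate every predicted intron.

    When a group contains an exact-annotated intron it is used as the
    comparison reference for alternative-site distances (the canonical
    splice sites), even if a novel member has higher support; the
    ``reference`` class label still goes to the max-support member.
    """
    out: list[ClassifiedIntron] = []
    for group in group_overlapping(predicted_introns):
        annotated_members = [
            m for m in group.members if annotation.has_exact_intron(m.interval)
        ]
        if annotated_members:
            comparison = min(annotated_members, key=_reference_key)
        else:
            comparison = group.reference
        for member in group.members:
            exact = annotation.has_exact_intron(member.interval)
            if exact:
                as_class = CLASS_ANNOTATED
                distances: tuple[AltSiteDistance, ...] = ()
            elif len(group.members) == 1:
                as_class = CLASS_SINGLE
                distances = ()
            elif member is group.reference:
                as_class = CLASS_REFERENCE
                distances = ()
            elif member is comparison:
                as_class = CLASS_REFERENCE
                distances = ()
            else:
                as_class, distances = classify_event(
                    member, comparison, member.strand
                )
            region = locate_in_gene(member.interval, annotation, genome, utr_window)
            out.append(
                ClassifiedIntron(
                    intron=member,
                    as_class=as_class,
                    distances=distances,
                    region=region,
                    annotated_exact=exact,
                )
            )
    return out


def class_counts(classified: Iterable[ClassifiedIntron]) -> dict[str, int]:
    counts = {c: 0 for c in AS_CLASSES}
    for item in classified:
        counts[item.as_class] += 1
    return counts


def classified_to_frame(classified: Sequence[ClassifiedIntron]) -> pd.DataFrame:
    """Event table shaped like the published intron tables."""
    rows = []
    for item in classified:
        iv = item.intron.interval
        dist3 = next((d.distance for d in item.distances if d.side == "3'"), None)
        dist5 = next((d.distance for d in item.distances if d.side == "5'"), None)
        rows.append(
            {
                "chrom": iv.chrom,
                "strand": item.intron.strand,
                "start": iv.start,
                "end": iv.end,
                "length": iv.length,
                "read_support": item.intron.read_support,
                "as_class": item.as_class,
                "region": item.region.region,
                "gene": item.region.gene_id or "",
                "distance_3p": dist3,
                "distance_5p": dist5,
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
            "as_class",
            "region",
            "gene",
            "distance_3p",
            "distance_5p",
        ],
    )
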