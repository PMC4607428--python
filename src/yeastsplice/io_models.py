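"""Genome / annotation input and strand-aware coordinate utilities.

All coordinates exposed by this package are 1-based and inclusive on both
ends, so ``length == end - start + 1`` holds for every interval, matching the
convention of the yeast community's printed intron tables.  Minus-strand
sequence requests return the reverse complement, i.e. the transcribed
sequence.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Default chromosome names treated as mitochondrial (excluded from nuclear
#: splicing analysis; the organellar group-I/II introns follow different rules).
DEFAULT_MITO_NAMES = ("chrmt", "chrM", "Mito", "chrMito", "MT")

#: Default width of the 5'UTR search window upstream of the CDS start, used
#: when a gene has no transcript annotation extending beyond its CDS.
DEFAULT_UTR_WINDOW = 300

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval.

    ``strand`` is "+", "-" or "." (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def same_locus(self, other: "GenomicInterval") -> bool:
        """Coordinate identity, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and self.end == other.end
        )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def with_strand(self, strand: str) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start, self.end, strand)


class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase nucleotide string."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self.chromosomes: dict[str, str] = {
            name: seq.upper() for name, seq in chromosomes.items()
        }

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def subsequence(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval`` on its own strand.

        Returns the genomic-forward sequence for "+" or unknown strand and
        the reverse complement for "-".
        """
        if interval.chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        seq = self.chromosomes[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {len(seq)}"
            )
        sub = seq[interval.start - 1 : interval.end]
        if interval.strand == "-":
            return reverse_complement(sub)
        return sub


def subsequence(genome: GenomeSequence, interval: GenomicInterval) -> str:
    """Module-level convenience wrapper for :meth:`GenomeSequence.subsequence`."""
    return genome.subsequence(interval)


def read_genome(fasta_path: str | Path) -> GenomeSequence:
    """Load a (multi-)FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; ``N`` is allowed.  Raises ``ValueError`` on an
    empty file, a duplicated record name, or a record without sequence.
    """
    path = Path(fasta_path)
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate FASTA record {record.id!r} in {path}")
        seq = str(record.seq)
        if not seq:
            raise ValueError(f"FASTA record {record.id!r} in {path} has no sequence")
        chromosomes[record.id] = seq.upper()
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(chromosomes)


@dataclass(eq=False)  # identity semantics; gene models are index entries
class GeneModel:
    """A gene with ordered CDS segments and its annotated introns.

    ``cds_segments`` are ordered 5'->3' on the transcribed strand and include
    the stop codon (GFF convention).  ``annotated_introns`` carry the gene's
    strand.
    """

    gene_id: str
    span: GenomicInterval
    cds_segments: list[GenomicInterval] = field(default_factory=list)
    annotated_introns: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein-coding"
    chromosome_class: str = "nuclear"
    transcript_span: GenomicInterval | None = None

    def __post_init__(self) -> None:
        for intron in self.annotated_introns:
            if not self.span.contains(intron) and self.transcript_span is not None:
                if not self.transcript_span.contains(intron):
                    raise ValueError(
                        f"annotated intron {intron} outside gene {self.gene_id}"
                    )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def cds_span(self) -> GenomicInterval | None:
        """Genomic hull of all CDS segments (includes internal introns)."""
        if not self.cds_segments:
            return None
        start = min(seg.start for seg in self.cds_segments)
        end = max(seg.end for seg in self.cds_segments)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def cds_start_position(self) -> int | None:
        """Genomic position of the first base of the start codon."""
        span = self.cds_span
        if span is None:
            return None
        return span.end if self.strand == "-" else span.start

    @property
    def stop_codon(self) -> GenomicInterval | None:
        """Genomic interval of the stop codon (last 3 coding bases)."""
        span = self.cds_span
        if span is None or span.length < 3:
            return None
        if self.strand == "-":
            return GenomicInterval(self.chrom, span.start, span.start + 2, "-")
        return GenomicInterval(self.chrom, span.end - 2, span.end, "+")

    def utr5_region(
        self, utr_window: int = DEFAULT_UTR_WINDOW, chrom_length: int | None = None
    ) -> GenomicInterval | None:
        """5'UTR search region.

        Uses the annotated transcript extent upstream of the CDS when
        available, otherwise a fixed window upstream of the CDS start (yeast
        GFFs rarely delimit UTRs explicitly).
        """
        span = self.cds_span
        if span is None:
            return None
        if self.strand == "-":
            lo = span.end + 1
            if self.transcript_span is not None and self.transcript_span.end > span.end:
                hi = self.transcript_span.end
            else:
                hi = span.end + utr_window
            if chrom_length is not None:
                hi = min(hi, chrom_length)
            if hi < lo:
                return None
            return GenomicInterval(self.chrom, lo, hi, "-")
        hi = span.start - 1
        if self.transcript_span is not None and self.transcript_span.start < span.start:
            lo = self.transcript_span.start
        else:
            lo = max(1, span.start - utr_window)
        if hi < lo:
            return None
        return GenomicInterval(self.chrom, lo, hi, "+")


class AnnotationSet:
    """Collection of gene models with interval indexes for fast lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        self._intron_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._gene_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intron_keys: set[tuple[str, int, int]] = set()
        for gene in self.genes:
            lookup_span = gene.span
            if gene.transcript_span is not None:
                lookup_span = GenomicInterval(
                    gene.chrom,
                    min(gene.span.start, gene.transcript_span.start),
                    max(gene.span.end, gene.transcript_span.end),
                    gene.strand,
                )
            self._gene_tree[gene.chrom].addi(
                lookup_span.start, lookup_span.end + 1, gene
            )
            for intron in gene.annotated_introns:
                self._intron_tree[intron.chrom].addi(
                    intron.start, intron.end + 1, (gene, intron)
                )
                self._intron_keys.add(intron.key)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        hits = self._gene_tree[interval.chrom].overlap(
            interval.start, interval.end + 1
        )
        return sorted({h.data for h in hits}, key=lambda g: (g.span.start, g.gene_id))

    def introns_overlapping(
        self, interval: GenomicInterval
    ) -> list[tuple[GeneModel, GenomicInterval]]:
        hits = self._intron_tree[interval.chrom].overlap(
            interval.start, interval.end + 1
        )
        return sorted((h.data for h in hits), key=lambda gi: gi[1].start)

    def has_exact_intron(self, interval: GenomicInterval) -> bool:
        return interval.key in self._intron_keys

    def all_introns(
        self,
        include_mitochondrial: bool = False,
        exclude_biotypes: Sequence[str] = ("tRNA", "snoRNA"),
    ) -> list[tuple[GeneModel, GenomicInterval]]:
        """All annotated introns, by default nuclear and non-structural-RNA."""
        out = []
        for gene in self.genes:
            if not include_mitochondrial and gene.chromosome_class == "mitochondrial":
                continue
            if gene.biotype in exclude_biotypes:
                continue
            for intron in gene.annotated_introns:
                out.append((gene, intron))
        return out


_GENE_TYPES_SUFFIX = "_gene"
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "tRNA", "snoRNA", "ncRNA", "rRNA", "snRNA"}


def _gene_biotype(feature: gffutils.Feature, has_cds: bool) -> str:
    ftype = feature.featuretype
    attrs = feature.attributes
    for key in ("gene_biotype", "biotype", "so_term_name"):
        if key in attrs:
            val = attrs[key][0]
            if "tRNA" in val:
                return "tRNA"
            if "snoRNA" in val:
                return "snoRNA"
            if "protein" in val:
                return "protein-coding"
    if "tRNA" in ftype:
        return "tRNA"
    if "snoRNA" in ftype:
        return "snoRNA"
    if has_cds:
        return "protein-coding"
    return "other"


def _derive_introns_from_segments(
    segments: list[gffutils.Feature],
) -> list[tuple[int, int]]:
    """Gaps between consecutive (sorted) exon or CDS features."""
    introns = []
    ordered = sorted(segments, key=lambda f: f.start)
    for left, right in zip(ordered, ordered[1:]):
        if right.start > left.end + 1:
            introns.append((left.end + 1, right.start - 1))
    return introns


def read_annotation(
    gff_path: str | Path,
    genome: GenomeSequence,
    utr_window: int = DEFAULT_UTR_WINDOW,
    mito_names: Sequence[str] = DEFAULT_MITO_NAMES,
) -> AnnotationSet:
    """Parse a GFF3/GFF annotation into an :class:`AnnotationSet`.

    Introns absent as explicit ``intron`` features are derived as gaps
    between consecutive exons (per transcript), falling back to gaps between
    CDS segments.  Features on chromosomes missing from ``genome`` are
    rejected with a warning; coordinates beyond the chromosome end raise.
    Genes without a strand are skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_types = [
        t for t in db.featuretypes() if t == "gene" or t.endswith(_GENE_TYPES_SUFFIX)
    ]
    genes: list[GeneModel] = []
    mito_set = set(mito_names)
    for ftype in gene_types:
        for feat in db.features_of_type(ftype):
            if feat.seqid not in genome:
                logger.warning(
                    "rejecting gene %s on chromosome %s absent from genome",
                    feat.id,
                    feat.seqid,
                )
                continue
            if feat.end > genome.length(feat.seqid):
                raise ValueError(
                    f"gene {feat.id} coordinates exceed chromosome {feat.seqid} "
                    f"length {genome.length(feat.seqid)}"
                )
            if feat.strand not in ("+", "-"):
                logger.warning("skipping gene %s without strand", feat.id)
                continue
            strand = feat.strand
            cds_feats = list(db.children(feat, featuretype="CDS"))
            exon_feats = list(db.children(feat, featuretype="exon"))
            intron_feats = list(db.children(feat, featuretype="intron"))
            transcript_feats = [
                c
                for c in db.children(feat, level=1)
                if c.featuretype in _TRANSCRIPT_TYPES
            ]

            intron_coords: set[tuple[int, int]] = {
                (f.start, f.end) for f in intron_feats
            }
            if not intron_coords:
                if exon_feats:
                    # derive per transcript so alternative transcripts do not
                    # produce spurious cross-transcript gaps
                    by_parent: dict[str, list[gffutils.Feature]] = defaultdict(list)
                    for ex in exon_feats:
                        parent = ex.attributes.get("Parent", [feat.id])[0]
                        by_parent[parent].append(ex)
                    for exons in by_parent.values():
                        intron_coords.update(_derive_introns_from_segments(exons))
                elif cds_feats:
                    intron_coords.update(_derive_introns_from_segments(cds_feats))

            cds_segments = [
                GenomicInterval(feat.seqid, f.start, f.end, strand)
                for f in sorted(cds_feats, key=lambda f: f.start)
            ]
            if strand == "-":
                cds_segments = cds_segments[::-1]

            transcript_span = None
            if transcript_feats:
                transcript_span = GenomicInterval(
                    feat.seqid,
                    min(t.start for t in transcript_feats),
                    max(t.end for t in transcript_feats),
                    strand,
                )

            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    span=GenomicInterval(feat.seqid, feat.start, feat.end, strand),
                    cds_segments=cds_segments,
                    annotated_introns=[
                        GenomicInterval(feat.seqid, s, e, strand)
                        for s, e in sorted(intron_coords)
                    ],
                    biotype=_gene_biotype(feat, bool(cds_feats)),
                    chromosome_class=(
                        "mitochondrial" if feat.seqid in mito_set else "nuclear"
                    ),
                    transcript_span=transcript_span,
                )
            )
    return AnnotationSet(genes)
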