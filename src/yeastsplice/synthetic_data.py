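"""Synthetic genome, annotation and pre-spliced alignments with ground truth.

The generator emulates the structure of the yeast transcriptome relevant to
splice-junction discovery: two-exon genes with one intron, a bimodal intron
length distribution with modes near 100 and 400 bases, GT..AG donor/acceptor
dinucleotides with a TACTAAC branch-point motif upstream of the acceptor,
100-base reads, and configurable mixtures of spliced, unspliced,
alternative-site, UTR, terminal and fusion isoforms.  Alignments are emitted
directly with exact CIGAR strings (no mapper involved), so the planted truth
is exact and the whole pipeline is testable offline.

Every gene cassette is composed in transcribed space and reverse-complemented
into the chromosome for minus-strand genes, which keeps the motif surgery
strand-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .intron_filtering import FilterConfig
from .io_models import GenomeSequence, GenomicInterval, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_CODON_TABLE = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
}

# isoform kinds; genes in the first group carry an annotated intron
ANNOTATED_KINDS = ("annotated", "retention", "alt3", "alt5", "both")
NOVEL_KINDS = (
    "novel_cds_inframe",
    "novel_cds_frameshift",
    "utr5",
    "terminal",
    "fusion_terminal",
)

DEFAULT_EVENT_MIX: dict[str, float] = {
    "annotated": 0.25,
    "retention": 0.10,
    "alt3": 0.15,
    "alt5": 0.10,
    "both": 0.05,
    "novel_cds_inframe": 0.10,
    "novel_cds_frameshift": 0.05,
    "utr5": 0.10,
    "terminal": 0.05,
    "fusion_terminal": 0.05,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    ``major_support`` is the junction read count of the dominant spliced
    isoform, ``minor_support`` that of alternative/novel minor isoforms, and
    ``unspliced_reads`` the number of ungapped reads tiled across each splice
    boundary (evidence of the unspliced transcript).
    """

    seed: int = 1
    n_genes: int = 50
    n_chromosomes: int = 2
    read_length: int = 100
    short_mean: float = 100.0
    short_sd: float = 15.0
    long_mean: float = 400.0
    long_sd: float = 50.0
    p_short: float = 0.6
    major_support: int = 30
    minor_support: int = 8
    unspliced_reads: int = 6
    event_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    repeat_prob: float = 0.1
    error_rate: float = 0.0
    min_anchor: int = 10
    utr_length: int = 200
    trailer_length: int = 400
    ensure_all_kinds: bool = True

    def __post_init__(self) -> None:
        total = sum(self.event_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"event_mix proportions sum to {total}, expected 1")
        unknown = set(self.event_mix) - set(ANNOTATED_KINDS) - set(NOVEL_KINDS)
        if unknown:
            raise ValueError(f"unknown event kinds: {sorted(unknown)}")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must be >= 2 * min_anchor")
        if max(self.major_support, self.minor_support) > 60:
            raise ValueError("support levels above 60 reads are not supported")


@dataclass
class PlantedIntron:
    """One planted junction with its expected pipeline outcome."""

    interval: GenomicInterval  # carries the gene strand
    kind: str
    support: int
    fragments: int
    expected_class: str
    distance_3p: int | None
    distance_5p: int | None
    expected_slack: int
    region: str
    frame_basis: int | None
    gene_id: str
    anchor_left: int = 0
    anchor_right: int = 0


@dataclass
class PlantedGene:
    gene_id: str
    kind: str
    chrom: str
    strand: str
    gene_span: GenomicInterval
    transcript_span: GenomicInterval
    cds_span: GenomicInterval
    annotated_introns: list[GenomicInterval]
    planted: list[PlantedIntron]
    protein_ori: str
    protein_var: str | None
    premature_stop_var: bool | None
    fusion_partner: str | None


@dataclass(frozen=True)
class PlannedRead:
    read_id: str
    chrom: str
    pos: int  # 1-based leftmost
    cigar: str
    blocks: tuple[tuple[int, int], ...]


@dataclass
class SyntheticTruth:
    """Planted genes, junction truth and the deterministic read plan."""

    config: SimulationConfig
    genome: GenomeSequence
    genes: list[PlantedGene]
    junctions: dict[tuple[str, int, int], PlantedIntron]
    expected_predicted: set[tuple[str, int, int]]
    retention_expected: dict[tuple[str, int, int], tuple[int, int]]
    reads: list[PlannedRead]
    gff_text: str


# ---------------------------------------------------------------------------
# sequence composition helpers (transcribed space)
# ---------------------------------------------------------------------------


def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _rand_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_CODONS), size=n)
    return list("".join(_CODONS[i] for i in idx))


def _translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate from position 0; returns (protein ending '*' if stopped, found)."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODON_TABLE.get(seq[i : i + 3], "X")
        out.append(aa)
        if aa == "*":
            return "".join(out), True
    return "".join(out), False


def _make_intron(rng: np.random.Generator, length: int) -> list[str]:
    """Canonical intron: GTATGT head, TACTAAC branch point, AG acceptor."""
    if length < 40:
        raise ValueError("intron length below 40")
    b = _rand_bases(rng, length)
    b[0:6] = list("GTATGT")
    b[length - 2 :] = list("AG")
    bp = length - 27
    b[bp : bp + 7] = list("TACTAAC")
    return b


def sample_intron_length(
    rng: np.random.Generator, config: SimulationConfig, lo: int = 60, hi: int = 1000
) -> int:
    """Draw from the bimodal intron-length mixture, clipped to [lo, hi]."""
    for _ in range(1000):
        if rng.random() < config.p_short:
            value = rng.normal(config.short_mean, config.short_sd)
        else:
            value = rng.normal(config.long_mean, config.long_sd)
        value = int(round(value))
        if lo <= value <= hi:
            return value
    raise RuntimeError("intron length sampling failed")


def _apply_codon_safe(coding: list[str], sets: dict[int, str]) -> bool:
    """Apply base substitutions unless they create an internal in-frame stop."""
    old = {i: coding[i] for i in sets}
    for i, b in sets.items():
        coding[i] = b
    for c0 in sorted({(i // 3) * 3 for i in sets}):
        codon = "".join(coding[c0 : c0 + 3])
        if codon in _STOPS and c0 != len(coding) - 3:
            for i, b in old.items():
                coding[i] = b
            return False
    return True


def _ensure_stop(region: list[str], first_codon: int, plant_at_codon: int = 12) -> None:
    """Guarantee an in-frame stop in ``region`` for codons starting at
    ``first_codon`` (+3k); plants TAA if none occurs naturally."""
    for c0 in range(first_codon, len(region) - 2, 3):
        if "".join(region[c0 : c0 + 3]) in _STOPS:
            return
    c0 = first_codon + 3 * plant_at_codon
    while c0 + 3 > len(region):
        c0 -= 3
    region[c0 : c0 + 3] = list("TAA")


def _clear_stops(region: list[str], first_codon: int, end: int) -> None:
    """Remove in-frame stops from region[first_codon:end] (codon steps)."""
    for c0 in range(first_codon, min(end, len(region)) - 2, 3):
        if "".join(region[c0 : c0 + 3]) in _STOPS:
            region[c0] = "C"  # no stop codon contains C


# ---------------------------------------------------------------------------
# cassette construction
# ---------------------------------------------------------------------------


@dataclass
class _PlantSpec:
    """A planted junction in cassette coordinates (1-based, transcribed)."""

    start: int
    end: int
    kind: str
    support: int
    expected_class: str
    distance_3p: int | None = None
    distance_5p: int | None = None
    expected_slack: int = 0
    region: str = "CDS"
    frame_basis: int | None = None


@dataclass
class _Cassette:
    kind: str  # realized kind (surgery failures fall back to "annotated")
    seq: str
    gene: tuple[int, int]
    transcript: tuple[int, int]
    cds: tuple[int, int]
    annot_introns: list[tuple[int, int]]
    plants: list[_PlantSpec]
    protein_ori: str
    protein_var: str | None
    premature_stop_var: bool | None
    boundary_mult: int = 1
    partner_cds: tuple[int, int] | None = None
    partner_protein: str | None = None


def _pick_insertion_offset(
    rng: np.random.Generator, coding: list[str], lo: int, hi: int
) -> int:
    """Offset o with non-G neighbours so the planted junction has zero slack."""
    candidates = list(range(lo, hi))
    rng.shuffle(candidates)
    for o in candidates:
        if coding[o - 1] != "G" and coding[o] != "G":
            return o
    raise RuntimeError("no slack-free insertion offset found")


def _alt_site_surgery(
    rng: np.random.Generator,
    coding: list[str],
    intron: list[str],
    o_a: int,
    kind: str,
) -> tuple[int | None, int | None]:
    """Plant alternative donor/acceptor sites; returns (distance_5p, distance_3p).

    Negative distances shorten the intron (alternative site inside it),
    positive distances extend it into the flanking exon (codon-safe surgery
    on the coding sequence).
    """
    L = len(intron)
    d5 = d3 = None
    if kind in ("alt3", "both"):
        if kind == "both":
            choices = [-6, -3]
        else:
            choices = [-18, -12, -9, -7, -6, -4, -3, 3, 4, 8, 9, 12]
        rng.shuffle(choices)
        for d in choices:
            if d < 0:
                if -d > 15:
                    continue
                intron[L + d - 2] = "A"
                intron[L + d - 1] = "G"
                if intron[L + d] == "G":
                    intron[L + d] = "C"
                d3 = d
                break
            if o_a + d + 3 > len(coding) - 3:
                continue
            sets = {o_a + d - 2: "A", o_a + d - 1: "G"}
            if coding[o_a + d] == "G":
                sets[o_a + d] = "C"
            if _apply_codon_safe(coding, sets):
                d3 = d
                break
    if kind in ("alt5", "both"):
        if kind == "both":
            choices = [-9, -6]
        else:
            choices = [-18, -12, -9, -7, -6, 6, 7, 9, 12]
        rng.shuffle(choices)
        for d in choices:
            if d < 0:
                if -d < 6 or -d > L - 40:
                    continue
                intron[-d] = "G"
                intron[-d + 1] = "T"
                if intron[-d - 1] == "G":
                    intron[-d - 1] = "C"
                d5 = d
                break
            if o_a - d - 1 < 3:
                continue
            sets = {o_a - d: "G", o_a - d + 1: "T"}
            if coding[o_a - d - 1] == "G":
                sets[o_a - d - 1] = "C"
            if _apply_codon_safe(coding, sets):
                d5 = d
                break
    return d5, d3


def _build_cassette(
    rng: np.random.Generator, config: SimulationConfig, kind: str, index: int
) -> _Cassette:
    pad5 = _rand_bases(rng, 150)
    utr = _rand_bases(rng, config.utr_length)
    n_codons = int(rng.integers(70, 110))
    coding = list("ATG") + _rand_codons(rng, n_codons) + list("TAA")
    trailer = _rand_bases(rng, config.trailer_length)
    pad3 = _rand_bases(rng, 50)

    annot_introns_local: list[tuple[int, int]] = []  # offsets within coding
    plants: list[_PlantSpec] = []
    protein_var: str | None = None
    premature_var: bool | None = None
    partner_cds = None
    partner_protein = None
    boundary_mult = 3 if kind == "retention" else 1
    intron: list[str] = []
    o_a = None

    if kind in ANNOTATED_KINDS:
        L = sample_intron_length(rng, config)
        intron = _make_intron(rng, L)
        o_a = _pick_insertion_offset(rng, coding, 21, len(coding) - 45)
        d5 = d3 = None
        if kind in ("alt3", "alt5", "both"):
            d5, d3 = _alt_site_surgery(rng, coding, intron, o_a, kind)
            if kind == "alt3" and d3 is None:
                kind = "annotated"
            elif kind == "alt5" and d5 is None:
                kind = "annotated"
            elif kind == "both" and (d5 is None or d3 is None):
                kind = "annotated"
    elif kind in ("novel_cds_inframe", "novel_cds_frameshift"):
        hi = len(coding) - 60
        L = sample_intron_length(rng, config, lo=60, hi=min(200, hi - 24))
        if kind == "novel_cds_inframe":
            L -= L % 3
        elif L % 3 == 0:
            L += 1
        placed = False
        offsets = list(range(24, len(coding) - 24 - L))
        rng.shuffle(offsets)
        for o in offsets:
            trial = list(coding)
            window = _make_intron(rng, L)
            sets = {o + i: window[i] for i in range(L)}
            if trial[o - 1] == "G" or trial[o + L] == "G":
                continue
            if not _apply_codon_safe(trial, sets):
                continue
            # spliced product must not gain a stop at the new junction
            spliced = trial[:o] + trial[o + L :]
            junction_ok = True
            if L % 3 == 0:
                for c0 in range((max(o - 3, 0) // 3) * 3, o + 3, 3):
                    if (
                        c0 + 3 <= len(spliced)
                        and "".join(spliced[c0 : c0 + 3]) in _STOPS
                    ):
                        junction_ok = False
            if not junction_ok:
                continue
            coding = trial
            placed = True
            break
        if not placed:
            kind = "annotated"  # extremely unlikely fallback
            L = sample_intron_length(rng, config)
            intron = _make_intron(rng, L)
            o_a = _pick_insertion_offset(rng, coding, 21, len(coding) - 45)
        else:
            if L % 3 != 0:
                # guarantee the frame-shifted product terminates in the trailer
                spliced = coding[:o] + coding[o + L :]
                prot, found = _translate_to_stop("".join(spliced))
                if not found:
                    phase = len(spliced) % 3
                    _ensure_stop(trailer, (3 - phase) % 3)
    elif kind == "utr5":
        L = sample_intron_length(rng, config, lo=60, hi=config.utr_length - 40)
        u = int(rng.integers(20, config.utr_length - L - 20))
        window = _make_intron(rng, L)
        utr[u : u + L] = window
        slippery = rng.random() < config.repeat_prob
        if slippery:
            utr[u - 1] = "G"  # equals the acceptor's G: one leftward placement
            if utr[u - 2] == "A":
                utr[u - 2] = "C"
            utr[u + L] = "G"  # equals the donor's G: one rightward placement
            if utr[u + L + 1] == "T":
                utr[u + L + 1] = "C"
            slack = 2
        else:
            if utr[u - 1] == "G":
                utr[u - 1] = "C"
            if utr[u + L] == "G":
                utr[u + L] = "C"
            slack = 0
    elif kind in ("terminal", "fusion_terminal"):
        delta = int(rng.integers(4, 7)) * 3  # CDS bases spliced out before the stop
        L = int(rng.integers(delta + 36, delta + 70))
        tau = L - delta - 3  # intronic bases inside the trailer
        o_t = len(coding) - 3 - delta
        # o_t is codon-aligned (delta multiple of 3), so GT? is never a stop
        _apply_codon_safe(coding, {o_t: "G", o_t + 1: "T"})
        if coding[o_t - 1] == "G":
            _apply_codon_safe(coding, {o_t - 1: "C"})
        trailer[tau - 2 : tau] = list("AG")
        trailer[tau - 27 : tau - 20] = list("TACTAAC")
        if trailer[tau] == "G":
            trailer[tau] = "C"
        phase = o_t % 3
        junction_fill = (3 - phase) % 3
        if kind == "terminal":
            _ensure_stop(trailer, tau + junction_fill)
        else:
            # partner gene downstream, entered in frame by the extension
            gap = 21 + junction_fill  # bases between intron end and partner ATG
            partner_codons = int(rng.integers(40, 60))
            partner = list("ATG") + _rand_codons(rng, partner_codons) + list("TAA")
            head = trailer[: tau + gap]
            _clear_stops(head, tau + junction_fill, len(head))
            if phase != 0:
                junction = coding[o_t - phase : o_t] + head[tau : tau + junction_fill]
                if "".join(junction) in _STOPS:
                    head[tau] = "C"
            trailer = head + partner + _rand_bases(rng, 120)
            partner_cds = (tau + gap, tau + gap + len(partner))  # offsets in trailer
            partner_protein, _ = _translate_to_stop("".join(partner))

    # assemble cassette (1-based coordinates)
    coding_with_introns = list(coding)
    if o_a is not None:
        coding_with_introns = coding[:o_a] + intron + coding[o_a:]
        annot_introns_local.append((o_a, o_a + len(intron)))  # 0-based [s, e)

    parts = [pad5, utr, coding_with_introns, trailer, pad3]
    offsets = []
    pos = 0
    for part in parts:
        offsets.append(pos)
        pos += len(part)
    seq = "".join("".join(p) for p in parts)
    utr_off, cds_off, trailer_off = offsets[1], offsets[2], offsets[3]

    def cass(a0: int, b0: int) -> tuple[int, int]:
        """0-based [a0, b0) to 1-based inclusive cassette coordinates."""
        return a0 + 1, b0

    cds_start0 = cds_off
    cds_end0 = cds_off + len(coding_with_introns)
    transcript = cass(utr_off, cds_end0)
    cds = cass(cds_start0, cds_end0)
    annot = [cass(cds_off + s, cds_off + e) for s, e in annot_introns_local]

    # expected proteins (composed independently of the analysis pipeline)
    protein_ori, _ = _translate_to_stop("".join(coding))

    support_major = config.major_support
    support_minor = config.minor_support

    if kind in ANNOTATED_KINDS:
        a_s, a_e = annot[0]
        plants.append(
            _PlantSpec(
                a_s,
                a_e,
                "annotated",
                support_major,
                "annotated",
                region="CDS",
                frame_basis=len(intron),
            )
        )
        if kind in ("alt3", "alt5", "both"):
            L = len(intron)
            alt_s, alt_e = a_s, a_e
            if d5 is not None:
                alt_s = a_s - d5 if d5 > 0 else a_s + (-d5)
            if d3 is not None:
                alt_e = a_e + d3
            var_coding = _alt_spliced(coding, intron, o_a, d5, d3)
            protein_var, found = _translate_to_stop(
                "".join(var_coding) + "".join(trailer)
            )
            if not found:
                phase = len(var_coding) % 3
                _ensure_stop(trailer, (3 - phase) % 3)
                seq = _reassemble(parts, trailer, 3)
                protein_var, _ = _translate_to_stop(
                    "".join(var_coding) + "".join(trailer)
                )
            premature_var = (
                len(protein_var) < len(protein_ori)
                and ((d3 or 0) + (d5 or 0)) % 3 != 0
            )
            basis = abs(d3 or 0) + abs(d5 or 0)
            cls = {"alt3": "alt3", "alt5": "alt5", "both": "both"}[kind]
            plants.append(
                _PlantSpec(
                    alt_s,
                    alt_e,
                    kind,
                    support_minor,
                    cls,
                    distance_3p=d3,
                    distance_5p=d5,
                    region="CDS",
                    frame_basis=basis,
                )
            )
    elif kind in ("novel_cds_inframe", "novel_cds_frameshift"):
        n_s, n_e = cass(cds_off + o, cds_off + o + L)
        spliced = coding[:o] + coding[o + L :]
        protein_var, _ = _translate_to_stop("".join(spliced) + "".join(trailer))
        premature_var = L % 3 != 0 and len(protein_var) < len(protein_ori)
        plants.append(
            _PlantSpec(
                n_s,
                n_e,
                kind,
                support_minor,
                "single",
                region="CDS",
                frame_basis=L,
            )
        )
    elif kind == "utr5":
        u_s, u_e = cass(utr_off + u, utr_off + u + L)
        protein_var = protein_ori
        plants.append(
            _PlantSpec(
                u_s,
                u_e,
                "utr5",
                support_major,
                "single",
                expected_slack=slack,
                region="5'UTR",
                frame_basis=L,
            )
        )
    elif kind in ("terminal", "fusion_terminal"):
        t_s = cass(cds_off + o_t, cds_off + o_t)[0]
        t_e = trailer_off + tau  # 1-based end: trailer[0..tau) intronic
        spliced_var = "".join(coding[:o_t]) + "".join(trailer[tau:])
        protein_var, _ = _translate_to_stop(spliced_var)
        premature_var = False
        plants.append(
            _PlantSpec(
                t_s,
                t_e,
                kind,
                support_major,
                "single",
                region="terminal",
                frame_basis=None,
            )
        )
        if partner_cds is not None:
            partner_cds = (
                trailer_off + partner_cds[0] + 1,
                trailer_off + partner_cds[1],
            )

    seq = "".join("".join(p) for p in parts)  # parts lists may have been mutated
    gene_span = transcript
    return _Cassette(
        kind=kind,
        seq=seq,
        gene=gene_span,
        transcript=transcript,
        cds=cds,
        annot_introns=annot,
        plants=plants,
        protein_ori=protein_ori,
        protein_var=protein_var,
        premature_stop_var=premature_var,
        boundary_mult=boundary_mult,
        partner_cds=partner_cds,
        partner_protein=partner_protein,
    )


def _alt_spliced(
    coding: list[str],
    intron: list[str],
    o_a: int,
    d5: int | None,
    d3: int | None,
) -> list[str]:
    """Coding sequence spliced with the alternative (minor) junction."""
    L = len(intron)
    left = list(coding[:o_a])
    right = list(coding[o_a:])
    if d5 is not None:
        if d5 > 0:
            left = left[:-d5]
        else:
            left = left + intron[: -d5]
    if d3 is not None:
        if d3 > 0:
            right = right[d3:]
        else:
            right = intron[L + d3 :] + right
    return left + right


def _reassemble(parts: list[list[str]], new_part: list[str], index: int) -> str:
    parts[index] = new_part
    return "".join("".join(p) for p in parts)


# ---------------------------------------------------------------------------
# read planning
# ---------------------------------------------------------------------------


def _junction_read_plan(
    gene_id: str,
    tag: str,
    chrom: str,
    gs: int,
    ge: int,
    support: int,
    config: SimulationConfig,
) -> tuple[list[PlannedRead], int]:
    rl, ma = config.read_length, config.min_anchor
    if support == 1:
        anchors = [rl // 2]
    else:
        anchors = [ma + (k * (rl - 2 * ma)) // (support - 1) for k in range(support)]
        if support >= 4:
            anchors[1] = anchors[0]  # a duplicated fragment, as real libraries show
    glen = ge - gs + 1
    reads = []
    for i, a in enumerate(anchors):
        reads.append(
            PlannedRead(
                read_id=f"{gene_id}|{tag}|sr{i}",
                chrom=chrom,
                pos=gs - a,
                cigar=f"{a}M{glen}N{rl - a}M",
                blocks=((gs - a, gs - 1), (ge + 1, ge + rl - a)),
            )
        )
    return reads, len(set(anchors))


def _boundary_read_plan(
    gene_id: str,
    tag: str,
    chrom: str,
    gs: int,
    ge: int,
    count: int,
    config: SimulationConfig,
) -> list[PlannedRead]:
    rl = config.read_length
    offs = [20 + (k * 60) // max(count - 1, 1) for k in range(count)]
    reads = []
    for i, off in enumerate(offs):
        for side, anchor_pos in (("u5", gs), ("u3", ge)):
            start = anchor_pos - off
            reads.append(
                PlannedRead(
                    read_id=f"{gene_id}|{tag}|{side}_{i}",
                    chrom=chrom,
                    pos=start,
                    cigar=f"{rl}M",
                    blocks=((start, start + rl - 1),),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# genome assembly and public API
# ---------------------------------------------------------------------------


def _map_interval(
    cass_start: int, cass_end: int, offset: int, cassette_len: int, strand: str
) -> tuple[int, int]:
    """Cassette (1-based) to genomic coordinates; minus strand mirrors."""
    if strand == "-":
        return (
            offset + cassette_len - cass_end + 1,
            offset + cassette_len - cass_start + 1,
        )
    return offset + cass_start, offset + cass_end


def build_simulation(config: SimulationConfig) -> SyntheticTruth:
    """Compose genome, annotation and read plan with complete ground truth."""
    rng = np.random.default_rng(config.seed)
    kinds_all = sorted(config.event_mix)
    probs = np.array([config.event_mix[k] for k in kinds_all])
    kinds = [kinds_all[i] for i in rng.choice(len(kinds_all), config.n_genes, p=probs)]
    if config.ensure_all_kinds and config.n_genes >= len(kinds_all):
        present = set(kinds)
        missing = [k for k in kinds_all if config.event_mix[k] > 0 and k not in present]
        for m in missing:
            counts = pd.Series(kinds).value_counts()
            kinds[kinds.index(counts.idxmax())] = m
            # recompute on next loop iteration via updated kinds
    if not any(k in ANNOTATED_KINDS for k in kinds):
        kinds[0] = "annotated"

    chrom_names = [f"syn{_roman(i + 1)}" for i in range(config.n_chromosomes)]
    chrom_parts: dict[str, list[str]] = {c: ["".join(_rand_bases(rng, 100))] for c in chrom_names}
    chrom_len: dict[str, int] = {c: 100 for c in chrom_names}

    genes: list[PlantedGene] = []
    junctions: dict[tuple[str, int, int], PlantedIntron] = {}
    reads: list[PlannedRead] = []
    gff_rows: list[str] = []

    for i, kind in enumerate(kinds):
        cassette = _build_cassette(rng, config, kind, i)
        kind = cassette.kind
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = chrom_names[i % config.n_chromosomes]
        linker = "".join(_rand_bases(rng, 50))
        chrom_parts[chrom].append(linker)
        chrom_len[chrom] += len(linker)
        offset = chrom_len[chrom]
        placed = cassette.seq if strand == "+" else reverse_complement(cassette.seq)
        chrom_parts[chrom].append(placed)
        chrom_len[chrom] += len(cassette.seq)
        Lc = len(cassette.seq)

        def gmap(se: tuple[int, int]) -> GenomicInterval:
            s, e = _map_interval(se[0], se[1], offset, Lc, strand)
            return GenomicInterval(chrom, s, e, strand)

        gene_id = f"SYNG{i:04d}"
        gene_span = gmap(cassette.gene)
        transcript_span = gmap(cassette.transcript)
        cds_span = gmap(cassette.cds)
        annot_ivs = sorted(
            (gmap(se) for se in cassette.annot_introns), key=lambda iv: iv.start
        )

        planted: list[PlantedIntron] = []
        for spec in cassette.plants:
            iv = gmap((spec.start, spec.end))
            tag = spec.kind
            jreads, n_frag = _junction_read_plan(
                gene_id, tag, chrom, iv.start, iv.end, spec.support, config
            )
            reads.extend(jreads)
            boundary_n = config.unspliced_reads * cassette.boundary_mult
            if boundary_n > 0 and spec.kind == "annotated":
                reads.extend(
                    _boundary_read_plan(
                        gene_id, tag, chrom, iv.start, iv.end, boundary_n, config
                    )
                )
            pi = PlantedIntron(
                interval=iv,
                kind=spec.kind,
                support=spec.support,
                fragments=n_frag,
                expected_class=spec.expected_class,
                distance_3p=spec.distance_3p,
                distance_5p=spec.distance_5p,
                expected_slack=spec.expected_slack,
                region=spec.region,
                frame_basis=spec.frame_basis,
                gene_id=gene_id,
            )
            planted.append(pi)
            junctions[iv.key] = pi

        fusion_partner = None
        if cassette.partner_cds is not None:
            partner_id = f"{gene_id}P"
            fusion_partner = partner_id
            partner_span = gmap(cassette.partner_cds)
            gff_rows.extend(
                _gff_gene_rows(partner_id, partner_span, [partner_span], [])
            )
            genes.append(
                PlantedGene(
                    gene_id=partner_id,
                    kind="partner",
                    chrom=chrom,
                    strand=strand,
                    gene_span=partner_span,
                    transcript_span=partner_span,
                    cds_span=partner_span,
                    annotated_introns=[],
                    planted=[],
                    protein_ori=cassette.partner_protein or "",
                    protein_var=None,
                    premature_stop_var=None,
                    fusion_partner=None,
                )
            )

        genes.append(
            PlantedGene(
                gene_id=gene_id,
                kind=kind,
                chrom=chrom,
                strand=strand,
                gene_span=gene_span,
                transcript_span=transcript_span,
                cds_span=cds_span,
                annotated_introns=annot_ivs,
                planted=planted,
                protein_ori=cassette.protein_ori,
                protein_var=cassette.protein_var,
                premature_stop_var=cassette.premature_stop_var,
                fusion_partner=fusion_partner,
            )
        )
        exons = _complement_within(transcript_span, annot_ivs)
        cds_segments = _complement_within(cds_span, annot_ivs)
        gff_rows.extend(
            _gff_gene_rows(gene_id, transcript_span, cds_segments, exons)
        )

    for chrom in chrom_names:
        tail = "".join(_rand_bases(rng, 100))
        chrom_parts[chrom].append(tail)
        chrom_len[chrom] += 100

    genome = GenomeSequence({c: "".join(chrom_parts[c]) for c in chrom_names})

    # anchors realized by the read plan
    anchor_map: dict[tuple[str, int, int], list[int]] = {}
    for read in reads:
        if len(read.blocks) < 2:
            continue
        for b1, b2 in zip(read.blocks, read.blocks[1:]):
            key = (read.chrom, b1[1] + 1, b2[0] - 1)
            left, right = b1[1] - b1[0] + 1, b2[1] - b2[0] + 1
            if key not in anchor_map:
                anchor_map[key] = [left, right]
            else:
                anchor_map[key][0] = max(anchor_map[key][0], left)
                anchor_map[key][1] = max(anchor_map[key][1], right)
    for key, pi in junctions.items():
        pi.anchor_left, pi.anchor_right = anchor_map[key]

    default = FilterConfig()
    expected_predicted = set()
    for key, pi in junctions.items():
        length = pi.interval.length
        if not (default.min_length <= length <= default.max_length):
            continue
        if pi.support < default.min_read_support:
            continue
        score_l = pi.anchor_left - pi.expected_slack
        score_r = pi.anchor_right - pi.expected_slack
        if (
            max(score_l, score_r) > default.quality_max_threshold
            and min(score_l, score_r) > default.quality_min_threshold
        ):
            expected_predicted.add(key)

    # retention evidence expected from the planned ungapped reads
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for read in reads:
        if len(read.blocks) == 1:
            spans_by_chrom.setdefault(read.chrom, []).append(read.blocks[0])
    retention: dict[tuple[str, int, int], tuple[int, int]] = {}
    ov = 8
    for key, pi in junctions.items():
        spans = spans_by_chrom.get(pi.interval.chrom, [])
        s, e = pi.interval.start, pi.interval.end
        five = sum(1 for a, b in spans if a <= s - 1 and b >= s + ov - 1)
        three = sum(1 for a, b in spans if a <= e - ov + 1 and b >= e + 1)
        retention[key] = (five, three)

    header = "##gff-version 3\n" + "".join(
        f"##sequence-region {c} 1 {genome.length(c)}\n" for c in chrom_names
    )
    gff_text = header + "".join(gff_rows)

    reads.sort(key=lambda r: (r.chrom, r.pos, r.read_id))
    return SyntheticTruth(
        config=config,
        genome=genome,
        genes=genes,
        junctions=junctions,
        expected_predicted=expected_predicted,
        retention_expected=retention,
        reads=reads,
        gff_text=gff_text,
    )


def _roman(n: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return numerals[n - 1] if n <= 10 else str(n)


def _complement_within(
    span: GenomicInterval, introns: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Span minus introns: the exonic segments, ascending."""
    segments = []
    cursor = span.start
    for intron in sorted(introns, key=lambda iv: iv.start):
        if intron.start > cursor:
            segments.append(
                GenomicInterval(span.chrom, cursor, intron.start - 1, span.strand)
            )
        cursor = intron.end + 1
    if cursor <= span.end:
        segments.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return segments


def _gff_gene_rows(
    gene_id: str,
    transcript_span: GenomicInterval,
    cds_segments: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval],
) -> list[str]:
    chrom, strand = transcript_span.chrom, transcript_span.strand
    src = "yeastsplice_sim"
    rows = [
        f"{chrom}\t{src}\tgene\t{transcript_span.start}\t{transcript_span.end}\t.\t{strand}\t.\tID={gene_id};Name={gene_id};gene_biotype=protein_coding\n",
        f"{chrom}\t{src}\tmRNA\t{transcript_span.start}\t{transcript_span.end}\t.\t{strand}\t.\tID={gene_id}_mRNA;Parent={gene_id}\n",
    ]
    if not exons:
        exons = list(cds_segments)
    for n, ex in enumerate(sorted(exons, key=lambda iv: iv.start)):
        rows.append(
            f"{chrom}\t{src}\texon\t{ex.start}\t{ex.end}\t.\t{strand}\t.\tID={gene_id}_exon{n};Parent={gene_id}_mRNA\n"
        )
    ordered = sorted(cds_segments, key=lambda iv: iv.start)
    if strand == "-":
        ordered = ordered[::-1]
    phase = 0
    phased = []
    for seg in ordered:
        phased.append((seg, phase))
        phase = (3 - ((seg.length - phase) % 3)) % 3
    for n, (seg, ph) in enumerate(phased):
        rows.append(
            f"{chrom}\t{src}\tCDS\t{seg.start}\t{seg.end}\t.\t{strand}\t{ph}\tID={gene_id}_cds{n};Parent={gene_id}_mRNA\n"
        )
    return rows


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome.names():
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_reference(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[Path, Path, SyntheticTruth]:
    """Write genome FASTA, annotation GFF3 and truth tables; return paths + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = build_simulation(config)
    fasta = out / "genome.fa"
    gff = out / "annotation.gff3"
    write_genome_fasta(truth.genome, fasta)
    gff.write_text(truth.gff_text)
    truth_frame(truth).to_csv(out / "truth_junctions.tsv", sep="\t", index=False)
    return fasta, gff, truth


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    rows = []
    for key, pi in sorted(truth.junctions.items()):
        rows.append(
            {
                "chrom": pi.interval.chrom,
                "strand": pi.interval.strand,
                "start": pi.interval.start,
                "end": pi.interval.end,
                "length": pi.interval.length,
                "kind": pi.kind,
                "support": pi.support,
                "fragments": pi.fragments,
                "expected_class": pi.expected_class,
                "distance_3p": pi.distance_3p,
                "distance_5p": pi.distance_5p,
                "expected_slack": pi.expected_slack,
                "region": pi.region,
                "gene": pi.gene_id,
                "expected_predicted": key in truth.expected_predicted,
            }
        )
    return pd.DataFrame(rows)


def _read_sequence(genome: GenomeSequence, read: PlannedRead) -> str:
    parts = [
        genome.subsequence(GenomicInterval(read.chrom, s, e)) for s, e in read.blocks
    ]
    return "".join(parts)


def simulate_alignments(
    truth: SyntheticTruth,
    out_path: str | Path,
    config: SimulationConfig | None = None,
) -> Path:
    """Emit the planned reads as a SAM file (primary, unique, exact CIGARs).

    Sequencing errors (uniform substitutions at ``error_rate``) are applied
    from an RNG stream derived from the config seed, so repeated calls are
    byte-identical.
    """
    config = config or truth.config
    out_path = Path(out_path)
    rng = np.random.default_rng([config.seed, 9973])
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": truth.genome.length(name)}
            for name in truth.genome.names()
        ],
    }
    with pysam.AlignmentFile(str(out_path), "w", header=header) as sam:
        for read in truth.reads:
            seq = _read_sequence(truth.genome, read)
            if config.error_rate > 0:
                chars = list(seq)
                for i in range(len(chars)):
                    if rng.random() < config.error_rate:
                        chars[i] = str(_BASES[rng.integers(0, 4)])
                seq = "".join(chars)
            a = pysam.AlignedSegment(sam.header)
            a.query_name = read.read_id
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = sam.header.references.index(read.chrom)
            a.reference_start = read.pos - 1
            a.mapping_quality = 50
            a.cigarstring = read.cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("NH", 1)
            sam.write(a)
    return out_path


def write_fastq(truth: SyntheticTruth, out_path: str | Path) -> Path:
    """Escape hatch: emit the simulated reads as FASTQ for a real mapper."""
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for read in truth.reads:
            seq = _read_sequence(truth.genome, read)
            fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return out_path


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Full desk-scale dataset: FASTA + GFF3 + SAM + truth tables."""
    out = Path(out_dir)
    fasta, gff, truth = generate_reference(config, out)
    sam = simulate_alignments(truth, out / "alignments.sam", config)
    return {"fasta": fasta, "gff": gff, "sam": sam, "truth": out / "truth_junctions.tsv"}, truth
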