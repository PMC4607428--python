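# Methods

## Coordinates and strand conventions

All interfaces use 1-based, fully inclusive coordinates, so
`length = end − start + 1` holds for every interval and can be checked
directly against published intron tables.  The only 0-based, half-open
surface is the BED junction writer, converted at the writer boundary.
Minus-strand sequence requests return the reverse complement (the
transcribed sequence); a "5' splice site" on the minus strand is the
genomic *end* of the intron.  Alternative-site distances are signed in
transcribed space: positive when the variant intron extends past the
reference splice site, negative when it is shortened.  Junction identity
ignores alignment strand flags — RNA-seq libraries are commonly unstranded —
and the strand of a predicted intron is inferred from its splice signal
instead.

## Potential introns from split reads

A split read is any primary, uniquely mapped alignment whose CIGAR contains
≥ 1 skipped-region (`N`) operation.  Uniqueness uses the alignment flags
(secondary/supplementary records are dropped) plus the `NH` tag when
present (`NH > 1` dropped); primary records without an `NH` tag are
accepted, since no flag-level recipe is universal across mappers.  Each `N`
gap contributes one junction; reads with two or more junctions contribute
each junction independently, which keeps support counts conservative and
conserving (the sum of read support over junctions equals the number of
junction instances).  A *fragment* is the set of reads with identical
chromosome and block layout — PCR or optical duplicates of one cDNA
fragment — counted once in fragment support.  Per-side *anchors* are the
maxima over supporting reads of the contiguous aligned bases adjacent to
the junction.

Retention evidence counts ungapped reads whose aligned span covers the last
exonic base plus the first `min_overhang` intronic bases of each splice
site (default `min_overhang = 8`, chosen to exclude dubious one-base
overlaps).

## The filter cascade

Stages run in a fixed order — long (> 1002 bases), short (< 40), signal,
support (< 3 reads), quality — and each candidate is removed at the first
failing stage, so per-stage tallies are well defined and conserved (stage
counts plus survivors equal the input, for introns and for their reads).

The valid splice-signal set is extracted at run time from the annotation:
the distinct (donor, acceptor) dinucleotide pairs observed at annotated
nuclear, non-tRNA/snoRNA introns read on the transcribed strand.  Both
orientations of a candidate junction are tested; the matching orientation
infers the strand, with "+" preferred on the (practically impossible,
given canonical signal sets) tie.

Junction-placement slack *n* counts the alternative placements
*j ∈ [−10, +10], j ≠ 0* for which shifting the whole intron by *j* bases
leaves the spliced exon-flank concatenation unchanged.  Shift validity is
nested (shift +j requires +1…+(j−1)), so slack is computed by extending
base-equality runs on both sides; the search truncates at chromosome ends.
The per-side junction quality is `anchor − n`; survivors need
`max > 85` and `min > 25`, both strictly — a junction scoring exactly
(85, 25) fails.  Thresholds are configurable (`FilterConfig`); the defaults
above are the study conditions this package reproduces.

## Grouping and AS classes

Predicted introns overlapping by ≥ 1 base on the same chromosome and
inferred strand form groups (connected components; bookended introns are
not grouped).  The group reference is the member with the highest read
support, ties broken by shorter length, then leftmost start.  When a group
contains an intron exactly matching the annotation, that member is the
*comparison* reference for alternative-site distances — distances are
measured to the canonical splice site — while the `reference` class label
still goes to the max-support member.  Classes: `annotated` (exact
annotation match), `single` (isolated novel intron, no AS evidence),
`reference`, `alt3`, `alt5`, `both`.

Gene-region calls give precedence to `terminal` (the interval contains a
gene's complete stop codon) so a terminal intron running toward a
downstream gene is not demoted to `multiple`.  Because yeast GFFs rarely
delimit UTRs, the 5'UTR search region is the annotated transcript extent
upstream of the CDS when present, otherwise a configurable window
(default 300 bases) upstream of the CDS start.  Mitochondrial chromosomes
(configurable name list: chrmt/chrM/Mito/chrMito/MT) and tRNA/snoRNA genes
are excluded from signal extraction, as organellar and tRNA splicing follow
different mechanisms.

## Isoform consequences

The frame rule is mod-3 on the intron length (novel introns) or the signed
alternative-site distance sum (alt-site events); it applies only in the
CDS — for 5'UTR, intergenic and terminal events (where the stop codon
itself is removed) the reading frame is not applicable.

Translation always starts at the annotated start codon with the standard
nuclear genetic code (no start re-scanning).  ORI uses the annotated splice
pattern; VAR substitutes the predicted intron for an overlapping annotated
intron or splices it in addition.  If VAR removes the annotated stop,
translation extends into downstream genomic sequence up to a bounded search
(default 5 kb) for the next in-frame stop; records exceeding the bound are
flagged rather than scanned chromosome-wide.  A gene fusion is reported
when a codon start of the extended reading frame coincides with a codon
start of a downstream same-strand gene's own annotated frame; mere
extension into intergenic sequence is an alternative C-terminus.
Transcript ORI/VAR sequences are reported over the hull of the gene span
and the event, so `length_delta = −(intron length)` holds for newly spliced
introns, including terminal ones.  Protein deltas use a longest common
prefix/suffix decomposition.  Note that a frame-preserving event can still
truncate the protein when retained intronic bases encode an in-frame stop;
the `premature_stop` flag is computed from the realized stop position, not
from the frame rule.

## Cross-dataset validation

Validation requires an exact junction-coordinate match in the second
dataset (no ± slack window — ambiguous junctions were already removed by
the quality filter) and ≥ 1 supporting read by default.  Support
correlation per AS class uses `log1p`-scaled read counts and the
product-moment coefficient; classes with < 3 records are skipped and
zero-variance classes are reported as undefined.  Reads are pooled across
conditions/replicates by default.

## Synthetic data: what it emulates and what it does not

The generator composes one cassette per gene in transcribed space — random
pad, 200-base 5'UTR, an ORF of 70–110 random non-stop codons, a 400-base
trailer — and reverse-complements whole cassettes into the chromosome for
minus-strand genes, so all motif surgery is strand-agnostic.  Planted
introns draw from a two-component normal length mixture (means 100 and 400,
SDs 15 and 50, 60% short, clipped to [60, 1000]) mirroring the bimodal
yeast intron length distribution, and carry GTATGT…TACTAAC…AG motifs (the
branch point 20–27 bases upstream of the acceptor).  Event kinds per gene
(annotated-only, retention, alt3, alt5, both, novel CDS in-frame/
frameshift, 5'UTR, terminal, terminal-with-fusion) are drawn from a
configurable mixture; by default every kind is guaranteed at least once.
Alternative sites are planted by placing AG/GT dinucleotides inside the
intron (shortening) or, codon-safely, in the flanking exon (extension);
all surgeries verify that no in-frame stop is created in the annotated ORF
and that frame-shifted variant products terminate within the trailer.
Junction-flank bases are controlled so planted junctions have zero
placement slack, except deliberate repeat-context junctions (planted at
5'UTR introns, where flanks are freely mutable without ORF constraints)
with slack exactly 2.

Alignments are emitted directly with exact CIGARs — no mapper runs — with
anchor offsets tiled evenly over [10, 90] so maximal anchors are 90 per
side, one deliberate duplicate fragment per junction with support ≥ 4, and
ungapped boundary reads for the unspliced isoform (default 6 per boundary;
3× for retention genes).  Default supports are 30 reads for the major
spliced isoform and 8 for minor isoforms.  Everything is deterministic
given the seed; a `write_fastq` escape hatch exists for users who want to
exercise a real mapper.  The simulation does **not** model sequencing-error
realism (only uniform substitutions, default 0), quality scores,
paired-end fragments, coverage variability, multi-mapping reads, or
annotation errors — so passing tests demonstrate the correctness of the
pipeline's logic on idealized alignments, not robustness to mapper
artifacts on real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run a 50-gene, ~80 kb, ~2,000-read
simulation (a scale at which the planted truth is exhaustively checkable)
plus 1,000 random junctions for the slack oracle; these sizes were chosen
so every planted event can be verified individually.  Tie-breaks
(reference selection, "+"-strand signal preference), strict threshold
inequalities, and degenerate inputs (empty alignment sets, zero-variance
correlations, truncated slack windows at chromosome ends) are fixed as
described above and exercised in the test suite.

## Known limitations

Exon-skipping / cassette-exon detection is out of scope (single-intron
gene structure), as are read mapping itself, NMD modeling, and uORF
analysis for 5'UTR introns.  Genome-scale annotated counts (e.g. how many
introns a given reference release contains) depend on external downloads
and are treated as documentation examples, not tests.
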