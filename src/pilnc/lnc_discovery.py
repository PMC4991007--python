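"""Novel lncRNA discovery: the three-filter cascade and position classes.

A newly assembled transcript is retained as a novel lncRNA only if it

1. shares no exonic nucleotide with an annotated coding-transcript exon or
   an annotated lncRNA exon on the same strand, nor with an annotated
   lncRNA exon on the antisense strand,
2. has spliced length >= 200 nt, and
3. shows no protein-coding potential (score <= 0).

Coding potential is judged by an ORF-coverage score: the longest forward
frame ATG..stop open reading frame divided by transcript length, minus a
threshold tau (default 0.35); externally computed scores can be supplied
instead.  Retained lncRNAs are then placed into exactly one genomic
position class — pseudogenic / TE-related, antisense, cis (within 500 nt of
a protein-coding gene) or intergenic — with that fixed priority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genomics_io import GenomicsIOError, TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

REMOVAL_OVERLAP = "overlap_annotation"
REMOVAL_SHORT = "short"
REMOVAL_CODING = "coding_potential"

POSITION_CLASSES = ("pseudogenic", "te_related", "antisense", "cis", "intergenic")


@dataclass
class FilterReport:
    """Per-stage accounting for the novel-lncRNA filter cascade."""

    n_input: int = 0
    n_removed_overlap: int = 0
    n_removed_short: int = 0
    n_removed_coding: int = 0
    n_retained: int = 0
    removal_reason: dict[str, str] = field(default_factory=dict)

    def check_conservation(self) -> None:
        total = (
            self.n_removed_overlap
            + self.n_removed_short
            + self.n_removed_coding
            + self.n_retained
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter report does not conserve transcripts: {total} != {self.n_input}"
            )


def longest_orf(seq: str) -> int:
    """Length in nt of the longest ATG..stop ORF over the 3 forward frames.

    The length includes the stop codon; ORFs lacking an in-frame stop do not
    count.  Returns 0 when no ORF exists.
    """
    if not seq:
        raise GenomicsIOError("empty sequence")
    seq = seq.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def coding_potential_surrogate(seq: str, tau: float = 0.35) -> float:
    """ORF-coverage coding score: longest forward ORF / length - tau.

    Positive scores call the transcript coding.  The spliced, strand-oriented
    sequence is scanned in the 3 forward frames only.
    """
    if not seq:
        raise GenomicsIOError("empty sequence")
    return longest_orf(seq) / len(seq) - tau


def _exon_trees(
    transcripts: Iterable[TranscriptModel], biotypes: set[str]
) -> dict[tuple[str, str], IntervalTree]:
    """Exon interval trees keyed by (chrom, strand) for the given biotypes."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        if t.biotype not in biotypes:
            continue
        for e in t.exons:
            trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(e.start, e.end)
    return trees


def _hits(trees: dict[tuple[str, str], IntervalTree], t: TranscriptModel, strand: str) -> bool:
    tree = trees.get((t.chrom, strand))
    if tree is None:
        return False
    return any(tree.overlap(e.start, e.end) for e in t.exons)


def filter_novel_lncrnas(
    candidates: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    min_len: int = 200,
    coding_scores: Mapping[str, float] | None = None,
    tau: float = 0.35,
) -> tuple[list[TranscriptModel], FilterReport]:
    """Run the three-filter cascade, in order, over candidate transcripts.

    Filters: (1) exonic overlap with annotated coding or lncRNA exons
    (same-strand) or lncRNA exons (antisense); (2) spliced length < min_len;
    (3) coding score > 0 (``coding_scores`` if supplied, else the ORF
    surrogate on the spliced sequence).  Returns the retained transcripts,
    relabelled ``novel``, and a :class:`FilterReport`.
    """
    report = FilterReport(n_input=len(candidates))
    coding_trees = _exon_trees(annotation, {"protein_coding"})
    lnc_trees = _exon_trees(annotation, {"tair10_lncRNA"})

    retained: list[TranscriptModel] = []
    for t in candidates:
        antistrand = "-" if t.strand == "+" else "+"
        if (
            _hits(coding_trees, t, t.strand)
            or _hits(lnc_trees, t, t.strand)
            or _hits(lnc_trees, t, antistrand)
        ):
            report.n_removed_overlap += 1
            report.removal_reason[t.transcript_id] = REMOVAL_OVERLAP
            continue
        if t.length < min_len:
            report.n_removed_short += 1
            report.removal_reason[t.transcript_id] = REMOVAL_SHORT
            continue
        if coding_scores is not None and t.transcript_id in coding_scores:
            score = coding_scores[t.transcript_id]
        else:
            score = coding_potential_surrogate(t.spliced_sequence(genome), tau=tau)
        if score > 0:
            report.n_removed_coding += 1
            report.removal_reason[t.transcript_id] = REMOVAL_CODING
            continue
        retained.append(t.with_biotype("novel"))
    report.n_retained = len(retained)
    report.check_conservation()
    return retained, report


# ---------------------------------------------------------------------------
# Genomic position classification
# ---------------------------------------------------------------------------


class _AnnotationIndex:
    """Span/exon indexes over an annotation, reusable across many queries."""

    def __init__(self, annotation: Sequence[TranscriptModel], antisense_exon_only: bool = False):
        self.antisense_exon_only = antisense_exon_only
        self.pseudo_te: dict[str, IntervalTree] = {}
        self.coding_span: dict[tuple[str, str], IntervalTree] = {}
        self.coding_exon: dict[tuple[str, str], IntervalTree] = {}
        self.coding_bounds: dict[str, list[tuple[int, int]]] = {}
        for t in annotation:
            if t.biotype in ("pseudogene", "TE_related"):
                self.pseudo_te.setdefault(t.chrom, IntervalTree()).addi(
                    t.start, t.end, t.biotype
                )
            elif t.biotype == "protein_coding":
                key = (t.chrom, t.strand)
                self.coding_span.setdefault(key, IntervalTree()).addi(t.start, t.end)
                for e in t.exons:
                    self.coding_exon.setdefault(key, IntervalTree()).addi(e.start, e.end)
                self.coding_bounds.setdefault(t.chrom, []).append((t.start, t.end))


def classify_position(
    lncrna: TranscriptModel,
    annotation: Sequence[TranscriptModel] | _AnnotationIndex,
    cis_max_dist: int = 500,
    antisense_exon_only: bool = False,
) -> str:
    """Assign exactly one genomic position class to an lncRNA.

    Priority: pseudogenic/te_related (>=1 nt overlap, either strand) >
    antisense (exon overlaps a protein-coding transcript on the opposite
    strand; the coding side is taken intron-inclusive by default) > cis
    (closest protein-coding gene boundary <= ``cis_max_dist`` nt,
    strand-agnostic) > intergenic.
    """
    idx = (
        annotation
        if isinstance(annotation, _AnnotationIndex)
        else _AnnotationIndex(annotation, antisense_exon_only)
    )
    # pseudogene / TE overlap on either strand, transcript span
    tree = idx.pseudo_te.get(lncrna.chrom)
    if tree is not None:
        hits = tree.overlap(lncrna.start, lncrna.end)
        if hits:
            # deterministic: pseudogene outranks TE when both overlap
            kinds = {h.data for h in hits}
            return "pseudogenic" if "pseudogene" in kinds else "te_related"
    antistrand = "-" if lncrna.strand == "+" else "+"
    coding = idx.coding_exon if (antisense_exon_only or idx.antisense_exon_only) else idx.coding_span
    anti = coding.get((lncrna.chrom, antistrand))
    if anti is not None and any(anti.overlap(e.start, e.end) for e in lncrna.exons):
        return "antisense"
    # distance to the nearest protein-coding gene boundary (either strand)
    best = None
    for s, e in idx.coding_bounds.get(lncrna.chrom, []):
        if s < lncrna.end and lncrna.start < e:
            d = 0
        elif e <= lncrna.start:
            d = lncrna.start - e
        else:
            d = s - lncrna.end
        best = d if best is None else min(best, d)
    if best is not None and best <= cis_max_dist:
        return "cis"
    return "intergenic"


def classify_positions(
    lncrnas: Sequence[TranscriptModel],
    annotation: Sequence[TranscriptModel],
    cis_max_dist: int = 500,
    antisense_exon_only: bool = False,
) -> dict[str, str]:
    """Classify many lncRNAs against one annotation (shared index)."""
    idx = _AnnotationIndex(annotation, antisense_exon_only)
    return {
        t.transcript_id: classify_position(t, idx, cis_max_dist, antisense_exon_only)
        for t in lncrnas
    }
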