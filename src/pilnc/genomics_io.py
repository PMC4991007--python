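"""Core genomic data model and text-format I/O.

Everything downstream of assembly works on three containers: stranded
multi-exon :class:`TranscriptModel` objects, a transcripts-by-libraries
:class:`ExpressionMatrix` with the 2 tissues x 2 Pi conditions x 2 poly(A)
fractions x 2 replicates design encoded in :class:`LibraryMeta`, and a
piecewise-constant :class:`BedGraphSignal` for chromatin accessibility.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
format's 1-based inclusive convention.  FASTA is uppercased on read and
wrapped at 60 columns on write.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

STRANDS = ("+", "-")

BIOTYPES = (
    "protein_coding",
    "tair10_lncRNA",
    "canonical_ncRNA",
    "pseudogene",
    "TE_related",
    "novel",
)

TISSUES = ("root", "shoot")
CONDITIONS = ("P_plus", "P_minus")
POLYA_FRACTIONS = ("PA", "NPA")  # poly(A)+ selected / poly(A)- (ribo-depleted)

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, case preserved as upper)."""
    return seq.upper().translate(COMPLEMENT)[::-1]


class GenomicsIOError(ValueError):
    """Raised on malformed input files or inconsistent genomic objects."""


# ---------------------------------------------------------------------------
# Interval / transcript model
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval, 0-based half-open: [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise GenomicsIOError(f"negative start {self.start}")
        if self.end <= self.start:
            raise GenomicsIOError(f"empty/inverted interval [{self.start},{self.end})")
        if self.strand not in STRANDS:
            raise GenomicsIOError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript with a biotype label.

    Exons are sorted, disjoint, and share chrom/strand; these invariants are
    enforced at construction because every overlap/classification rule
    downstream assumes them.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "novel"

    def __post_init__(self) -> None:
        if not self.exons:
            raise GenomicsIOError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.biotype not in BIOTYPES:
            raise GenomicsIOError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise GenomicsIOError(f"{self.transcript_id}: exons span chrom/strand")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise GenomicsIOError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the transcript span."""
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        """First-exon-start to last-exon-end, intron inclusive."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths (nt)."""
        return sum(len(e) for e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Strand-oriented spliced transcript sequence (5'->3')."""
        if self.chrom not in genome:
            raise GenomicsIOError(f"{self.transcript_id}: chrom {self.chrom!r} absent from genome")
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[e.start : e.end] for e in self.exons).upper()
        return seq if self.strand == "+" else revcomp(seq)

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return replace(self, biotype=biotype)


# ---------------------------------------------------------------------------
# Library metadata / expression matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibraryMeta:
    """One strand-specific RNA-seq library of the 2x2x2x2 design."""

    library_id: str
    tissue: str
    condition: str
    polya: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise GenomicsIOError(f"tissue must be in {TISSUES}, got {self.tissue!r}")
        if self.condition not in CONDITIONS:
            raise GenomicsIOError(f"condition must be in {CONDITIONS}, got {self.condition!r}")
        if self.polya not in POLYA_FRACTIONS:
            raise GenomicsIOError(f"polya must be in {POLYA_FRACTIONS}, got {self.polya!r}")


def full_design(n_replicates: int = 2) -> list[LibraryMeta]:
    """Enumerate the 16-library design (2 tissues x 2 conditions x PA/NPA x reps)."""
    libs = []
    for tissue in TISSUES:
        for condition in CONDITIONS:
            for polya in POLYA_FRACTIONS:
                for rep in range(1, n_replicates + 1):
                    lid = f"{tissue}_{condition}_{polya}_r{rep}"
                    libs.append(LibraryMeta(lid, tissue, condition, polya, rep))
    return libs


class ExpressionMatrix:
    """Transcripts x libraries matrix of counts or RPKM with library metadata."""

    def __init__(
        self,
        values: pd.DataFrame,
        libraries: Sequence[LibraryMeta],
        total_mapped_reads: Mapping[str, float] | None = None,
    ) -> None:
        lib_ids = [l.library_id for l in libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise GenomicsIOError("duplicate library ids")
        missing = set(values.columns) - set(lib_ids)
        if missing:
            raise GenomicsIOError(f"libraries absent from metadata: {sorted(missing)}")
        if set(lib_ids) != set(values.columns):
            raise GenomicsIOError("metadata lists libraries absent from the matrix")
        if values.isna().any().any():
            raise GenomicsIOError("missing values in expression matrix")
        if (values.to_numpy() < 0).any():
            raise GenomicsIOError("negative expression values")
        # align column order to metadata order
        self.values = values.loc[:, lib_ids].astype(float)
        self.libraries = list(libraries)
        self._by_id = {l.library_id: l for l in libraries}
        if total_mapped_reads is not None:
            bad = set(lib_ids) ^ set(total_mapped_reads)
            if bad:
                raise GenomicsIOError(f"total_mapped_reads keys mismatch: {sorted(bad)}")
            if any(v <= 0 for v in total_mapped_reads.values()):
                raise GenomicsIOError("total_mapped_reads must be positive")
        self.total_mapped_reads = dict(total_mapped_reads) if total_mapped_reads else None

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def meta(self, library_id: str) -> LibraryMeta:
        return self._by_id[library_id]

    def select_libraries(self, **factors) -> list[str]:
        """Library ids matching all given design factors (tissue=, condition=, polya=)."""
        out = []
        for lib in self.libraries:
            if all(getattr(lib, k) == v for k, v in factors.items()):
                out.append(lib.library_id)
        return out


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"\s*;')
_GFF3_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(attr: str, lineno: int) -> dict[str, str]:
    if "=" in attr and '"' not in attr:  # GFF3 style
        pairs = dict(_GFF3_ATTR_RE.findall(attr))
        if not pairs:
            raise GenomicsIOError(f"line {lineno}: malformed attribute string: {attr!r}")
        # map GFF3 Parent/ID onto GTF-like keys
        if "Parent" in pairs and "transcript_id" not in pairs:
            pairs["transcript_id"] = pairs["Parent"]
        return pairs
    pairs = dict(_ATTR_RE.findall(attr))
    if not pairs:
        raise GenomicsIOError(f"line {lineno}: malformed attribute string: {attr!r}")
    return pairs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF2.2/GFF3 file into TranscriptModels.

    File coordinates (1-based inclusive) are converted to internal 0-based
    half-open.  Exons are grouped by transcript_id; gene_id defaults to the
    transcript id and biotype to ``novel`` when the attributes are absent.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomicsIOError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr, lineno)
            tid = attrs.get("transcript_id")
            if not tid:
                raise GenomicsIOError(f"line {lineno}: exon without transcript id")
            gid = attrs.get("gene_id", tid)
            biotype = attrs.get("biotype", "novel")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            exons.setdefault(tid, []).append(iv)
            meta[tid] = (gid, biotype)
    out = []
    for tid, ivs in exons.items():
        gid, biotype = meta[tid]
        out.append(TranscriptModel(tid, gid, tuple(ivs), biotype))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "pilnc") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attr = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}, id = first token of header."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise GenomicsIOError(f"duplicate FASTA id {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise GenomicsIOError("sequence before FASTA header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width].upper() + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


class BedGraphSignal:
    """Per-chromosome piecewise-constant signal; uncovered bases read as 0."""

    def __init__(self, records: Iterable[tuple[str, int, int, float]]) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start or start < 0:
                raise GenomicsIOError(f"bad bedGraph record {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end, float(value)))
        self._starts: dict[str, list[int]] = {}
        self._records: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, recs in per_chrom.items():
            recs.sort()
            for (s1, e1, _), (s2, _e2, _) in zip(recs, recs[1:]):
                if s2 < e1:
                    raise GenomicsIOError(f"overlapping bedGraph records on {chrom}")
            self._records[chrom] = recs
            self._starts[chrom] = [r[0] for r in recs]

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end); uncovered bases contribute 0."""
        if end <= start:
            raise GenomicsIOError(f"empty query [{start},{end})")
        recs = self._records.get(chrom)
        if not recs:
            return 0.0
        total = 0.0
        i = max(bisect_right(self._starts[chrom], start) - 1, 0)
        for s, e, v in recs[i:]:
            if s >= end:
                break
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                total += v * (hi - lo)
        return total / (end - start)


def read_bedgraph(path: str | Path) -> BedGraphSignal:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise GenomicsIOError(f"line {lineno}: bedGraph needs 4 columns")
            records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return BedGraphSignal(records)


def write_bedgraph(records: Iterable[tuple[str, int, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (rows transcripts, header library ids) plus a
    metadata TSV carrying the four design factors and total mapped reads."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"library_id", "tissue", "condition", "polya", "replicate"}
    if not required.issubset(meta.columns):
        raise GenomicsIOError(f"metadata must carry columns {sorted(required)}")
    libs = [
        LibraryMeta(r.library_id, r.tissue, r.condition, r.polya, int(r.replicate))
        for r in meta.itertuples()
    ]
    totals = None
    if "total_mapped_reads" in meta.columns:
        totals = dict(zip(meta["library_id"], meta["total_mapped_reads"].astype(float)))
    return ExpressionMatrix(values, libs, totals)


def write_expression(matrix: ExpressionMatrix, path: str | Path, meta_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="transcript_id")
    rows = []
    for lib in matrix.libraries:
        row = {
            "library_id": lib.library_id,
            "tissue": lib.tissue,
            "condition": lib.condition,
            "polya": lib.polya,
            "replicate": lib.replicate,
        }
        if matrix.total_mapped_reads:
            row["total_mapped_reads"] = matrix.total_mapped_reads[lib.library_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
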