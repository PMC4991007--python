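"""Seeded generator for a miniature Pi-starvation lncRNA study.

``simulate`` builds a self-consistent desk-scale dataset emulating the
study design the pipeline expects: a single synthetic chromosome carrying
protein-coding genes, annotated lncRNAs, pseudogenes and TE genes; novel
transcripts planted into known genomic position classes; negative-binomial
counts for the 16-library design (2 tissues x 2 Pi conditions x poly(A)+/-
x 2 replicates) with planted differential expression and poly(A)
partitioning; promoters carrying 0-4 planted P1BS words with a DNase
accessibility track over designated PHR1 targets; and miRNAs with planted
cleavage-target, target-mimic and shuffled-negative sites.  A
:class:`TruthManifest` records every planted label so downstream stages can
be scored exactly.

Two printed reference tables from the source study are also provided as
machine-readable fixtures: the miR399 target table (:func:`table2_fixture`)
and the per-stage transcript counts of the discovery filter cascade
(:func:`cascade_fixture`), the latter as a fully engineered synthetic
dataset whose cascade reproduces the printed stage totals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genomics_io import (
    ExpressionMatrix,
    GenomicsIOError,
    GenomicInterval,
    BedGraphSignal,
    LibraryMeta,
    TranscriptModel,
    full_design,
    revcomp,
    write_bedgraph,
    write_expression,
    write_fasta,
    write_gtf,
)

# Reference composition of the source study's assembly and DE catalogue;
# these printed totals are inputs to consistency checks, not measurements.
REFERENCE_ASSEMBLY_COMPOSITION = {
    "protein_coding": 31139,
    "tair10_lncRNA": 393,
    "canonical_ncRNA": 817,
    "pseudogene": 862,
    "TE_related": 3844,
    "new_assembled": 22972,
}
REFERENCE_ASSEMBLY_TOTAL = 60027

REFERENCE_DE_LNC_COUNTS = {"tair10_lncRNA": 82, "novel": 227}

# Printed per-stage counts of the discovery cascade.
CASCADE_STAGE_COUNTS = {
    "n_input": 22972,
    "n_removed_overlap": 21459,
    "n_removed_short": 3,
    "n_removed_coding": 298,
    "n_retained": 1212,
}

P1BS = "GNATATNC"
_P1BS_RE = re.compile("G[ACGT]ATAT[ACGT]C")

_NONCODING_ALPHABET = np.frombuffer(b"ACT", dtype=np.uint8)  # no G => no ATG
_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
# stops in all three frames, G-free (cannot seed an ATG or extend an ORF)
_ORF_TERMINATOR = "TAATTAACTAAC"


@dataclass
class SimConfig:
    """Generator settings.  Defaults define the simulated study conditions."""

    seed: int = 0
    n_coding: int = 150
    n_tair10_lnc: int = 40
    n_pseudo: int = 12
    n_te: int = 12
    n_novel: int = 200
    n_decoy_short: int = 3
    n_decoy_coding: int = 12
    chrom: str = "chr1"
    promoter_len: int = 2000
    base_mean: float = 200.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.6
    de_fold: float = 5.0
    polya_plus_fraction: float = 0.7
    polya_minus_fraction: float = 0.1
    polya_ratio: float = 8.0
    motif_counts: dict = field(
        default_factory=lambda: {0: 0.40, 1: 0.20, 2: 0.20, 3: 0.12, 4: 0.08}
    )
    motif_fold_step: float = 1.4  # up-DE fold multiplied by step**n_motifs
    n_mirna: int = 4
    n_planted_targets: int = 8
    n_planted_mimics: int = 4
    n_planted_negatives: int = 4
    mirna_fold: float = 6.0
    dnase_value: float = 7.5

    def validate(self) -> None:
        counts = [
            self.n_coding, self.n_tair10_lnc, self.n_pseudo, self.n_te,
            self.n_novel, self.n_mirna, self.n_planted_targets,
            self.n_planted_mimics,
        ]
        if any(c < 0 for c in counts):
            raise GenomicsIOError("counts must be >= 0")
        if self.de_fold <= 1:
            raise GenomicsIOError("de_fold must exceed 1")
        if self.nb_dispersion <= 0:
            raise GenomicsIOError("nb_dispersion must be positive")
        if abs(sum(self.motif_counts.values()) - 1.0) > 1e-9:
            raise GenomicsIOError("motif_counts must be a distribution")


@dataclass
class TruthManifest:
    """Planted ground truth, one row per generated transcript."""

    transcripts: pd.DataFrame  # indexed by transcript_id
    mirna_targets: dict[str, list[str]]
    mirna_mimics: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.transcripts.index.duplicated().any():
            raise GenomicsIOError("duplicate transcript in truth manifest")


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    annotation: list[TranscriptModel]
    candidates: list[TranscriptModel]
    counts: ExpressionMatrix
    lengths: dict[str, int]
    dnase_records: list[tuple[str, int, int, float]]
    mirnas: dict[str, str]
    mirna_expr: dict[str, np.ndarray]
    matched_libraries: list[str]  # the 8 PA libraries, in matched-sample order
    term_map: dict[str, set[str]]
    truth: TruthManifest

    @property
    def dnase(self) -> BedGraphSignal:
        return BedGraphSignal(self.dnase_records)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Persist all outputs in their standard text formats.

        Refuses to overwrite: an existing target file is an error.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "candidates": outdir / "candidates.gtf",
            "counts": outdir / "counts.tsv",
            "libraries": outdir / "libraries.tsv",
            "dnase": outdir / "dnase.bedgraph",
            "mirnas": outdir / "mirnas.fa",
            "mirna_expression": outdir / "mirna_expression.tsv",
            "truth": outdir / "truth_transcripts.tsv",
            "term_map": outdir / "term_map.tsv",
            "config": outdir / "config.yaml",
        }
        for name, p in paths.items():
            if p.exists():
                raise GenomicsIOError(f"output path already exists: {p}")
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.annotation, paths["annotation"])
        write_gtf(self.candidates, paths["candidates"])
        write_expression(self.counts, paths["counts"], paths["libraries"])
        write_bedgraph(self.dnase_records, paths["dnase"])
        write_fasta(self.mirnas, paths["mirnas"])
        expr = pd.DataFrame(self.mirna_expr, index=self.matched_libraries).T
        expr.to_csv(paths["mirna_expression"], sep="\t", index_label="mirna_id")
        self.truth.transcripts.to_csv(paths["truth"], sep="\t", index_label="transcript_id")
        with open(paths["term_map"], "w") as fh:
            for term in sorted(self.term_map):
                for gene in sorted(self.term_map[term]):
                    fh.write(f"{term}\t{gene}\n")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump({**self.config.__dict__}, fh)
        return paths


# ---------------------------------------------------------------------------
# Count simulation (reusable without the genome)
# ---------------------------------------------------------------------------


def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) samples with variance mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    return rng.negative_binomial(n, p).astype(float)


def simulate_library_sizes(rng: np.random.Generator, libraries: Sequence[LibraryMeta]) -> dict[str, float]:
    """Total mapped reads per library, uniform in [0.8, 1.2] million."""
    return {
        lib.library_id: float(rng.uniform(0.8e6, 1.2e6)) for lib in libraries
    }


def simulate_two_group_counts(
    rng: np.random.Generator,
    n_transcripts: int,
    base_mean: float,
    dispersion: float,
    fold: float = 1.0,
    n_replicates: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate count matrices for a control and a ``fold``-scaled group."""
    a = nb_counts(rng, np.full((n_transcripts, n_replicates), base_mean), dispersion)
    b = nb_counts(rng, np.full((n_transcripts, n_replicates), base_mean * fold), dispersion)
    return a, b


# ---------------------------------------------------------------------------
# Genome construction helpers
# ---------------------------------------------------------------------------


class _GenomeBuilder:
    def __init__(self, rng: np.random.Generator, length: int):
        self.rng = rng
        self.arr = _DNA[rng.integers(0, 4, size=length)].copy()

    def write_oriented(self, exons: Sequence[GenomicInterval], strand: str, seq: str) -> None:
        """Write a spliced, strand-oriented sequence across an exon chain."""
        if strand == "-":
            seq = revcomp(seq)
        data = np.frombuffer(seq.encode(), dtype=np.uint8)
        pos = 0
        for e in exons:
            n = e.end - e.start
            self.arr[e.start : e.end] = data[pos : pos + n]
            pos += n
        assert pos == len(data)

    def noncoding_fill(self, exons: Sequence[GenomicInterval], strand: str) -> None:
        """Fill a transcript's exons with an ATG-free (A/C/T) sequence in its
        own orientation, so its forward frames carry no ORF."""
        total = sum(e.end - e.start for e in exons)
        seq = bytes(_NONCODING_ALPHABET[self.rng.integers(0, 3, size=total)]).decode()
        self.write_oriented(exons, strand, seq)

    def sequence(self) -> str:
        return self.arr.tobytes().decode()


def _coding_sequence(rng: np.random.Generator, length: int, orf_fraction: float = 0.8) -> str:
    """A transcript sequence starting with an ATG..stop ORF covering roughly
    ``orf_fraction`` of the length (no 5'UTR: the ATG sits at the TSS)."""
    n_codons = max(int(length * orf_fraction) // 3, 3)
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    body = "".join(_NONSTOP_CODONS[i] for i in idx)
    orf = "ATG" + body + "TAA"
    tail_len = length - len(orf)
    tail = bytes(_NONCODING_ALPHABET[rng.integers(0, 3, size=tail_len)]).decode()
    return orf + tail


def _instantiate_p1bs(rng: np.random.Generator) -> str:
    return "G" + "ACGT"[rng.integers(4)] + "ATAT" + "ACGT"[rng.integers(4)] + "C"


# ---------------------------------------------------------------------------
# The generator
# ---------------------------------------------------------------------------

_DE_PATTERNS = {  # cluster -> (root direction, shoot direction)
    1: ("up", "up"),
    2: ("up", "none"),
    3: ("none", "up"),
    4: ("down", "down"),
    5: ("down", "none"),
    6: ("none", "down"),
}


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate the full synthetic study.  Deterministic under fixed seed."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    prom = cfg.promoter_len
    gene_body = 2400
    locus_pitch = prom + gene_body + 2800  # room for a partner lncRNA promoter

    # --- layout -----------------------------------------------------------
    transcripts: list[TranscriptModel] = []
    candidates: list[TranscriptModel] = []
    truth_rows: dict[str, dict] = {}
    cursor = 1000

    coding_loci: list[TranscriptModel] = []
    for i in range(cfg.n_coding):
        start = cursor + prom
        strand = "+"
        exons = (
            GenomicInterval(cfg.chrom, start, start + 1200, strand),
            GenomicInterval(cfg.chrom, start + 1400, start + gene_body, strand),
        )
        t = TranscriptModel(f"GENE{i:04d}.1", f"GENE{i:04d}", exons, "protein_coding")
        coding_loci.append(t)
        transcripts.append(t)
        cursor += locus_pitch

    def simple_locus(tid: str, gid: str, biotype: str, length: int, strand: str, upstream: int):
        nonlocal cursor
        start = cursor + upstream
        t = TranscriptModel(
            tid, gid, (GenomicInterval(cfg.chrom, start, start + length, strand),), biotype
        )
        cursor = start + length + 2600
        return t

    tair_lncs = []
    for i in range(cfg.n_tair10_lnc):
        length = int(rng.integers(300, 800))
        t = simple_locus(f"AT10LNC{i:04d}.1", f"AT10LNC{i:04d}", "tair10_lncRNA", length, "+", prom)
        tair_lncs.append(t)
        transcripts.append(t)

    pseudo_hosts, te_hosts = [], []
    for i in range(cfg.n_pseudo):
        t = simple_locus(f"PSEUDO{i:04d}.1", f"PSEUDO{i:04d}", "pseudogene", 800, "+", 200)
        pseudo_hosts.append(t)
        transcripts.append(t)
    for i in range(cfg.n_te):
        t = simple_locus(f"TEG{i:04d}.1", f"TEG{i:04d}", "TE_related", 800, "+", 200)
        te_hosts.append(t)
        transcripts.append(t)

    # novel lncRNA placement: mostly antisense, then intergenic/cis/pseudo/TE
    class_plan: list[str] = []
    fracs = {"antisense": 0.55, "intergenic": 0.20, "cis": 0.13}
    n_pg = min(cfg.n_pseudo, max(int(0.06 * cfg.n_novel), 1) if cfg.n_novel else 0)
    n_te_c = min(cfg.n_te, max(int(0.06 * cfg.n_novel), 1) if cfg.n_novel else 0)
    n_anti = int(fracs["antisense"] * cfg.n_novel)
    n_cis = int(fracs["cis"] * cfg.n_novel)
    n_anti = min(n_anti, len(coding_loci))
    n_cis = min(n_cis, max(len(coding_loci) - n_anti, 0))
    n_inter = cfg.n_novel - n_anti - n_cis - n_pg - n_te_c
    class_plan = (
        ["antisense"] * n_anti + ["cis"] * n_cis + ["pseudogenic"] * n_pg
        + ["te_related"] * n_te_c + ["intergenic"] * max(n_inter, 0)
    )

    partner_free_genes = list(coding_loci)  # genes without a planted partner
    novel_lncs: list[TranscriptModel] = []
    gene_iter = iter(coding_loci)
    pseudo_iter = iter(pseudo_hosts)
    te_iter = iter(te_hosts)
    for i, cls in enumerate(class_plan):
        tid, gid = f"XLOC{i:05d}.1", f"XLOC{i:05d}"
        length = int(rng.integers(400, 900))
        if cls == "antisense":
            host = next(gene_iter)
            partner_free_genes.remove(host)
            # antisense strand, inside the host span, TSS at the right end
            end = host.end - int(rng.integers(0, 100))
            start = max(end - length, host.start + 50)
            exons = (GenomicInterval(cfg.chrom, start, end, "-"),)
        elif cls == "cis":
            host = next(gene_iter)
            partner_free_genes.remove(host)
            gap = int(rng.integers(100, 450))
            start = host.end + gap
            exons = (GenomicInterval(cfg.chrom, start, start + length, "+"),)
        elif cls == "pseudogenic":
            host = next(pseudo_iter)
            start = host.start + 100
            exons = (GenomicInterval(cfg.chrom, start, start + length, "+"),)
        elif cls == "te_related":
            host = next(te_iter)
            start = host.start + 100
            exons = (GenomicInterval(cfg.chrom, start, start + length, "+"),)
        else:  # intergenic: its own isolated slot
            start = cursor + prom
            n_ex = int(rng.integers(1, 4))
            if n_ex == 1:
                exons = (GenomicInterval(cfg.chrom, start, start + length, "+"),)
            else:
                piece = length // n_ex
                exs = []
                pos = start
                for k in range(n_ex):
                    exs.append(GenomicInterval(cfg.chrom, pos, pos + piece, "+"))
                    pos += piece + 150
                exons = tuple(exs)
            cursor = exons[-1].end + 2600
        t = TranscriptModel(tid, gid, exons, "novel")
        novel_lncs.append(t)
        candidates.append(t)
        truth_rows[tid] = {"biotype": "novel", "position_class": cls}

    # decoy candidates exercising the filter cascade
    for i in range(cfg.n_decoy_short):
        start = cursor + 100
        t = TranscriptModel(
            f"DECOYS{i:03d}.1", f"DECOYS{i:03d}",
            (GenomicInterval(cfg.chrom, start, start + 150, "+"),), "novel",
        )
        cursor = start + 2600
        candidates.append(t)
        truth_rows[t.transcript_id] = {"biotype": "decoy_short", "position_class": "none"}
    decoy_coding = []
    for i in range(cfg.n_decoy_coding):
        start = cursor + 100
        t = TranscriptModel(
            f"DECOYC{i:03d}.1", f"DECOYC{i:03d}",
            (GenomicInterval(cfg.chrom, start, start + 600, "+"),), "novel",
        )
        cursor = start + 3000
        decoy_coding.append(t)
        candidates.append(t)
        truth_rows[t.transcript_id] = {"biotype": "decoy_coding", "position_class": "none"}

    genome_len = cursor + prom + 1000
    gb = _GenomeBuilder(rng, genome_len)

    # --- sequence content -------------------------------------------------
    for t in coding_loci:
        gb.write_oriented(t.exons, t.strand, _coding_sequence(rng, t.length))
    for t in decoy_coding:
        gb.write_oriented(t.exons, t.strand, _coding_sequence(rng, t.length))
    for t in tair_lncs + novel_lncs:
        gb.noncoding_fill(t.exons, t.strand)
    for i in range(cfg.n_decoy_short):
        t = candidates[len(novel_lncs) + i]
        gb.noncoding_fill(t.exons, t.strand)

    # --- expression truth: polyA class, DE pattern ------------------------
    expressed = coding_loci + tair_lncs + novel_lncs
    for t in coding_loci + tair_lncs + pseudo_hosts + te_hosts:
        truth_rows[t.transcript_id] = {
            "biotype": t.biotype,
            "position_class": "none",
        }

    def draw_polya() -> str:
        u = rng.random()
        if u < cfg.polya_plus_fraction:
            return "polyA_plus"
        if u < cfg.polya_plus_fraction + cfg.polya_minus_fraction:
            return "polyA_minus"
        return "bimorphic"

    for t in expressed:
        truth_rows[t.transcript_id]["polya_class"] = draw_polya()

    n_de = int(round(cfg.de_fraction * len(expressed)))
    de_ids = list(rng.choice([t.transcript_id for t in expressed], size=n_de, replace=False))
    clusters = [1 + i % 6 for i in range(n_de)]
    for tid, cl in zip(de_ids, clusters):
        root_dir, shoot_dir = _DE_PATTERNS[cl]
        truth_rows[tid].update({"cluster": cl, "de_root": root_dir, "de_shoot": shoot_dir})
    for t in expressed:
        truth_rows[t.transcript_id].setdefault("cluster", 0)
        truth_rows[t.transcript_id].setdefault("de_root", "none")
        truth_rows[t.transcript_id].setdefault("de_shoot", "none")

    # --- promoters, P1BS planting, DNase ---------------------------------
    motif_levels = np.array(sorted(cfg.motif_counts))
    motif_probs = np.array([cfg.motif_counts[k] for k in motif_levels])

    def promoter_interval(t: TranscriptModel) -> tuple[int, int]:
        if t.strand == "+":
            return t.start - prom, t.start
        return t.end, t.end + prom

    planted_windows: dict[str, list[tuple[int, str]]] = {}
    for t in coding_loci + novel_lncs:
        k = int(rng.choice(motif_levels, p=motif_probs))
        offsets: list[int] = []
        words: list[str] = []
        if k:
            # distances upstream of the anchor for the most-5' motif base
            ds = sorted(rng.choice(np.arange(10, prom - 10, 14), size=k, replace=False))
            for d in ds:
                word = _instantiate_p1bs(rng)
                # promoter index of the window start, promoter oriented
                j = prom - d
                strand_choice = "+" if rng.random() < 0.5 else "-"
                planted = word if strand_choice == "+" else revcomp(word)
                # genomic placement via the oriented write over the promoter
                ps, pe = promoter_interval(t)
                if t.strand == "+":
                    g0 = ps + j
                    gb.arr[g0 : g0 + 8] = np.frombuffer(planted.encode(), dtype=np.uint8)
                else:
                    g0 = pe - j - 8
                    gb.arr[g0 : g0 + 8] = np.frombuffer(
                        revcomp(planted).encode(), dtype=np.uint8
                    )
                offsets.append(j - prom)
                words.append(word)
                planted_windows.setdefault(t.transcript_id, []).append((j, planted))
        truth_rows[t.transcript_id]["motif_count"] = k
        truth_rows[t.transcript_id]["motif_offsets"] = ",".join(map(str, offsets))
        truth_rows[t.transcript_id]["motif_words"] = ",".join(words)
    for t in expressed:
        truth_rows[t.transcript_id].setdefault("motif_count", 0)
        truth_rows[t.transcript_id].setdefault("motif_offsets", "")
        truth_rows[t.transcript_id].setdefault("motif_words", "")

    # designated PHR1 targets: motif >= 1 and planted DE -> DNase accessible
    dnase_records = []
    for t in coding_loci + novel_lncs:
        row = truth_rows[t.transcript_id]
        eligible = row["motif_count"] >= 1 and row["cluster"] != 0
        is_target = bool(eligible and rng.random() < 0.7)
        row["is_phr1_target"] = is_target
        if is_target:
            ps, pe = promoter_interval(t)
            dnase_records.append((cfg.chrom, ps, pe, cfg.dnase_value))
    for t in expressed:
        truth_rows[t.transcript_id].setdefault("is_phr1_target", False)
    dnase_records.sort(key=lambda r: r[1])

    # --- miRNAs: planted cleavage targets, mimics, shuffled negatives -----
    mirnas: dict[str, str] = {}
    for i in range(cfg.n_mirna):
        seq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=21))
        mirnas[f"miR-sim{i + 1}"] = seq
    mirna_ids = list(mirnas)

    intergenic_lncs = [
        t for t in novel_lncs if truth_rows[t.transcript_id]["position_class"] == "intergenic"
    ]
    hosts_pool = intergenic_lncs + partner_free_genes
    need = cfg.n_planted_targets + cfg.n_planted_mimics + cfg.n_planted_negatives
    if need > len(hosts_pool):
        raise GenomicsIOError("not enough isolated transcripts to host miRNA sites")
    host_idx = rng.choice(len(hosts_pool), size=need, replace=False)
    hosts = [hosts_pool[int(i)] for i in host_idx]
    target_hosts = hosts[: cfg.n_planted_targets]
    mimic_hosts = hosts[cfg.n_planted_targets : cfg.n_planted_targets + cfg.n_planted_mimics]
    negative_hosts = hosts[cfg.n_planted_targets + cfg.n_planted_mimics :]

    mirna_targets: dict[str, list[str]] = {m: [] for m in mirna_ids}
    mirna_mimics: dict[str, list[str]] = {m: [] for m in mirna_ids}

    def embed(t: TranscriptModel, site: str) -> None:
        """Place a site + ORF terminator mid-transcript, in its orientation."""
        seq = t.spliced_sequence({cfg.chrom: gb.sequence()})
        insert = site + _ORF_TERMINATOR
        pos = max((t.length - len(insert)) // 2, 0)
        new = seq[:pos] + insert + seq[pos + len(insert) :]
        gb.write_oriented(t.exons, t.strand, new)

    for i, host in enumerate(target_hosts):
        mid = mirna_ids[i % len(mirna_ids)]
        m = mirnas[mid].replace("U", "T")
        site = list(revcomp(m))
        n_mm = int(rng.integers(0, 3))  # 0-2 non-seed mismatches, score <= 2
        # non-seed miRNA positions 9..21 pair site indices 0..12
        mm_pos = rng.choice(np.arange(0, 12), size=n_mm, replace=False)
        for p in mm_pos:
            cur = site[int(p)]
            site[int(p)] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
        embed(host, "".join(site))
        mirna_targets[mid].append(host.transcript_id)
        row = truth_rows[host.transcript_id]
        row.update({"mirna_role": "cleavage_target", "mirna_id": mid})
        # cleaved targets are repressed while the miRNA is induced
        row.update({"cluster": 4, "de_root": "down", "de_shoot": "down"})

    for i, host in enumerate(mimic_hosts):
        mid = mirna_ids[i % len(mirna_ids)]
        m = mirnas[mid].replace("U", "T")
        site = revcomp(m[10:]) + "CTA" + revcomp(m[:10])
        embed(host, site)
        mirna_mimics[mid].append(host.transcript_id)
        row = truth_rows[host.transcript_id]
        row.update({"mirna_role": "mimic", "mirna_id": mid})
        row.update({"cluster": 1, "de_root": "up", "de_shoot": "up"})

    for i, host in enumerate(negative_hosts):
        mid = mirna_ids[i % len(mirna_ids)]
        m = mirnas[mid].replace("U", "T")
        site = revcomp(m)
        perm = rng.permutation(len(site))
        embed(host, "".join(site[int(p)] for p in perm))
        row = truth_rows[host.transcript_id]
        row.update({"mirna_role": "shuffled_negative", "mirna_id": mid})
    for row in truth_rows.values():
        row.setdefault("polya_class", "none")
        row.setdefault("cluster", 0)
        row.setdefault("de_root", "none")
        row.setdefault("de_shoot", "none")
        row.setdefault("motif_count", 0)
        row.setdefault("motif_offsets", "")
        row.setdefault("motif_words", "")
        row.setdefault("is_phr1_target", False)
        row.setdefault("mirna_role", "none")
        row.setdefault("mirna_id", "")

    # --- sanitize promoters: no accidental P1BS words ---------------------
    genome_arr = gb.arr
    for t in coding_loci + novel_lncs:
        ps, pe = promoter_interval(t)
        planted = planted_windows.get(t.transcript_id, [])
        if t.strand == "+":
            planted_g = {ps + j for j, _ in planted}
        else:
            planted_g = {pe - j - 8 for j, _ in planted}
        for _ in range(20):
            region = genome_arr[ps:pe].tobytes().decode()
            dirty = False
            for mm in _iter_consensus_matches(region):
                g = ps + mm
                if g in planted_g:
                    continue
                # break the match at a base outside any planted window
                for rel in (3, 4, 2, 5, 0, 7, 1, 6):
                    if all(not (w <= g + rel < w + 8) for w in planted_g):
                        genome_arr[g + rel] = ord("C") if genome_arr[g + rel] != ord("C") else ord("A")
                        break
                dirty = True
            if not dirty:
                break

    genome = {cfg.chrom: gb.sequence()}

    # --- counts ------------------------------------------------------------
    libraries = full_design(2)
    lib_sizes = simulate_library_sizes(rng, libraries)
    all_counted = expressed + candidates[len(novel_lncs) :] + pseudo_hosts + te_hosts
    seen = set()
    counted = []
    for t in all_counted:
        if t.transcript_id not in seen:
            counted.append(t)
            seen.add(t.transcript_id)

    mean_rows = []
    for t in counted:
        row = truth_rows.get(t.transcript_id, {})
        polya = row.get("polya_class", "bimorphic")
        means = []
        for lib in libraries:
            mu = cfg.base_mean
            direction = row.get(f"de_{lib.tissue}", "none")
            if lib.condition == "P_minus" and direction != "none":
                fold = cfg.de_fold
                if direction == "up":
                    fold *= cfg.motif_fold_step ** row.get("motif_count", 0)
                    mu *= fold
                else:
                    mu /= fold
            if polya == "polyA_plus" and lib.polya == "NPA":
                mu /= cfg.polya_ratio
            elif polya == "polyA_minus" and lib.polya == "PA":
                mu /= cfg.polya_ratio
            mu *= lib_sizes[lib.library_id] / 1e6
            means.append(mu)
        mean_rows.append(means)
    mean_matrix = np.array(mean_rows)
    count_matrix = nb_counts(rng, mean_matrix, cfg.nb_dispersion)
    counts = ExpressionMatrix(
        pd.DataFrame(
            count_matrix,
            index=[t.transcript_id for t in counted],
            columns=[l.library_id for l in libraries],
        ),
        libraries,
        lib_sizes,
    )
    lengths = {t.transcript_id: t.length for t in counted}

    # --- matched small-RNA expression -------------------------------------
    matched = [
        lib.library_id
        for lib in libraries
        if lib.polya == "PA"
    ]
    mirna_expr: dict[str, np.ndarray] = {}
    for mid in mirna_ids:
        vals = []
        for lid in matched:
            lib = counts.meta(lid)
            mu = 60.0 * (cfg.mirna_fold if lib.condition == "P_minus" else 1.0)
            vals.append(float(nb_counts(rng, np.array([mu]), cfg.nb_dispersion)[0]))
        mirna_expr[mid] = np.array(vals)

    # --- toy GO-style term map --------------------------------------------
    term_map: dict[str, set[str]] = {}
    for cl in range(1, 7):
        term_map[f"TERM:cluster{cl}"] = {
            tid for tid, row in truth_rows.items() if row.get("cluster") == cl
        }
    universe = [t.transcript_id for t in expressed]
    for i in range(4):
        pick = rng.choice(universe, size=min(30, len(universe)), replace=False)
        term_map[f"TERM:random{i}"] = set(map(str, pick))

    truth_df = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth_df.index.name = "transcript_id"
    truth = TruthManifest(truth_df, mirna_targets, mirna_mimics)

    return SimResult(
        cfg, genome, transcripts, candidates, counts, lengths, dnase_records,
        {k: v for k, v in mirnas.items()}, mirna_expr, matched, term_map, truth,
    )


def _iter_consensus_matches(seq: str):
    """Start offsets of all (overlapping) P1BS consensus matches in ``seq``.

    The consensus is its own reverse complement, so sense matches cover both
    scan strands.  Overlapping matches are all reported.
    """
    pos = 0
    while True:
        m = _P1BS_RE.search(seq, pos)
        if m is None:
            break
        yield m.start()
        pos = m.start() + 1


# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------

# The printed miR399 target table: (miRNA, target, PCC, target score, cluster);
# cluster "/" marks the one row printed without a cluster assignment.
_TABLE2_ROWS: list[tuple[str, str, float, float, str]] = [
    ("miR399a", "AtPT1", -0.72, 5.0, "3"),
    ("miR399a", "SMXL5", -0.72, 5.0, "1"),
    ("miR399a", "ECT2", -0.71, 4.5, "3"),
    ("miR399a", "AtCS-C", -0.70, 4.8, "2"),
    ("miR399a", "TIP4;1", -0.68, 4.8, "3"),
    ("miR399a", "AtPT2", -0.67, 5.0, "1"),
    ("miR399a", "SPPL5", -0.67, 5.0, "6"),
    ("miR399a", "AtSCAR4", -0.62, 5.0, "6"),
    ("miR399a", "AtPP2-A5", -0.59, 4.0, "6"),
    ("miR399a", "AT3G18620", -0.59, 4.8, "3"),
    ("miR399a", "AtCFM2", -0.59, 4.5, "6"),
    ("miR399a", "AT1G61860", -0.58, 4.8, "3"),
    ("miR399a", "AT2G31150", -0.58, 5.0, "6"),
    ("miR399a", "AT3G44820", -0.58, 4.8, "3"),
    ("miR399a", "IPGAM1", -0.57, 5.0, "3"),
    ("miR399a", "AT2G25420", -0.57, 4.0, "6"),
    ("miR399a", "AtOPR1", -0.57, 4.8, "3"),
    ("miR399a", "AT4G19520", -0.56, 5.0, "6"),
    ("miR399a", "OZS2", -0.55, 4.8, "3"),
    ("miR399a", "AT2G38740", -0.55, 4.5, "2"),
    ("miR399a", "BLH1", -0.53, 4.2, "3"),
    ("miR399a", "TGA7", -0.51, 5.0, "3"),
    ("miR399a", "AT1G61590", -0.51, 4.8, "3"),
    ("miR399a", "CYP705A30", -0.44, 2.0, "3"),
    ("miR399a", "PHO2", -0.37, 0.8, "/"),
    ("miR399a", "NF-YA10", -0.10, 2.5, "1"),
    ("miR399d", "XLOC_001691", -0.74, 5.0, "1"),
    ("miR399b", "XLOC_026270", -0.68, 5.0, "6"),
    ("miR399e", "XLOC_013661", -0.64, 5.0, "2"),
    ("miR399b", "XLOC_013840", -0.63, 4.5, "6"),
    ("miR399e", "XLOC_026270", -0.62, 4.5, "6"),
    ("miR399e", "XLOC_003248", -0.60, 5.0, "3"),
    ("miR399e", "XLOC_001806", -0.59, 4.8, "5"),
    ("miR399a", "XLOC_018338", -0.58, 4.5, "5"),
    ("miR399d", "XLOC_027498", -0.58, 4.8, "6"),
    ("miR399d", "XLOC_010238", -0.57, 4.8, "3"),
    ("miR399c-5p", "XLOC_019368", -0.57, 5.0, "4"),
    ("miR399c-3p", "XLOC_016349", -0.53, 4.0, "6"),
    ("miR399b", "XLOC_020833", -0.53, 5.0, "3"),
    ("miR399a", "XLOC_008029", -0.51, 5.0, "6"),
    ("miR399c-3p", "XLOC_005358", -0.50, 4.8, "6"),
    ("miR399f", "XLOC_026270", -0.50, 4.5, "6"),
]


def table2_fixture() -> pd.DataFrame:
    """The printed miR399 target table as a DataFrame (one row per entry)."""
    df = pd.DataFrame(
        _TABLE2_ROWS, columns=["mirna", "target", "pcc", "target_score", "cluster"]
    )
    df["is_lncRNA"] = df["target"].str.startswith("XLOC_")
    return df


def write_table2_fixture(path: str | Path) -> pd.DataFrame:
    df = table2_fixture()
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Cascade fixture: engineered to the printed per-stage counts
# ---------------------------------------------------------------------------


def cascade_fixture(seed: int = 0):
    """Synthetic candidates/annotation/genome whose discovery cascade
    reproduces the source study's printed per-stage counts: 22,972 in;
    21,459 removed by annotation overlap (21,435 same-strand coding/lncRNA +
    24 antisense lncRNA); 3 removed as < 200 nt; 298 removed as coding;
    1,212 retained.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrF"
    n_same, n_anti = (
        CASCADE_STAGE_COUNTS["n_removed_overlap"] - 24,
        24,
    )
    n_short = CASCADE_STAGE_COUNTS["n_removed_short"]
    n_coding = CASCADE_STAGE_COUNTS["n_removed_coding"]
    n_clean = CASCADE_STAGE_COUNTS["n_retained"]

    annotation: list[TranscriptModel] = []
    candidates: list[TranscriptModel] = []

    # a handful of annotated genes to overlap; candidates tile across them
    n_genes = 40
    gene_len = 3000
    pitch = 4000
    for i in range(n_genes):
        s = 1000 + i * pitch
        annotation.append(
            TranscriptModel(
                f"G{i:03d}.1", f"G{i:03d}",
                (GenomicInterval(chrom, s, s + gene_len, "+"),), "protein_coding",
            )
        )
    lnc_s = 1000 + n_genes * pitch
    for i in range(4):
        s = lnc_s + i * pitch
        annotation.append(
            TranscriptModel(
                f"L{i:02d}.1", f"L{i:02d}",
                (GenomicInterval(chrom, s, s + 1500, "+"),), "tair10_lncRNA",
            )
        )

    for i in range(n_same):
        g = annotation[i % n_genes]
        off = int(rng.integers(0, gene_len - 300))
        strand = "+"  # same strand as the gene
        candidates.append(
            TranscriptModel(
                f"CUFF.S{i:05d}.1", f"CUFF.S{i:05d}",
                (GenomicInterval(chrom, g.start + off, g.start + off + 250, strand),),
                "novel",
            )
        )
    for i in range(n_anti):
        l = annotation[n_genes + i % 4]
        off = int(rng.integers(0, 1200))
        candidates.append(
            TranscriptModel(
                f"CUFF.A{i:05d}.1", f"CUFF.A{i:05d}",
                (GenomicInterval(chrom, l.start + off, l.start + off + 250, "-"),),
                "novel",
            )
        )

    cursor = lnc_s + 4 * pitch + 2000
    seq_regions: list[tuple[TranscriptModel, str]] = []

    def add_isolated(tid: str, length: int, kind: str):
        nonlocal cursor
        t = TranscriptModel(
            tid, tid.rsplit(".", 1)[0],
            (GenomicInterval(chrom, cursor, cursor + length, "+"),), "novel",
        )
        cursor += length + 120
        candidates.append(t)
        seq_regions.append((t, kind))
        return t

    for i in range(n_short):
        add_isolated(f"CUFF.T{i:05d}.1", 150 + i * 10, "noncoding")
    for i in range(n_coding):
        add_isolated(f"CUFF.C{i:05d}.1", 600, "coding")
    for i in range(n_clean):
        add_isolated(f"CUFF.N{i:05d}.1", int(rng.integers(250, 600)), "noncoding")

    genome_len = cursor + 1000
    gb = _GenomeBuilder(rng, genome_len)
    for t, kind in seq_regions:
        if kind == "coding":
            gb.write_oriented(t.exons, t.strand, _coding_sequence(rng, t.length))
        else:
            gb.noncoding_fill(t.exons, t.strand)
    genome = {chrom: gb.sequence()}
    assert len(candidates) == CASCADE_STAGE_COUNTS["n_input"]
    return candidates, annotation, genome
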