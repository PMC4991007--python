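"""P1BS promoter-motif scanning and PHR1 target prediction.

The PHR1 binding site (P1BS, consensus GNATATNC) is turned into a position
weight matrix with pseudocounts; promoters are scanned with log-odds scores
whose background tail probabilities are computed exactly by dynamic
programming over a discretized score lattice, so a FIMO-style p < 1e-3
cutoff is available without simulation.  Promoters are the 2 kb upstream of
the first ATG (genes) or the transcription start (lncRNAs).

A transcript is called a PHR1 target only when three evidence layers agree:
at least one P1BS hit in its promoter, significant differential expression
under Pi starvation, and positive chromatin accessibility (DNase signal)
over the promoter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomics_io import BedGraphSignal, GenomicsIOError, TranscriptModel, revcomp

DNA = "ACGT"
_CODE = {c: i for i, c in enumerate(DNA)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

P1BS_CONSENSUS = "GNATATNC"


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # negative; most-5' base of the hit window relative to the anchor
    strand: str
    word: str
    score: float
    p_value: float


class PWMModel:
    """PWM with exact background score distribution on a discrete lattice.

    Per-position log2-odds scores are discretized to ``n_bins`` levels per
    position; the distribution of the total discretized score under the
    background is obtained by position-wise convolution, giving exact tail
    probabilities for every achievable word score.
    """

    def __init__(
        self,
        probs: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.0,
        n_bins: int = 1000,
    ) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise GenomicsIOError("PWM probabilities must be (L, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0):
            raise GenomicsIOError("PWM rows must sum to 1")
        self.probs = probs
        self.pseudocount = pseudocount
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise GenomicsIOError("background must sum to 1")
        self.length = probs.shape[0]
        # zero probabilities are floored so log-odds stay finite; words using
        # such letters score far below any threshold of interest
        self.scores = np.log2(np.maximum(self.probs, 1e-12) / self.background[None, :])
        # discretize: common bin width from the widest per-position range
        ranges = self.scores.max(axis=1) - self.scores.min(axis=1)
        self._delta = max(float(ranges.max()), 1e-12) / n_bins
        self.qscores = np.rint(self.scores / self._delta).astype(np.int64)
        self._build_tail()

    def _build_tail(self) -> None:
        lo = int(self.qscores.min(axis=1).sum())
        hi = int(self.qscores.max(axis=1).sum())
        width = hi - lo + 1
        dist = np.zeros(width)
        # start as a delta at 0 (represented at index -lo)
        dist[-lo] = 1.0
        cur_lo = 0
        for i in range(self.length):
            nxt = np.zeros(width)
            for a in range(4):
                q = int(self.qscores[i, a])
                b = self.background[a]
                if b == 0:
                    continue
                shift = q  # shifting the support by q
                src = dist
                if shift >= 0:
                    nxt[shift:] += src[: width - shift] * b
                else:
                    nxt[: width + shift] += src[-shift:] * b
            dist = nxt
            cur_lo += 0
        self._qlo = lo
        # tail[i] = P(Q >= lo + i)
        self._tail = dist[::-1].cumsum()[::-1]

    def word_qscore(self, word: str) -> int:
        return int(sum(self.qscores[i, _CODE[c]] for i, c in enumerate(word)))

    def word_score(self, word: str) -> float:
        """Real-valued log2-odds score of an exact-length word."""
        if len(word) != self.length:
            raise GenomicsIOError("word length mismatch")
        return float(sum(self.scores[i, _CODE[c]] for i, c in enumerate(word.upper())))

    def tail_probability(self, qscore: int) -> float:
        """Exact P(background word q-score >= qscore)."""
        idx = qscore - self._qlo
        if idx < 0:
            return 1.0
        if idx >= len(self._tail):
            return 0.0
        return float(self._tail[idx])

    def word_p_value(self, word: str) -> float:
        return self.tail_probability(self.word_qscore(word.upper()))


def iupac_to_pwm(
    consensus: str,
    pseudocount: float = 0.05,
    background: np.ndarray | None = None,
    n_bins: int = 1000,
) -> PWMModel:
    """Build a PWM from an IUPAC consensus.

    At each position the letters allowed by the IUPAC symbol share the
    probability mass 1 - 4*pseudocount equally; every letter additionally
    receives the pseudocount (so N positions are uniform).
    """
    consensus = consensus.upper()
    if pseudocount < 0 or pseudocount >= 0.25:
        raise GenomicsIOError("pseudocount must lie in [0, 0.25)")
    rows = []
    for sym in consensus:
        if sym not in IUPAC:
            raise GenomicsIOError(f"invalid IUPAC symbol {sym!r}")
        allowed = IUPAC[sym]
        row = np.full(4, pseudocount)
        for c in allowed:
            row[_CODE[c]] += (1 - 4 * pseudocount) / len(allowed)
        rows.append(row)
    return PWMModel(np.array(rows), background, pseudocount, n_bins)


def scan_promoter(
    pwm: PWMModel,
    sequence: str,
    sequence_id: str = "",
    p_threshold: float = 1e-3,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a promoter (5'->3' toward the anchor) for PWM hits with exact
    tail probability <= ``p_threshold``.

    Offsets are reported in the negative upstream convention: a window whose
    most-5' base sits d nt upstream of the anchor gets offset -d (the last
    promoter base is 1 nt upstream, offset -1 for a window ending there).
    Reverse-strand hits are scored on the reverse complement of the window
    and reported at the same window offset with strand '-'.  Windows with
    non-ACGT letters are skipped; sequences shorter than the motif yield [].
    """
    seq = sequence.upper()
    L = pwm.length
    n = len(seq)
    if n < L:
        return []
    codes = np.full(n, -1, dtype=np.int64)
    for c, i in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(c)] = i
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    hits: list[MotifHit] = []

    def q_of(window_codes: np.ndarray, qtable: np.ndarray) -> np.ndarray:
        return qtable[np.arange(L)[None, :], window_codes].sum(axis=1)

    strands: list[tuple[str, np.ndarray]] = [("+", pwm.qscores)]
    if both_strands:
        # scoring revcomp(window) with the PWM == scoring the window with the
        # reverse-complemented score table
        rc_q = pwm.qscores[::-1, ::-1]
        strands.append(("-", rc_q))
    for strand, qtable in strands:
        qs = q_of(np.where(windows >= 0, windows, 0), qtable)
        for j in np.nonzero(valid)[0]:
            p = pwm.tail_probability(int(qs[j]))
            if p <= p_threshold:
                word = seq[j : j + L]
                if strand == "-":
                    scored = revcomp(word)
                else:
                    scored = word
                hits.append(
                    MotifHit(sequence_id, int(j) - n, strand, word, pwm.word_score(scored), p)
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Promoter:
    """An upstream promoter window, oriented 5'->3' toward its anchor."""

    sequence_id: str
    chrom: str
    start: int
    end: int
    strand: str
    anchor: int  # genomic coordinate of the anchor (ATG or TSS)
    sequence: str
    truncated: bool


def _first_atg_genomic(transcript: TranscriptModel, genome: Mapping[str, str]) -> int | None:
    """Genomic coordinate of the first ATG in the spliced transcript, or None."""
    seq = transcript.spliced_sequence(genome)
    pos = seq.find("ATG")
    if pos == -1:
        return None
    # walk the exon chain 5'->3' to map the spliced index to genome space
    exons = transcript.exons if transcript.strand == "+" else transcript.exons[::-1]
    remaining = pos
    for e in exons:
        if remaining < len(e):
            if transcript.strand == "+":
                return e.start + remaining
            return e.end - 1 - remaining
        remaining -= len(e)
    raise AssertionError("unreachable: ATG index beyond transcript")


def extract_promoter(
    anchor: TranscriptModel,
    genome: Mapping[str, str],
    length: int = 2000,
    anchor_mode: str = "TSS",
) -> Promoter:
    """Extract the upstream promoter of a transcript.

    ``anchor_mode='ATG'`` anchors at the first ATG of the spliced sequence
    (falling back to the TSS when no ATG exists); ``'TSS'`` anchors at the
    transcription start.  On '+' the window is [anchor-length, anchor); on
    '-' it is [anchor, anchor+length) reverse-complemented.  Windows are
    truncated at chromosome edges (flagged).
    """
    if anchor.chrom not in genome:
        raise GenomicsIOError(f"chrom {anchor.chrom!r} absent from genome")
    chrom_seq = genome[anchor.chrom]
    if anchor_mode == "ATG":
        pos = _first_atg_genomic(anchor, genome)
        apos = pos if pos is not None else anchor.tss
    elif anchor_mode == "TSS":
        apos = anchor.tss
    else:
        raise GenomicsIOError(f"anchor_mode must be ATG or TSS, got {anchor_mode!r}")
    if apos < 0 or apos > len(chrom_seq):
        raise GenomicsIOError(f"anchor {apos} beyond chromosome {anchor.chrom}")
    if anchor.strand == "+":
        start, end = max(apos - length, 0), apos
        seq = chrom_seq[start:end].upper()
        truncated = (end - start) < length
    else:
        start, end = apos, min(apos + length, len(chrom_seq))
        seq = revcomp(chrom_seq[start:end])
        truncated = (end - start) < length
    return Promoter(anchor.transcript_id, anchor.chrom, start, end, anchor.strand, apos, seq, truncated)


# ---------------------------------------------------------------------------
# PHR1 evidence cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegTarget:
    transcript_id: str
    n_motifs: int
    dnase_mean: float
    de_significant: bool
    is_target: bool


def phr1_target_cascade(
    hits: Mapping[str, Sequence[MotifHit]],
    de_significant: Mapping[str, bool],
    dnase: BedGraphSignal,
    promoters: Mapping[str, Promoter],
) -> tuple[list[RegTarget], list[str]]:
    """Combine motif, expression and accessibility evidence per transcript.

    is_target requires >=1 promoter P1BS hit AND significant Pi-starvation
    response AND positive mean DNase signal over the promoter.  Transcripts
    lacking a promoter are excluded and returned separately.  The universe
    tested is the union of transcripts with hits or DE calls that have a
    promoter.
    """
    excluded = sorted(set(hits) - set(promoters)) + sorted(
        set(de_significant) - set(promoters) - set(hits)
    )
    targets = []
    for tid, prom in promoters.items():
        n_motifs = len(hits.get(tid, ()))
        sig = bool(de_significant.get(tid, False))
        dn = dnase.mean(prom.chrom, prom.start, prom.end) if prom.end > prom.start else 0.0
        targets.append(RegTarget(tid, n_motifs, dn, sig, n_motifs >= 1 and sig and dn > 0))
    targets.sort(key=lambda t: t.transcript_id)
    return targets, excluded


def motif_count_fold_trend(
    targets: Sequence[RegTarget],
    log2_fc: Mapping[str, float],
    max_count: int = 4,
) -> tuple[pd.DataFrame, bool]:
    """Mean log2 fold change per promoter P1BS count, with 95% CI.

    Intended for up-regulated transcripts; empty bins are omitted.  The
    monotone flag is True when bin means strictly increase with motif count.
    """
    rows = []
    for c in range(0, max_count + 1):
        vals = [
            log2_fc[t.transcript_id]
            for t in targets
            if min(t.n_motifs, max_count) == c and t.transcript_id in log2_fc
        ]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        mean = float(arr.mean())
        half = 1.96 * float(arr.std(ddof=1)) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        rows.append({"n_motifs": c, "n": len(arr), "mean_log2fc": mean,
                     "ci_lo": mean - half, "ci_hi": mean + half})
    df = pd.DataFrame(rows)
    means = df["mean_log2fc"].to_numpy() if len(df) else np.array([])
    monotone = bool(len(means) >= 2 and np.all(np.diff(means) > 0))
    return df, monotone


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def hits_table(hits: Mapping[str, Sequence[MotifHit]]) -> pd.DataFrame:
    """Table-1-style report: one row per sequence with motif count, comma
    joined positions and matched words."""
    rows = []
    for sid in sorted(hits):
        hs = sorted(hits[sid], key=lambda h: -h.offset)  # closest to anchor first? keep 5'->3'
        hs = sorted(hits[sid], key=lambda h: h.offset)
        if not hs:
            continue
        rows.append(
            {
                "id": sid,
                "n_motifs": len(hs),
                "positions": ",".join(str(h.offset) for h in hs),
                "sequences": ",".join(h.word for h in hs),
            }
        )
    return pd.DataFrame(rows)


def write_meme_pwm(pwm: PWMModel, name: str, path) -> None:
    """Write the PWM in minimal MEME motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(f"Background letter frequencies\n")
        fh.write(
            "A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*pwm.background)
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" " + "  ".join(f"{v:.6f}" for v in row) + "\n")
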