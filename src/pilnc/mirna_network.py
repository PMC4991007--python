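"""miRNA target scoring, target mimicry detection and the ceRNA network.

Cleavage targets are scored by antiparallel complementarity between the
miRNA (5'->3') and a transcript window: each mismatch costs 1, each G:U
wobble 0.5 and each bulged/gapped base 2, with all penalties doubled at
miRNA positions 2-8 (the seed).  A perfect reverse-complement site scores 0
and candidate targets are kept at score <= 5.  Interactions entering the
competing-endogenous-RNA network must additionally show anti-correlated
expression (Pearson r <= -0.5 by default) over matched small-RNA / long-RNA
samples; a whitelist of validated targets may bypass the correlation gate.

A target mimic is a distinct interaction class: a site pairing the miRNA
perfectly over the seed but carrying an exact 3-nt unpaired insertion in
the TARGET opposite the junction of miRNA positions 10-11 (the IPS1/AT4
configuration, which blocks cleavage); bulge-free perfect complements are
cleavage targets, never mimics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genomics_io import GenomicsIOError, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
SEED_POSITIONS = range(2, 9)  # miRNA positions 2..8, 1-based from the 5' end
MAX_GAPS = 2
SCORE_CUTOFF = 5.0
PCC_CUTOFF = -0.5


@dataclass(frozen=True)
class MirnaInteraction:
    mirna_id: str
    target_id: str
    target_score: float
    site_start: int  # on the target transcript, 0-based half-open
    site_end: int
    pcc: float  # nan when not computed / undefined
    kind: str  # cleavage_target | mimic
    whitelisted: bool = False


def _pair_penalty(mirna_base: str, target_base: str) -> float:
    """0 for Watson-Crick, WOBBLE for G:U, MISMATCH otherwise."""
    mb, tb = mirna_base, target_base
    if _COMP.get(mb) == tb or (mb == "U" and tb == "A"):
        return 0.0
    if (mb == "G" and tb in "TU") or (mb in "TU" and tb == "G"):
        return WOBBLE
    return MISMATCH


def score_target(mirna: str, transcript: str) -> tuple[float, tuple[int, int]]:
    """Best (lowest) complementarity score over all target windows.

    The alignment is semi-global (the whole miRNA against any transcript
    window) with at most ``MAX_GAPS`` bulged bases.  Returns the score and
    the site coordinates on the transcript; ties resolve to the leftmost
    site.  Raises when the transcript is shorter than the miRNA.
    """
    m = mirna.upper().replace("U", "T")
    t = transcript.upper().replace("U", "T")
    L, n = len(m), len(t)
    if not 19 <= L <= 24:
        raise GenomicsIOError(f"miRNA length must be 19-24 nt, got {L}")
    if n < L:
        raise GenomicsIOError("transcript shorter than miRNA")
    # row i aligns reverse-complement index i-1, i.e. miRNA position L-i+1
    rcm = revcomp(m)
    mpos = [L - i for i in range(L)]  # miRNA position (1-based) of rcm index i
    weights = np.array([2.0 if p in SEED_POSITIONS else 1.0 for p in mpos])
    tcodes = np.frombuffer(t.encode(), dtype=np.uint8)
    pen_rows = np.empty((L, n))
    for i in range(L):
        mb = m[mpos[i] - 1]
        row = np.empty(n)
        for j, tb in enumerate(t):
            row[j] = _pair_penalty(mb, tb)
        pen_rows[i] = row * weights[i]
    INF = 1e18
    # D[g][j]: cost of aligning the first i rcm bases ending at target pos j
    D = np.zeros((MAX_GAPS + 1, n + 1))
    for i in range(1, L + 1):
        w = weights[i - 1]
        gap_cost = GAP * w
        nxt = np.full((MAX_GAPS + 1, n + 1), INF)
        for g in range(MAX_GAPS + 1):
            # diagonal: pair rcm[i-1] with t[j-1]
            nxt[g, 1:] = D[g, :-1] + pen_rows[i - 1]
            # up: miRNA base unpaired (gap in target)
            if g > 0:
                nxt[g] = np.minimum(nxt[g], D[g - 1] + gap_cost)
        # left: target base unpaired (bulge in target); chains bounded by g
        for g in range(1, MAX_GAPS + 1):
            cand = np.full(n + 1, INF)
            cand[1:] = nxt[g - 1, :-1] + gap_cost
            nxt[g] = np.minimum(nxt[g], cand)
        D = nxt
    final = D.min(axis=0)[1:]  # best over gap counts, per end position j=1..n
    best = float(final.min())
    end = int(np.argmin(final)) + 1  # leftmost best end
    start = _trace_start(m, t, mpos, weights, end, best)
    return best, (start, end)


def _trace_start(m, t, mpos, weights, end, best_cost) -> int:
    """Recover the leftmost site start for the best alignment ending at ``end``
    by re-running a small DP on the tail window."""
    L = len(m)
    lo = max(end - L - MAX_GAPS, 0)
    sub = t[lo:end]
    ns = len(sub)
    INF = 1e18
    # D[i][j][g] over the small window, alignment anchored to end at ns
    D = np.full((L + 1, ns + 1, MAX_GAPS + 1), INF)
    S = np.full((L + 1, ns + 1, MAX_GAPS + 1), ns + 1, dtype=int)  # start col
    D[0, :, 0] = 0.0
    for j in range(ns + 1):
        S[0, j, 0] = j
    for i in range(1, L + 1):
        w = weights[i - 1]
        mb = m[mpos[i - 1] - 1]
        for j in range(ns + 1):
            for g in range(MAX_GAPS + 1):
                best, bstart = INF, ns + 1
                if j > 0:
                    c = D[i - 1, j - 1, g] + _pair_penalty(mb, sub[j - 1]) * w
                    if c < best or (c == best and S[i - 1, j - 1, g] < bstart):
                        best, bstart = c, S[i - 1, j - 1, g]
                if g > 0:
                    c = D[i - 1, j, g - 1] + GAP * w
                    if c < best or (c == best and S[i - 1, j, g - 1] < bstart):
                        best, bstart = c, S[i - 1, j, g - 1]
                if g > 0 and j > 0:
                    c = D[i, j - 1, g - 1] + GAP * w
                    if c < best or (c == best and S[i, j - 1, g - 1] < bstart):
                        best, bstart = c, S[i, j - 1, g - 1]
                D[i, j, g] = best
                S[i, j, g] = bstart
    gbest = int(np.argmin(D[L, ns, :]))
    return lo + int(S[L, ns, gbest])


# ---------------------------------------------------------------------------
# Expression correlation / ceRNA network
# ---------------------------------------------------------------------------


def expression_pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation over matched samples; nan flags zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise GenomicsIOError("expression vectors must have equal length")
    if x.size < 3:
        raise GenomicsIOError("need >=3 matched samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def build_cerna_network(
    interactions: Iterable[MirnaInteraction],
    pcc_cutoff: float = PCC_CUTOFF,
    score_cutoff: float = SCORE_CUTOFF,
    whitelist: Iterable[tuple[str, str]] = (),
) -> list[MirnaInteraction]:
    """Keep edges with target_score <= cutoff and PCC <= pcc_cutoff.

    (miRNA, target) pairs in ``whitelist`` bypass the correlation gate (but
    not the score gate) and are flagged.  Filter order is immaterial.
    """
    wl = set(whitelist)
    kept = []
    for it in interactions:
        if it.target_score > score_cutoff:
            continue
        white = (it.mirna_id, it.target_id) in wl
        if not white and not (not math.isnan(it.pcc) and it.pcc <= pcc_cutoff):
            continue
        kept.append(
            MirnaInteraction(
                it.mirna_id, it.target_id, it.target_score, it.site_start,
                it.site_end, it.pcc, it.kind, whitelisted=white,
            )
        )
    return kept


# ---------------------------------------------------------------------------
# Target mimicry
# ---------------------------------------------------------------------------


def detect_mimic(
    mirna: str,
    transcript: str,
    bulge_len: int = 3,
    max_mismatch: int = 3,
) -> tuple[int, int] | None:
    """Find a target-mimic site: seed-perfect pairing with an exact
    ``bulge_len``-nt target insertion opposite the miRNA 10-11 junction.

    Pairing outside the bulge is positional (no gaps); G:U wobbles count as
    mismatches and at most ``max_mismatch`` are tolerated outside the seed
    (miRNA positions 2-8).  Returns the leftmost site (start, end) on the
    transcript, or None.  Bulge-free perfect complements never match.
    """
    m = mirna.upper().replace("U", "T")
    t = transcript.upper().replace("U", "T")
    L = len(m)
    if not 19 <= L <= 24:
        raise GenomicsIOError(f"miRNA length must be 19-24 nt, got {L}")
    site_len = L + bulge_len
    if len(t) < site_len:
        return None
    # site = revcomp(m[10:]) + bulge + revcomp(m[:10]) pairs m antiparallel
    seg1_len = L - 10  # pairs miRNA positions 11..L
    for j in range(len(t) - site_len + 1):
        window = t[j : j + site_len]
        seg1 = window[:seg1_len]
        seg2 = window[seg1_len + bulge_len :]
        # seg1 index a pairs miRNA position L-a; seg2 index b pairs position 10-b
        mismatches = 0
        ok = True
        for a in range(seg1_len):
            p = L - a
            paired = _COMP[m[p - 1]] == seg1[a]
            if not paired:
                mismatches += 1
        for b in range(10):
            p = 10 - b
            paired = _COMP[m[p - 1]] == seg2[b]
            if not paired:
                if p in SEED_POSITIONS:
                    ok = False
                    break
                mismatches += 1
        if ok and mismatches <= max_mismatch:
            return (j, j + site_len)
    return None


# ---------------------------------------------------------------------------
# Batch prediction
# ---------------------------------------------------------------------------


def predict_interactions(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    mirna_expr: Mapping[str, Sequence[float]] | None = None,
    transcript_expr: Mapping[str, Sequence[float]] | None = None,
    score_cutoff: float = SCORE_CUTOFF,
) -> list[MirnaInteraction]:
    """Score all miRNA x transcript pairs; keep cleavage-target candidates at
    score <= cutoff and mimic sites, attaching expression PCC when matched
    expression vectors are supplied."""
    out = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            if len(tseq) < len(mseq):
                continue
            pcc = float("nan")
            if mirna_expr is not None and transcript_expr is not None:
                if mid in mirna_expr and tid in transcript_expr:
                    pcc = expression_pcc(mirna_expr[mid], transcript_expr[tid])
            mimic_site = detect_mimic(mseq, tseq)
            if mimic_site is not None:
                out.append(
                    MirnaInteraction(mid, tid, float("nan"), *mimic_site, pcc, "mimic")
                )
                continue
            score, (s, e) = score_target(mseq, tseq)
            if score <= score_cutoff:
                out.append(MirnaInteraction(mid, tid, score, s, e, pcc, "cleavage_target"))
    return out
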