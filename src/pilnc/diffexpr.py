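"""Differential expression under Pi starvation and response-pattern clusters.

The two-group test is a negative-binomial Wald test on replicate count
vectors: library size factors by median-of-ratios, a common dispersion
pooled across transcripts by method of moments (variance model
mu + alpha*mu^2), and a two-sided normal p-value on log2 fold change with a
0.5 pseudo-count on normalized group means.  A transcript is significantly
responsive when fold change (P-/P+) > 2 or < 0.5 with p < 0.05.

Responsive transcripts are grouped into six clusters by direction and
tissue scope: induced/repressed in both tissues (1/4), roots only (2/5),
shoots only (3/6).  Transcripts significant in opposite directions in the
two tissues are set aside as discordant.

Alternative-splicing events between two isoforms of a locus are called as
retained intron (RI), alternative 3'/5' splice site (A3SS/A5SS, strand
aware) or exon skipping (ES) from the exon chains alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics_io import ExpressionMatrix, GenomicsIOError, TranscriptModel

PSEUDO_MEAN = 0.5  # pseudo-count on normalized group means for FC
FC_UP = 2.0
FC_DOWN = 0.5
P_CUTOFF = 0.05

MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    tissue: str
    base_mean: float
    fold_change: float  # P- over P+, natural scale
    log2_fc: float
    p_value: float
    padj: float
    significant: bool
    all_zero: bool = False


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (geometric-mean reference)."""
    vals = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_vals = np.log(vals)
    ref = log_vals.mean(axis=1)  # -inf where any zero
    usable = np.isfinite(ref)
    if not usable.any():
        raise GenomicsIOError("no transcript with all-positive counts for size factors")
    ratios = log_vals[usable] - ref[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def pooled_dispersion(
    norm_a: np.ndarray, norm_b: np.ndarray
) -> float:
    """Common NB dispersion by pooled method of moments.

    ``norm_a``/``norm_b`` are (transcripts x replicates) normalized counts
    for the two groups; per-transcript within-group residual variance in
    excess of the mean is pooled against mu^2.
    """
    num = 0.0
    den = 0.0
    for grp in (norm_a, norm_b):
        if grp.shape[1] < 2:
            raise GenomicsIOError("need >=2 replicates per group")
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m**2))
    if den <= 0:
        return MIN_DISPERSION
    return float(np.clip(num / den, MIN_DISPERSION, MAX_DISPERSION))


def nb_de_test(
    counts_plus: np.ndarray,
    counts_minus: np.ndarray,
    size_factors_plus: np.ndarray,
    size_factors_minus: np.ndarray,
    dispersion: float,
    transcript_id: str = "",
    tissue: str = "",
) -> DEResult:
    """NB Wald test for one transcript: P- replicates against P+ replicates."""
    counts_plus = np.asarray(counts_plus, dtype=float)
    counts_minus = np.asarray(counts_minus, dtype=float)
    if counts_plus.size < 2 or counts_minus.size < 2:
        raise GenomicsIOError("need >=2 replicates per group")
    norm_p = counts_plus / size_factors_plus
    norm_m = counts_minus / size_factors_minus
    base_mean = float(np.concatenate([norm_p, norm_m]).mean())
    if counts_plus.sum() == 0 and counts_minus.sum() == 0:
        return DEResult(transcript_id, tissue, 0.0, 1.0, 0.0, 1.0, 1.0, False, all_zero=True)
    m_p = float(norm_p.mean()) + PSEUDO_MEAN
    m_m = float(norm_m.mean()) + PSEUDO_MEAN
    fc = m_m / m_p
    log2_fc = math.log2(fc)
    # Var(k/s) = mu/s + alpha mu^2; delta method onto log2 of the group mean
    inv_s_p = float(np.mean(1.0 / size_factors_plus))
    inv_s_m = float(np.mean(1.0 / size_factors_minus))
    var_p = (m_p * inv_s_p + dispersion * m_p**2) / counts_plus.size
    var_m = (m_m * inv_s_m + dispersion * m_m**2) / counts_minus.size
    se_log2 = math.sqrt(var_p / m_p**2 + var_m / m_m**2) / math.log(2)
    wald = log2_fc / se_log2 if se_log2 > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(wald)))
    sig = (fc > FC_UP or fc < FC_DOWN) and p < P_CUTOFF
    return DEResult(transcript_id, tissue, base_mean, fc, log2_fc, p, p, sig)


def de_analysis(
    counts: ExpressionMatrix,
    tissue: str,
    polya_classes: Mapping[str, str] | None = None,
    dispersion: float | None = None,
) -> dict[str, DEResult]:
    """Test every transcript in one tissue for P-/P+ differential expression.

    Expression source is poly(A)-aware when ``polya_classes`` is given:
    poly(A)+ and bimorphic transcripts are tested on PA libraries,
    poly(A)- transcripts on NPA libraries; default is PA.  Size factors are
    estimated once per library over all transcripts; dispersion is pooled
    across transcripts unless supplied.  BH-adjusted p-values are attached.
    """
    sf = size_factors(counts.values)

    def libs_for(tid: str, condition: str) -> list[str]:
        polya = "PA"
        if polya_classes is not None and polya_classes.get(tid) == "polyA_minus":
            polya = "NPA"
        out = counts.select_libraries(tissue=tissue, condition=condition, polya=polya)
        if not out:
            raise GenomicsIOError(f"no {polya} libraries for {tissue}/{condition}")
        return out

    if dispersion is None:
        # pool over the PA libraries of the tissue (the dominant source)
        plus = counts.select_libraries(tissue=tissue, condition="P_plus", polya="PA")
        minus = counts.select_libraries(tissue=tissue, condition="P_minus", polya="PA")
        norm_p = counts.values[plus].to_numpy() / sf[plus].to_numpy()
        norm_m = counts.values[minus].to_numpy() / sf[minus].to_numpy()
        dispersion = pooled_dispersion(norm_p, norm_m)

    results: dict[str, DEResult] = {}
    for tid in counts.transcript_ids:
        lp = libs_for(tid, "P_plus")
        lm = libs_for(tid, "P_minus")
        res = nb_de_test(
            counts.values.loc[tid, lp].to_numpy(),
            counts.values.loc[tid, lm].to_numpy(),
            sf[lp].to_numpy(),
            sf[lm].to_numpy(),
            dispersion,
            transcript_id=tid,
            tissue=tissue,
        )
        results[tid] = res
    # BH adjustment across all tested transcripts
    tids = list(results)
    pvals = [results[t].p_value for t in tids]
    padj = multipletests(pvals, method="fdr_bh")[1]
    for t, q in zip(tids, padj):
        r = results[t]
        results[t] = DEResult(
            r.transcript_id, r.tissue, r.base_mean, r.fold_change, r.log2_fc,
            r.p_value, float(q), r.significant, r.all_zero,
        )
    return results


def de_table(results: Mapping[str, DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "tissue": r.tissue,
                "baseMean": r.base_mean,
                "FC": r.fold_change,
                "log2FC": r.log2_fc,
                "p": r.p_value,
                "padj": r.padj,
                "significant": r.significant,
            }
            for r in results.values()
        ]
    )


# ---------------------------------------------------------------------------
# Six response clusters
# ---------------------------------------------------------------------------

CLUSTER_LABELS = (1, 2, 3, 4, 5, 6, "unassigned", "discordant")


def _direction(r: DEResult) -> int:
    if not r.significant:
        return 0
    return 1 if r.fold_change > 1 else -1


def assign_clusters(
    root: Mapping[str, DEResult], shoot: Mapping[str, DEResult]
) -> dict[str, int | str]:
    """Map each transcript to one of the six response clusters.

    1/4: induced/repressed in both tissues; 2/5: roots only; 3/6: shoots
    only; opposite directions -> ``discordant``; neither significant ->
    ``unassigned``.
    """
    if set(root) != set(shoot):
        only = set(root) ^ set(shoot)
        raise GenomicsIOError(f"transcripts present in one tissue only: {sorted(only)[:3]}")
    out: dict[str, int | str] = {}
    for tid in root:
        dr, ds = _direction(root[tid]), _direction(shoot[tid])
        if dr == 0 and ds == 0:
            out[tid] = "unassigned"
        elif dr * ds == -1:
            out[tid] = "discordant"
        elif dr == 1 and ds == 1:
            out[tid] = 1
        elif dr == -1 and ds == -1:
            out[tid] = 4
        elif dr == 1:
            out[tid] = 2
        elif dr == -1:
            out[tid] = 5
        elif ds == 1:
            out[tid] = 3
        else:
            out[tid] = 6
    return out


# ---------------------------------------------------------------------------
# Alternative splicing events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ASEvent:
    locus_id: str
    isoform_a: str
    isoform_b: str
    event_type: str  # RI | A3SS | A5SS | ES
    chrom: str
    start: int
    end: int
    strand: str


def call_as_events(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """Call AS events between two isoforms from their exon chains.

    RI: an intron of one isoform fully inside an exon of the other (event =
    the retained intron).  A3SS/A5SS: two overlapping introns sharing the
    donor (5') or acceptor (3') site and differing at the other (event = the
    differing stretch).  ES: an internal exon of one isoform entirely within
    an intron of the other (event = the skipped exon).  Returns a
    deduplicated, position-sorted list; non-overlapping isoforms yield [].
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        raise GenomicsIOError("isoforms must share chrom and strand")
    if not (a.start < b.end and b.start < a.end):
        return []
    locus = a.gene_id if a.gene_id == b.gene_id else f"{a.gene_id}|{b.gene_id}"
    strand = a.strand
    events: set[tuple[str, int, int]] = set()

    def scan(x: TranscriptModel, y: TranscriptModel) -> None:
        x_introns = x.introns()
        y_introns = y.introns()
        # RI: intron of x inside an exon of y
        for i in x_introns:
            for e in y.exons:
                if e.start <= i.start and i.end <= e.end:
                    events.add(("RI", i.start, i.end))
        # A3SS / A5SS: overlapping introns sharing exactly one boundary
        for i in x_introns:
            for j in y_introns:
                if not (i.start < j.end and j.start < i.end):
                    continue
                if i.start == j.start and i.end != j.end:
                    lo, hi = sorted((i.end, j.end))
                    kind = "A3SS" if strand == "+" else "A5SS"
                    events.add((kind, lo, hi))
                elif i.end == j.end and i.start != j.start:
                    lo, hi = sorted((i.start, j.start))
                    kind = "A5SS" if strand == "+" else "A3SS"
                    events.add((kind, lo, hi))
        # ES: internal exon of x inside an intron of y
        for e in x.exons[1:-1]:
            for j in y_introns:
                if j.start <= e.start and e.end <= j.end:
                    events.add(("ES", e.start, e.end))

    scan(a, b)
    scan(b, a)
    return [
        ASEvent(locus, a.transcript_id, b.transcript_id, t, a.chrom, s, e, strand)
        for t, s, e in sorted(events, key=lambda ev: (ev[1], ev[2], ev[0]))
    ]
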