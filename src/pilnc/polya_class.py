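"""RPKM computation and poly(A)+ / poly(A)- / bimorphic classification.

Transcripts are classified by the ratio of their RPKM in the poly(A)+
selected (PA) libraries over the poly(A)- ribo-depleted (NPA) libraries of
the same tissue and condition: ratio >= 2 -> poly(A)+, <= 0.5 -> poly(A)-,
in between -> bimorphic.  Transcripts below an RPKM floor (default 0.1) in
every library of the full 16-library design are set aside as low-expressed
before the ratio is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics_io import ExpressionMatrix, GenomicsIOError

EPS_RPKM = 1e-6  # denominator guard; preserves the >=2 / <=0.5 calls

POLYA_CLASSES = ("polyA_plus", "polyA_minus", "bimorphic", "low_expressed")


@dataclass(frozen=True)
class PolyaCall:
    transcript_id: str
    tissue: str
    rpkm_pa: float
    rpkm_npa: float
    ratio: float
    polya_class: str


def rpkm(count: float, transcript_len_nt: float, total_mapped_reads: float) -> float:
    """RPKM = count * 1e9 / (total_mapped_reads * transcript_len_nt)."""
    if transcript_len_nt <= 0:
        raise GenomicsIOError("transcript length must be positive")
    if total_mapped_reads <= 0:
        raise GenomicsIOError("total mapped reads must be positive")
    return count * 1e9 / (total_mapped_reads * transcript_len_nt)


def rpkm_matrix(counts: ExpressionMatrix, lengths: dict[str, int]) -> ExpressionMatrix:
    """Elementwise RPKM of a count matrix using its per-library totals."""
    if counts.total_mapped_reads is None:
        raise GenomicsIOError("count matrix lacks total_mapped_reads")
    missing = [t for t in counts.transcript_ids if t not in lengths]
    if missing:
        raise GenomicsIOError(f"lengths missing for {missing[:3]}...")
    lens = np.array([lengths[t] for t in counts.transcript_ids], dtype=float)
    totals = np.array(
        [counts.total_mapped_reads[l.library_id] for l in counts.libraries], dtype=float
    )
    vals = counts.values.to_numpy() * 1e9 / (totals[None, :] * lens[:, None])
    df = pd.DataFrame(vals, index=counts.transcript_ids, columns=counts.values.columns)
    return ExpressionMatrix(df, counts.libraries, counts.total_mapped_reads)


def classify_polya(
    rpkms: ExpressionMatrix,
    tissue: str,
    condition: str = "P_plus",
    min_rpkm: float = 0.1,
) -> list[PolyaCall]:
    """Classify each transcript's polyadenylation state in one tissue.

    The low-expression floor is applied globally first (RPKM < ``min_rpkm``
    in all libraries of the matrix); PA and NPA replicate means are then
    compared for the given tissue/condition.
    """
    pa_libs = rpkms.select_libraries(tissue=tissue, condition=condition, polya="PA")
    npa_libs = rpkms.select_libraries(tissue=tissue, condition=condition, polya="NPA")
    if not pa_libs or not npa_libs:
        raise GenomicsIOError(f"missing PA or NPA libraries for {tissue}/{condition}")
    low = (rpkms.values < min_rpkm).all(axis=1)
    pa_mean = rpkms.values[pa_libs].mean(axis=1)
    npa_mean = rpkms.values[npa_libs].mean(axis=1)
    calls = []
    for tid in rpkms.transcript_ids:
        pa, npa = float(pa_mean[tid]), float(npa_mean[tid])
        if low[tid]:
            calls.append(PolyaCall(tid, tissue, pa, npa, float("nan"), "low_expressed"))
            continue
        ratio = pa / max(npa, EPS_RPKM)
        if ratio >= 2:
            cls = "polyA_plus"
        elif ratio <= 0.5:
            cls = "polyA_minus"
        else:
            cls = "bimorphic"
        calls.append(PolyaCall(tid, tissue, pa, npa, ratio, cls))
    return calls


def polya_calls_table(calls: list[PolyaCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "tissue": c.tissue,
                "RPKM_PA": c.rpkm_pa,
                "RPKM_NPA": c.rpkm_npa,
                "ratio": c.ratio,
                "class": c.polya_class,
            }
            for c in calls
        ]
    )
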