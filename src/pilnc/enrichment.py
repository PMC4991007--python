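"""Over-representation statistics: hypergeometric GO terms and 2x2 chi-square.

GO terms are supplied as a flat term -> gene map (no DAG traversal); each
term is tested with the upper-tail hypergeometric against the chosen
universe and corrected across terms by Benjamini-Hochberg.  Ratio
comparisons (motif fractions between clusters, AS-event counts) use the
Pearson chi-square on a 2x2 table without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics_io import GenomicsIOError


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # selected genes annotated to the term
    n: int  # selected genes
    K: int  # universe genes annotated to the term
    N: int  # universe size
    p_value: float
    q_value: float


def hypergeom_enrich(
    selected: Iterable[str],
    universe: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per term, BH-corrected.

    Genes outside the universe never count; a selected gene missing from the
    universe is an error.  Terms with no universe gene (K=0) are skipped.
    """
    sel = set(selected)
    uni = set(universe)
    stray = sel - uni
    if stray:
        raise GenomicsIOError(f"selected genes absent from universe: {sorted(stray)[:3]}")
    N, n = len(uni), len(sel)
    rows = []
    for term, genes in term_to_genes.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & sel)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    if not rows:
        return []
    qs = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    out = [EnrichmentResult(*r, q_value=float(q)) for r, q in zip(rows, qs)]
    out.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return out


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    low_expected: bool  # any expected cell < 1


def chi2_ratio_test(hits_a: int, total_a: int, hits_b: int, total_b: int) -> Chi2Result:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table
    comparing hits_a/total_a against hits_b/total_b."""
    if total_a <= 0 or total_b <= 0:
        raise GenomicsIOError("totals must be positive")
    if hits_a > total_a or hits_b > total_b:
        raise GenomicsIOError("hits exceed totals")
    table = [
        [hits_a, total_a - hits_a],
        [hits_b, total_b - hits_b],
    ]
    row = [sum(r) for r in table]
    col = [table[0][j] + table[1][j] for j in range(2)]
    grand = sum(row)
    stat = 0.0
    low = False
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / grand
            if e < 1:
                low = True
            if e > 0:
                stat += (table[i][j] - e) ** 2 / e
    p = float(stats.chi2.sf(stat, df=1))
    return Chi2Result(stat, p, low)


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
             "p": r.p_value, "q": r.q_value}
            for r in results
        ]
    )


def read_term_map(path) -> dict[str, set[str]]:
    """Read a 2-column TSV (term, gene) into a flat term -> genes map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(str(term), set()).add(str(gene))
    return out
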