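"""Combine precedence and connectivity rankings; assign quadrant classes.

Plotting precedence rank against connectivity rank puts the genes that
are both well precedented and well connected near the origin.  A
fractional threshold (default 20%) cuts each rank axis into top and
bottom bands; two bands get named classes:

``high_conn_high_prec``
    Top band of both rankings — the high-confidence hits.
``high_conn_low_prec``
    Top band of connectivity, bottom band of precedence — highly
    connected but understudied genes, the candidates for novel follow-up.

Everything else is ``other``.  With N genes and threshold t the band size
is k = ceil(t*N), so at least one gene qualifies for any N >= 1.
"""

from __future__ import annotations

import math

import pandas as pd

from .model import (
    QUADRANT_HIGH_HIGH,
    QUADRANT_HIGH_LOW,
    QUADRANT_OTHER,
    CombinedTable,
    InputError,
    RankTable,
)


def combine_ranks(
    precedence_ranking: pd.Series,
    connectivity_ranking: pd.Series,
    ranking_method: str = "weighted",
) -> RankTable:
    """Join the two rankings into one table, ordered by connectivity rank.

    Both rankings must cover exactly the same gene set; a mismatch is
    fatal and names the symmetric difference.
    """
    prec_genes = set(precedence_ranking.index)
    conn_genes = set(connectivity_ranking.index)
    if prec_genes != conn_genes:
        only_prec = sorted(prec_genes - conn_genes)
        only_conn = sorted(conn_genes - prec_genes)
        raise InputError(
            "rankings cover different gene sets: "
            f"precedence-only={only_prec}, connectivity-only={only_conn}"
        )
    table = pd.DataFrame(
        {
            "precedence_rank": precedence_ranking,
            "connectivity_rank": connectivity_ranking,
        }
    ).sort_values("connectivity_rank")
    table.index.name = "gene"
    return RankTable(table=table.astype(int), ranking_method=ranking_method)


def band_size(n: int, threshold: float) -> int:
    """Number of genes in each threshold band: ceil(threshold * N)."""
    return math.ceil(threshold * n)


def classify_quadrants(table: RankTable, threshold: float = 0.20) -> CombinedTable:
    """Assign each gene a quadrant class at the given rank threshold.

    With k = ceil(threshold*N): ``high_conn_high_prec`` iff both ranks
    are <= k; ``high_conn_low_prec`` iff connectivity rank <= k and
    precedence rank >= N-k+1; otherwise ``other``.  The threshold must
    lie in (0, 0.5] so the two bands cannot overlap.
    """
    if not (0 < threshold <= 0.5):
        raise InputError(f"threshold {threshold} outside (0, 0.5]")
    df = table.table.copy()
    n = len(df)
    k = band_size(n, threshold)

    def classify(row: pd.Series) -> str:
        if row["connectivity_rank"] <= k:
            if row["precedence_rank"] <= k:
                return QUADRANT_HIGH_HIGH
            if row["precedence_rank"] >= n - k + 1:
                return QUADRANT_HIGH_LOW
        return QUADRANT_OTHER

    df["quadrant_class"] = df.apply(classify, axis=1)
    return CombinedTable(
        table=df, ranking_method=table.ranking_method, threshold=threshold
    )
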