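"""Domain types shared by every pipeline stage.

The pipeline moves a hit list through four representations: the validated
:class:`GeneList` and :class:`TermList` inputs, the gene x term
:class:`LiteratureMatrix` of publication counts, the
:class:`InteractionNetwork` induced on the hit list, and the ranked /
classified tables (:class:`NetworkMetrics`, :class:`RankTable`,
:class:`CombinedTable`).  Types validate their invariants on construction
and carry no computation beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("genetriage")

QUADRANT_HIGH_HIGH = "high_conn_high_prec"
QUADRANT_HIGH_LOW = "high_conn_low_prec"
QUADRANT_OTHER = "other"

QUADRANT_CLASSES = (QUADRANT_HIGH_HIGH, QUADRANT_HIGH_LOW, QUADRANT_OTHER)


class InputError(ValueError):
    """Invalid user input (bad gene list, malformed file, bad option)."""


@dataclass(frozen=True)
class GeneList:
    """Ordered, deduplicated list of uppercased official gene symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise InputError("empty gene list")
        if any(not s or s != s.strip() for s in self.symbols):
            raise InputError("gene symbols must be non-empty and trimmed")
        if any(s != s.upper() for s in self.symbols):
            raise InputError("gene symbols must be uppercased")
        if len(set(self.symbols)) != len(self.symbols):
            raise InputError("duplicate gene symbols")

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)


@dataclass(frozen=True)
class TermList:
    """Ordered search terms; the first term has highest ranking priority."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise InputError("empty term list")
        if any(not t.strip() for t in self.terms):
            raise InputError("search terms must be non-empty")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)


def validate_gene_list(raw_symbols: Sequence[str]) -> GeneList:
    """Trim, uppercase and deduplicate raw symbols into a :class:`GeneList`.

    Duplicates (after case-folding) are dropped keeping the first
    occurrence, with a logged warning; empty strings are dropped.  An empty
    result is a fatal input error.  Idempotent: re-validating the output
    returns an identical list.
    """
    cleaned: list[str] = []
    seen: set[str] = set()
    removed = 0
    for raw in raw_symbols:
        sym = raw.strip().upper()
        if not sym:
            removed += 1
            continue
        if sym in seen:
            removed += 1
            continue
        seen.add(sym)
        cleaned.append(sym)
    if removed:
        logger.warning(
            "gene list: removed %d duplicate/empty entries (%d of %d kept)",
            removed, len(cleaned), len(raw_symbols),
        )
    if not cleaned:
        raise InputError("empty gene list")
    return GeneList(tuple(cleaned))


@dataclass(frozen=True)
class LiteratureMatrix:
    """Gene x term publication-count matrix with per-gene totals."""

    genes: GeneList
    terms: TermList
    counts: np.ndarray  # shape (|genes|, |terms|), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes), len(self.terms)):
            raise InputError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.terms)} terms"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise InputError("publication counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise InputError("publication counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def totals(self) -> np.ndarray:
        """Per-gene total publications across all terms (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by gene, one column per term."""
        df = pd.DataFrame(
            self.counts, index=list(self.genes), columns=list(self.terms)
        )
        df.index.name = "gene"
        df["total"] = self.totals
        return df


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected simple interaction graph induced on the input gene list.

    Every input gene is a node (isolated genes included); every edge joins
    two input genes and may carry a STRING combined score in [0, 1000].
    """

    genes: GeneList
    graph: nx.Graph = field(compare=False)

    def __post_init__(self) -> None:
        nodes = set(self.graph.nodes)
        symbols = set(self.genes.symbols)
        if nodes != symbols:
            missing = symbols - nodes
            extra = nodes - symbols
            raise InputError(
                f"graph node set must equal gene list "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise InputError(f"self-loops not allowed: {loops}")
        for u, v, data in self.graph.edges(data=True):
            score = data.get("score")
            if score is not None and not (0 <= score <= 1000):
                raise InputError(f"edge ({u},{v}) score {score} outside [0,1000]")

    @classmethod
    def from_edges(
        cls,
        genes: GeneList,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
    ) -> "InteractionNetwork":
        """Build a network from (u, v) or (u, v, score) tuples.

        Duplicate edges collapse keeping the highest score; self-loops are
        dropped.  Endpoints must belong to ``genes``.
        """
        g = nx.Graph()
        g.add_nodes_from(genes.symbols)
        members = set(genes.symbols)
        for edge in edges:
            u, v = edge[0], edge[1]
            score = float(edge[2]) if len(edge) > 2 else None
            if u == v:
                continue
            if u not in members or v not in members:
                raise InputError(f"edge ({u},{v}) endpoint outside gene list")
            if g.has_edge(u, v):
                prev = g.edges[u, v].get("score")
                if score is not None and (prev is None or score > prev):
                    g.edges[u, v]["score"] = score
            else:
                if score is None:
                    g.add_edge(u, v)
                else:
                    g.add_edge(u, v, score=score)
        return cls(genes, g)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class NetworkMetrics:
    """Per-gene degree and ego-network connectivity percentage."""

    table: pd.DataFrame  # index: gene; columns: degree, connectivity_pct

    def __post_init__(self) -> None:
        df = self.table
        required = {"degree", "connectivity_pct"}
        if not required.issubset(df.columns):
            raise InputError(f"metrics table needs columns {sorted(required)}")
        if (df["degree"] < 0).any():
            raise InputError("degree must be non-negative")
        bad = df[(df["degree"] == 0) & (df["connectivity_pct"] != 0)]
        if len(bad):
            raise InputError(
                f"isolated genes must have connectivity 0: {list(bad.index)}"
            )
        out_of_range = df[
            (df["connectivity_pct"] < 0) | (df["connectivity_pct"] > 100)
        ]
        if len(out_of_range):
            raise InputError("connectivity_pct outside [0, 100]")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def _check_rank_columns(df: pd.DataFrame, columns: Sequence[str]) -> None:
    n = len(df)
    for col in columns:
        ranks = sorted(df[col])
        if ranks != list(range(1, n + 1)):
            raise InputError(f"{col} is not a permutation of 1..{n}")


@dataclass(frozen=True)
class RankTable:
    """Per-gene precedence and connectivity ranks (strict, 1..N)."""

    table: pd.DataFrame  # index: gene; columns: precedence_rank, connectivity_rank
    ranking_method: str  # "weighted" | "total"

    def __post_init__(self) -> None:
        if self.ranking_method not in ("weighted", "total"):
            raise InputError(f"unknown ranking method {self.ranking_method!r}")
        required = {"precedence_rank", "connectivity_rank"}
        if not required.issubset(self.table.columns):
            raise InputError(f"rank table needs columns {sorted(required)}")
        _check_rank_columns(self.table, ["precedence_rank", "connectivity_rank"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class CombinedTable:
    """Rank table plus quadrant class assignments at a given threshold."""

    table: pd.DataFrame  # adds column quadrant_class
    ranking_method: str
    threshold: float

    def __post_init__(self) -> None:
        if not (0 < self.threshold <= 0.5):
            raise InputError(
                f"threshold {self.threshold} outside (0, 0.5]"
            )
        if "quadrant_class" not in self.table.columns:
            raise InputError("combined table needs column quadrant_class")
        _check_rank_columns(self.table, ["precedence_rank", "connectivity_rank"])
        unknown = set(self.table["quadrant_class"]) - set(QUADRANT_CLASSES)
        if unknown:
            raise InputError(f"unknown quadrant classes {sorted(unknown)}")
        n = len(self.table)
        k = int(np.ceil(self.threshold * n))
        vc = self.table["quadrant_class"].value_counts()
        for cls in (QUADRANT_HIGH_HIGH, QUADRANT_HIGH_LOW):
            if vc.get(cls, 0) > k:
                raise InputError(f"{cls} has more than ceil(threshold*N)={k} members")

    def __len__(self) -> int:
        return len(self.table)

    def class_counts(self) -> Mapping[str, int]:
        vc = self.table["quadrant_class"].value_counts()
        return {cls: int(vc.get(cls, 0)) for cls in QUADRANT_CLASSES}
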