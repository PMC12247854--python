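"""Interaction network: STRING fetch / edge-list load, degree, connectivity.

The network is the subgraph of STRING interactions induced on the input
gene list — only edges between two input genes count, and the graph is
never expanded with external neighbours.  Two per-gene metrics drive the
connectivity ranking:

degree
    Number of interactions within the hit list.
connectivity
    Percentage of existing edges relative to the theoretical maximum in
    the gene's ego network (the subgraph spanned by the gene and its
    neighbours): with degree ``k`` and ``E_ego`` edges among the ``k+1``
    ego nodes, connectivity is ``100 * E_ego / (k*(k+1)/2)``.  Isolated
    genes get 0 by convention; degree-1 genes get 100 (one edge out of
    one possible).  This differs from the textbook local clustering
    coefficient, which excludes the centre node (a path-middle node has
    ego connectivity 66.7% but clustering 0); the textbook variant is
    available via ``method="clustering"``.

Metrics are computed on the unweighted graph after score thresholding;
edge confidence scores never weight them.
"""

from __future__ import annotations

import json
import logging
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import networkx as nx
import pandas as pd

from .model import GeneList, InputError, InteractionNetwork, NetworkMetrics

logger = logging.getLogger("genetriage")

STRING_API_BASE = "https://string-db.org/api"

#: STRING "medium confidence" combined-score cutoff.
DEFAULT_SCORE_THRESHOLD = 400


class ServiceError(RuntimeError):
    """STRING service failure after retries."""


Transport = Callable[[str, bytes | None], bytes]
"""(url, POST body or None) -> response body."""


def _default_transport(url: str, data: bytes | None = None) -> bytes:
    with urllib.request.urlopen(url, data=data, timeout=60) as resp:
        return resp.read()


@dataclass
class StringFetchConfig:
    """How to query the STRING API for a species' interaction network."""

    species_taxon: int = 9606
    score_threshold: int = DEFAULT_SCORE_THRESHOLD
    endpoint: str = STRING_API_BASE
    transport: Transport = field(default=_default_transport, repr=False)
    cache_path: Path | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.score_threshold <= 1000):
            raise InputError(
                f"score threshold {self.score_threshold} outside [0, 1000]"
            )


def fetch_string_network(
    genes: GeneList, config: StringFetchConfig
) -> InteractionNetwork:
    """Fetch the STRING network induced on ``genes`` for one species.

    The node set always equals the input gene list: genes STRING does not
    recognise become isolated nodes with a logged warning, and only edges
    joining two input genes (at or above the combined-score threshold)
    are kept.  Responses are cached to ``config.cache_path`` when set so
    a rerun is offline.
    """
    raw = _string_network_tsv(genes, config)
    edges: list[tuple[str, str, float]] = []
    members = set(genes.symbols)
    unmatched_edges = 0
    for row in raw:
        a, b, score = row
        a, b = a.upper(), b.upper()
        if a not in members or b not in members:
            unmatched_edges += 1
            continue
        if score < config.score_threshold:
            continue
        edges.append((a, b, score))
    if unmatched_edges:
        logger.info("dropped %d STRING edges outside the gene list", unmatched_edges)
    network = InteractionNetwork.from_edges(genes, edges)
    isolated = [g for g in genes if network.graph.degree[g] == 0]
    if isolated:
        logger.warning(
            "%d genes have no qualifying STRING interaction: %s",
            len(isolated), ", ".join(isolated),
        )
    return network


def _string_network_tsv(
    genes: GeneList, config: StringFetchConfig
) -> list[tuple[str, str, float]]:
    """Call the STRING ``network`` endpoint; return (geneA, geneB, score) rows.

    STRING reports the combined score as a 0-1 float; it is rescaled to the
    conventional 0-1000 integer range.  A cached response is reused when
    present.
    """
    cache_file = None
    if config.cache_path is not None:
        key = f"{config.species_taxon}-{len(genes)}-{hash(genes.symbols) & 0xFFFFFFFF:x}"
        cache_file = Path(config.cache_path) / f"string-{key}.json"
        if cache_file.exists():
            logger.info("STRING response served from cache %s", cache_file)
            return [tuple(row) for row in json.loads(cache_file.read_text())]
    url = f"{config.endpoint}/tsv-no-header/network"
    body = urllib.parse.urlencode(
        {
            "identifiers": "%0d".join(genes.symbols),
            "species": config.species_taxon,
            "caller_identity": "genetriage",
        }
    ).encode()
    last_error: Exception | None = None
    for attempt in range(3):
        try:
            payload = config.transport(url, body)
            break
        except (urllib.error.URLError, OSError) as exc:
            last_error = exc
    else:
        raise ServiceError(
            f"STRING request failed after retries ({last_error}); "
            "supply a local network with --edges-file"
        )
    rows: list[tuple[str, str, float]] = []
    for line in payload.decode().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        # tsv-no-header/network: preferredName_A/B at cols 2-3, score at col 5
        a, b, score = parts[2], parts[3], float(parts[5]) * 1000
        rows.append((a, b, score))
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(json.dumps(rows))
    return rows


def load_edge_list(
    path: Path,
    genes: GeneList,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
) -> InteractionNetwork:
    """Load a local TSV edge list (``geneA geneB score``) induced on ``genes``.

    Offline counterpart of :func:`fetch_string_network` with the same
    contract: the score column is optional (default 1000), self-loops are
    dropped, symmetric/duplicate edges collapse keeping the maximum
    score, edges touching genes outside the list are dropped with a
    logged count, and edges below the threshold are excluded.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"edge-list file not found: {path}")
    members = set(genes.symbols)
    edges: list[tuple[str, str, float]] = []
    dropped_external = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise InputError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
        a, b = parts[0].strip().upper(), parts[1].strip().upper()
        if lineno == 1 and (a, b) == ("GENEA", "GENEB"):
            continue  # header row
        if len(parts) == 3:
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: bad score {parts[2]!r}") from exc
        else:
            score = 1000.0
        if not a or not b:
            raise InputError(f"{path}:{lineno}: empty gene symbol")
        if a == b:
            continue
        if a not in members or b not in members:
            dropped_external += 1
            continue
        if score < score_threshold:
            continue
        edges.append((a, b, score))
    if dropped_external:
        logger.info(
            "dropped %d edges touching genes outside the input list",
            dropped_external,
        )
    return InteractionNetwork.from_edges(genes, edges)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_degree(network: InteractionNetwork, gene: str) -> int:
    """Number of interactions of ``gene`` within the hit list."""
    if gene not in network.graph:
        raise InputError(f"unknown gene {gene!r}")
    return int(network.graph.degree[gene])


def compute_connectivity(
    network: InteractionNetwork, gene: str, method: str = "ego"
) -> float:
    """Connectivity percentage of ``gene``'s ego network.

    ``method="ego"`` (default): 100 * E_ego / (k*(k+1)/2) over the node
    plus its neighbours.  ``method="clustering"``: textbook local
    clustering coefficient as a percentage (neighbours only).
    """
    g = network.graph
    if gene not in g:
        raise InputError(f"unknown gene {gene!r}")
    if method == "clustering":
        return 100.0 * nx.clustering(g, gene)
    if method != "ego":
        raise InputError(f"unknown connectivity method {method!r}")
    k = g.degree[gene]
    if k == 0:
        return 0.0
    nbrs = sorted(g[gene])
    ego_edges = k + sum(
        1
        for i, u in enumerate(nbrs)
        for v in nbrs[i + 1 :]
        if g.has_edge(u, v)
    )
    max_edges = (k + 1) * k // 2
    return 100.0 * ego_edges / max_edges


def compute_metrics(
    network: InteractionNetwork, method: str = "ego"
) -> NetworkMetrics:
    """Degree and connectivity for every gene, in gene-list order."""
    rows = {
        gene: (
            compute_degree(network, gene),
            compute_connectivity(network, gene, method=method),
        )
        for gene in network.genes
    }
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["degree", "connectivity_pct"]
    )
    table.index.name = "gene"
    return NetworkMetrics(table)


def rank_network(metrics: NetworkMetrics) -> tuple[pd.Series, pd.DataFrame]:
    """Rank genes by network connectivity; rank 1 is the most connected.

    Sort key: descending degree, then descending connectivity percentage,
    remaining ties alphabetical.  Returns the gene -> rank mapping and the
    sorted table (degree, connectivity_pct, connectivity_rank).
    """
    df = metrics.table.copy()
    order = sorted(
        df.index,
        key=lambda g: (-df.at[g, "degree"], -df.at[g, "connectivity_pct"], g),
    )
    ranks = pd.Series(
        {g: i for i, g in enumerate(order, start=1)}, name="connectivity_rank"
    ).reindex(df.index)
    ranks.index.name = "gene"
    sorted_table = df.loc[order].copy()
    sorted_table["connectivity_rank"] = range(1, len(order) + 1)
    return ranks.astype(int), sorted_table
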