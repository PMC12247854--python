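"""Literature precedence: PubMed co-occurrence counts and precedence ranking.

Precedence is measured by cross-searching every gene symbol against each
user search term in PubMed title/abstract text and recording the hit count
per (gene, term) pair.  Counts come either live from the NCBI E-utilities
``esearch`` endpoint (count-only retrieval, rate-limited, retried, cached
on disk) or from a cached/fixture count table for offline runs.

Genes are then ranked by precedence with one of two methods:

``weighted``
    Lexicographic sort on the per-term counts in the user-given term
    order: descending count for term 1, ties by term 2, and so on, final
    ties broken alphabetically.  This lets a specific term dominate the
    ranking while broader terms only break ties.
``total``
    Descending total count across all terms, ties alphabetical.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .model import GeneList, InputError, LiteratureMatrix, TermList

logger = logging.getLogger("genetriage")

# Bump when the query template changes: cache entries are keyed on it so a
# template change invalidates previously fetched counts.
QUERY_TEMPLATE_VERSION = "tiab-v1"

EUTILS_ESEARCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

#: NCBI E-utilities documented limits: 3 req/s anonymous, 10 with an API key.
RATE_LIMIT_NO_KEY = 3.0
RATE_LIMIT_WITH_KEY = 10.0

MAX_RETRIES = 3
BACKOFF_BASE_S = 0.5

#: Status codes worth retrying (throttling and transient server failures).
RETRYABLE_STATUS = frozenset({429, 500, 502, 503, 504})


class FetchError(RuntimeError):
    """Transport failure after retries, with gene/term context."""


@dataclass(frozen=True)
class QuerySpec:
    """A rendered PubMed query for one (gene, term) pair."""

    gene: str
    term: str
    rendered_query: str


def build_query(gene: str, term: str, field_tag: str = "tiab") -> QuerySpec:
    """Render the PubMed query for a (gene, term) pair.

    Both the gene symbol and the term are exact quoted phrases restricted
    to the title/abstract fields by default (``[tiab]``); hyphens and
    internal spaces survive inside the quotes.  ``field_tag`` may be set
    to e.g. ``"all"`` to search all fields instead.
    """
    gene = gene.strip()
    term = term.strip()
    if not gene or not term:
        raise InputError("gene and term must be non-empty")
    rendered = f'"{gene}"[{field_tag}] AND "{term}"[{field_tag}]'
    return QuerySpec(gene=gene, term=term, rendered_query=rendered)


# ---------------------------------------------------------------------------
# Count cache (plain JSON on disk, keyed gene|term|template-version)
# ---------------------------------------------------------------------------

def _cache_key(gene: str, term: str) -> str:
    return f"{gene}\t{term}\t{QUERY_TEMPLATE_VERSION}"


class CountCache:
    """On-disk JSON cache of (gene, term) hit counts.

    Entries never expire: PubMed counts drift over time, so reproducing a
    run requires pinning the cache, not refreshing it.
    """

    def __init__(self, path: Path | None = None):
        self.path = Path(path) if path else None
        self._data: dict[str, int] = {}
        if self.path and self.path.exists():
            self._data = json.loads(self.path.read_text())

    def get(self, gene: str, term: str) -> int | None:
        return self._data.get(_cache_key(gene, term))

    def put(self, gene: str, term: str, count: int) -> None:
        self._data[_cache_key(gene, term)] = int(count)
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text(json.dumps(self._data, sort_keys=True, indent=0))

    def __len__(self) -> int:
        return len(self._data)


def read_counts_table(path: Path) -> dict[tuple[str, str], int]:
    """Read a cached counts file: TSV ``gene<TAB>term<TAB>count`` or JSON.

    The JSON form is ``{gene: {term: count}}``.  Symbols are uppercased to
    match gene-list normalization.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"counts file not found: {path}")
    counts: dict[tuple[str, str], int] = {}
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for gene, row in payload.items():
            for term, count in row.items():
                counts[(gene.strip().upper(), term)] = int(count)
        return counts
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if lineno == 1 and parts[:3] == ["gene", "term", "count"]:
            continue
        if len(parts) != 3:
            raise InputError(f"{path}:{lineno}: expected 3 tab-separated fields")
        gene, term, raw = parts
        try:
            counts[(gene.strip().upper(), term)] = int(raw)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: bad count {raw!r}") from exc
    return counts


def write_counts_table(counts: Mapping[tuple[str, str], int], path: Path) -> None:
    """Write counts in the TSV exchange format (``--export-counts``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["gene\tterm\tcount"]
    for (gene, term), count in sorted(counts.items()):
        lines.append(f"{gene}\t{term}\t{count}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Live E-utilities client
# ---------------------------------------------------------------------------

Transport = Callable[[str], bytes]
"""Maps a URL to the response body; raises urllib.error.HTTPError on 4xx/5xx."""


def _default_transport(url: str) -> bytes:
    with urllib.request.urlopen(url, timeout=30) as resp:
        return resp.read()


class RateLimiter:
    """Enforce a minimum interval between consecutive requests."""

    def __init__(self, per_second: float, clock=time.monotonic, sleep=time.sleep):
        self.interval = 1.0 / per_second
        self._clock = clock
        self._sleep = sleep
        self._last: float | None = None

    def wait(self) -> None:
        now = self._clock()
        if self._last is not None:
            remaining = self._last + self.interval - now
            if remaining > 0:
                self._sleep(remaining)
                now = self._clock()
        self._last = now


@dataclass
class CountSource:
    """Where (gene, term) counts come from: live E-utilities or a cached table.

    Live mode hits the network; cached mode requires a complete gene x term
    table covering every requested pair.  ``transport`` is injectable so
    tests can simulate the server.
    """

    mode: str  # "live" | "cached"
    cached_counts: Mapping[tuple[str, str], int] | None = None
    cache: CountCache | None = None
    api_key: str | None = None
    email: str | None = None
    field_tag: str = "tiab"
    transport: Transport = field(default=_default_transport, repr=False)
    sleep: Callable[[float], None] = field(default=time.sleep, repr=False)
    rate_limit: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("live", "cached"):
            raise InputError(f"unknown count source mode {self.mode!r}")
        if self.mode == "cached" and self.cached_counts is None:
            raise InputError("cached mode requires a counts table")
        if self.rate_limit is None:
            self.rate_limit = (
                RATE_LIMIT_WITH_KEY if self.api_key else RATE_LIMIT_NO_KEY
            )
        self._limiter = RateLimiter(self.rate_limit, sleep=self.sleep)

    @classmethod
    def from_counts_file(cls, path: Path) -> "CountSource":
        return cls(mode="cached", cached_counts=read_counts_table(path))

    def esearch_url(self, query: QuerySpec) -> str:
        params = {
            "db": "pubmed",
            "term": query.rendered_query,
            "rettype": "count",
            "retmode": "json",
        }
        if self.api_key:
            params["api_key"] = self.api_key
        if self.email:
            params["email"] = self.email
        return EUTILS_ESEARCH_URL + "?" + urllib.parse.urlencode(params)


def _fetch_live(query: QuerySpec, source: CountSource) -> int:
    url = source.esearch_url(query)
    last_error: Exception | None = None
    for attempt in range(MAX_RETRIES + 1):
        if attempt:
            delay = BACKOFF_BASE_S * 2 ** (attempt - 1)
            logger.info(
                "retry %d for (%s, %s) after %.1fs", attempt, query.gene,
                query.term, delay,
            )
            source.sleep(delay)
        source._limiter.wait()
        try:
            body = source.transport(url)
            payload = json.loads(body)
            return int(payload["esearchresult"]["count"])
        except urllib.error.HTTPError as exc:
            last_error = exc
            if exc.code not in RETRYABLE_STATUS:
                break
        except (urllib.error.URLError, OSError, KeyError, ValueError) as exc:
            last_error = exc
    raise FetchError(
        f"PubMed count fetch failed for gene={query.gene!r} "
        f"term={query.term!r} after {MAX_RETRIES} retries: {last_error}"
    )


def fetch_count(query: QuerySpec, source: CountSource) -> int:
    """Return the PubMed hit count for one (gene, term) query.

    Live mode asks E-utilities for the count only (no record bodies) and
    writes the result to the on-disk cache; cached mode is a lookup that
    fails fast naming the missing pair.
    """
    if source.cache is not None:
        hit = source.cache.get(query.gene, query.term)
        if hit is not None:
            logger.debug("cache hit (%s, %s) = %d", query.gene, query.term, hit)
            return hit
    if source.mode == "cached":
        assert source.cached_counts is not None
        key = (query.gene, query.term)
        if key not in source.cached_counts:
            raise InputError(
                f"counts table is missing pair {key}; cached mode requires "
                "a complete gene x term table"
            )
        return int(source.cached_counts[key])
    count = _fetch_live(query, source)
    if source.cache is not None:
        source.cache.put(query.gene, query.term, count)
    return count


def build_literature_matrix(
    genes: GeneList, terms: TermList, source: CountSource
) -> LiteratureMatrix:
    """Fill the complete |genes| x |terms| count matrix from ``source``.

    In cached mode every missing pair is collected and reported at once.
    In live mode each fetched count lands in the on-disk cache as it
    arrives, so an interrupted run resumes where it stopped.
    """
    missing: list[tuple[str, str]] = []
    counts = np.zeros((len(genes), len(terms)), dtype=np.int64)
    done = 0
    for i, gene in enumerate(genes):
        for j, term in enumerate(terms):
            query = build_query(gene, term, field_tag=source.field_tag)
            try:
                counts[i, j] = fetch_count(query, source)
            except InputError:
                missing.append((gene, term))
                continue
            done += 1
    if missing:
        raise InputError(
            f"counts source is missing {len(missing)} (gene, term) pairs "
            f"(completed {done}): {missing}"
        )
    return LiteratureMatrix(genes=genes, terms=terms, counts=counts)


# ---------------------------------------------------------------------------
# Precedence ranking
# ---------------------------------------------------------------------------

def rank_precedence(matrix: LiteratureMatrix, method: str = "weighted") -> pd.Series:
    """Rank genes by literature precedence; returns gene -> rank (1..N).

    Rank 1 is the most precedented gene.  Ranks are strict: every tie is
    broken, ultimately alphabetically on the symbol, so the output is
    always a permutation of 1..N.
    """
    if method not in ("weighted", "total"):
        raise InputError(f"unknown ranking method {method!r}")
    symbols = list(matrix.genes)
    if method == "weighted":
        keys = [
            tuple(-int(c) for c in matrix.counts[i]) + (symbols[i],)
            for i in range(len(symbols))
        ]
    else:
        totals = matrix.totals
        keys = [(-int(totals[i]), symbols[i]) for i in range(len(symbols))]
    order = sorted(range(len(symbols)), key=lambda i: keys[i])
    ranks = pd.Series(0, index=pd.Index(symbols, name="gene"), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks.iloc[i] = rank
    return ranks
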