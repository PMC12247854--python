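"""Literature stage: query rendering, count sourcing, precedence ranking."""

import json
import urllib.error

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from genetriage import (
    CountCache,
    CountSource,
    FetchError,
    GeneList,
    InputError,
    LiteratureMatrix,
    TermList,
    build_literature_matrix,
    build_query,
    fetch_count,
    rank_precedence,
    read_counts_table,
    write_counts_table,
)


class TestBuildQuery:
    def test_quoted_phrases_restricted_to_title_abstract(self):
        q = build_query("CD40", "cancer")
        assert q.rendered_query == '"CD40"[tiab] AND "cancer"[tiab]'

    def test_hyphen_and_space_survive_inside_quotes(self):
        q = build_query("HLA-B", "checkpoint blockade")
        assert '"HLA-B"' in q.rendered_query
        assert '"checkpoint blockade"' in q.rendered_query

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            build_query("", "cancer")
        with pytest.raises(InputError):
            build_query("CD40", "   ")

    def test_field_tag_configurable(self):
        q = build_query("CD40", "cancer", field_tag="all")
        assert "[all]" in q.rendered_query and "[tiab]" not in q.rendered_query


def _response(count: int) -> bytes:
    return json.dumps({"esearchresult": {"count": str(count)}}).encode()


class TestFetchCount:
    def test_cached_passthrough_and_missing_pair(self):
        source = CountSource(mode="cached", cached_counts={("TP53", "cancer"): 5123})
        assert fetch_count(build_query("TP53", "cancer"), source) == 5123
        with pytest.raises(InputError, match=r"\('TP53', 'fibrosis'\)"):
            fetch_count(build_query("TP53", "fibrosis"), source)

    def test_live_retries_transient_429_then_succeeds(self):
        calls = []

        def transport(url):
            calls.append(url)
            if len(calls) == 1:
                raise urllib.error.HTTPError(url, 429, "Too Many Requests", {}, None)
            return _response(17)

        source = CountSource(mode="live", transport=transport, sleep=lambda s: None)
        assert fetch_count(build_query("CD40", "cancer"), source) == 17
        assert len(calls) == 2

    def test_live_gives_up_after_retries(self):
        def transport(url):
            raise urllib.error.HTTPError(url, 503, "unavailable", {}, None)

        source = CountSource(mode="live", transport=transport, sleep=lambda s: None)
        with pytest.raises(FetchError, match="CD40"):
            fetch_count(build_query("CD40", "cancer"), source)

    def test_non_retryable_http_error_fails_fast(self):
        calls = []

        def transport(url):
            calls.append(url)
            raise urllib.error.HTTPError(url, 400, "bad request", {}, None)

        source = CountSource(mode="live", transport=transport, sleep=lambda s: None)
        with pytest.raises(FetchError):
            fetch_count(build_query("CD40", "cancer"), source)
        assert len(calls) == 1

    def test_rate_limiter_spaces_requests(self):
        sleeps = []
        source = CountSource(
            mode="live",
            transport=lambda url: _response(1),
            sleep=sleeps.append,
            rate_limit=2.0,
        )
        for _ in range(3):
            fetch_count(build_query("CD40", "cancer"), source)
        # 2nd and 3rd requests must each wait close to the 0.5 s interval
        assert len(sleeps) == 2
        assert all(0 < s <= 0.5 for s in sleeps)

    def test_api_key_raises_rate_limit_and_is_sent(self):
        seen = []
        source = CountSource(
            mode="live", api_key="KEY123", transport=lambda u: (seen.append(u), _response(0))[1],
            sleep=lambda s: None,
        )
        assert source.rate_limit == 10.0
        fetch_count(build_query("CD40", "cancer"), source)
        assert "api_key=KEY123" in seen[0]

    def test_count_only_request(self):
        seen = []
        source = CountSource(
            mode="live", transport=lambda u: (seen.append(u), _response(0))[1],
            sleep=lambda s: None,
        )
        fetch_count(build_query("CD40", "cancer"), source)
        assert "rettype=count" in seen[0]

    def test_disk_cache_hit_skips_transport(self, tmp_path):
        cache = CountCache(tmp_path / "cache.json")
        calls = []

        def transport(url):
            calls.append(url)
            return _response(42)

        source = CountSource(mode="live", cache=cache, transport=transport,
                             sleep=lambda s: None)
        q = build_query("CD40", "cancer")
        assert fetch_count(q, source) == 42
        # reload cache from disk; transport now fails, count must come from cache
        reloaded = CountSource(
            mode="live",
            cache=CountCache(tmp_path / "cache.json"),
            transport=lambda u: (_ for _ in ()).throw(OSError("offline")),
            sleep=lambda s: None,
        )
        assert fetch_count(q, reloaded) == 42
        assert len(calls) == 1


class TestBuildMatrix:
    def test_row_totals(self):
        counts = {("A", "t1"): 1, ("A", "t2"): 2, ("B", "t1"): 3, ("B", "t2"): 4}
        source = CountSource(mode="cached", cached_counts=counts)
        m = build_literature_matrix(GeneList(("A", "B")), TermList(("t1", "t2")), source)
        assert list(m.totals) == [3, 7]

    def test_all_zero_matrix_is_valid(self):
        counts = {(g, t): 0 for g in ("A", "B") for t in ("t1",)}
        source = CountSource(mode="cached", cached_counts=counts)
        m = build_literature_matrix(GeneList(("A", "B")), TermList(("t1",)), source)
        assert m.totals.sum() == 0

    def test_missing_pair_is_fatal_and_named(self):
        counts = {("A", "t1"): 1, ("B", "t1"): 2}
        source = CountSource(mode="cached", cached_counts=counts)
        with pytest.raises(InputError, match=r"\('C', 't1'\)"):
            build_literature_matrix(GeneList(("A", "B", "C")), TermList(("t1",)), source)


class TestCountsFileFormats:
    def test_tsv_round_trip(self, tmp_path):
        counts = {("CD40", "cancer"): 12, ("FAS", "immunology"): 7}
        path = tmp_path / "counts.tsv"
        write_counts_table(counts, path)
        assert read_counts_table(path) == counts

    def test_json_format(self, tmp_path):
        path = tmp_path / "counts.json"
        path.write_text(json.dumps({"cd40": {"cancer": 3}}))
        assert read_counts_table(path) == {("CD40", "cancer"): 3}

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tterm\tcount\nCD40\tcancer\n")
        with pytest.raises(InputError, match=":2"):
            read_counts_table(path)


class TestRankPrecedence:
    def test_weighted_is_lexicographic_on_term_order(self, small_matrix):
        ranks = rank_precedence(small_matrix, "weighted")
        assert dict(ranks) == {"G3": 1, "G1": 2, "G2": 3}

    def test_total_sorts_by_row_sum(self, small_matrix):
        ranks = rank_precedence(small_matrix, "total")
        assert dict(ranks) == {"G2": 1, "G3": 2, "G1": 3}

    def test_all_zero_falls_back_to_alphabetical(self):
        m = LiteratureMatrix(
            GeneList(("C", "A", "B")), TermList(("t",)), np.zeros((3, 1), dtype=int)
        )
        for method in ("weighted", "total"):
            assert dict(rank_precedence(m, method)) == {"A": 1, "B": 2, "C": 3}

    def test_unknown_method_rejected(self, small_matrix):
        with pytest.raises(InputError):
            rank_precedence(small_matrix, "median")


@st.composite
def count_matrices(draw, max_genes=8, max_terms=4):
    n = draw(st.integers(1, max_genes))
    t = draw(st.integers(1, max_terms))
    counts = draw(arrays(np.int64, (n, t), elements=st.integers(0, 50)))
    genes = GeneList(tuple(f"G{i:02d}" for i in range(n)))
    terms = TermList(tuple(f"t{j}" for j in range(t)))
    return LiteratureMatrix(genes, terms, counts)


class TestRankingProperties:
    @settings(derandomize=True, max_examples=100)
    @given(count_matrices(), st.sampled_from(["weighted", "total"]))
    def test_output_is_permutation(self, matrix, method):
        ranks = rank_precedence(matrix, method)
        assert sorted(ranks) == list(range(1, len(matrix.genes) + 1))

    @settings(derandomize=True, max_examples=100)
    @given(count_matrices(max_terms=1))
    def test_single_term_weighted_equals_total(self, matrix):
        assert rank_precedence(matrix, "weighted").equals(
            rank_precedence(matrix, "total")
        )

    @settings(derandomize=True, max_examples=100)
    @given(count_matrices(), st.randoms(use_true_random=False))
    def test_gene_order_permutation_invariance(self, matrix, rnd):
        idx = list(range(len(matrix.genes)))
        rnd.shuffle(idx)
        shuffled = LiteratureMatrix(
            GeneList(tuple(matrix.genes.symbols[i] for i in idx)),
            matrix.terms,
            matrix.counts[idx],
        )
        for method in ("weighted", "total"):
            a = rank_precedence(matrix, method)
            b = rank_precedence(shuffled, method)
            assert dict(a) == dict(b)

    @settings(derandomize=True, max_examples=60)
    @given(count_matrices(max_terms=3), st.integers(0, 10 ** 6))
    def test_weighted_ignores_later_terms_when_first_distinct(self, matrix, salt):
        counts = matrix.counts.copy()
        n = len(matrix.genes)
        counts[:, 0] = np.arange(n) * 7 + 1  # force distinct first-term counts
        base = LiteratureMatrix(matrix.genes, matrix.terms, counts)
        perturbed_counts = counts.copy()
        if counts.shape[1] > 1:
            rng = np.random.default_rng(salt)
            perturbed_counts[:, 1:] = rng.integers(0, 100, counts[:, 1:].shape)
        perturbed = LiteratureMatrix(matrix.genes, matrix.terms, perturbed_counts)
        assert rank_precedence(base, "weighted").equals(
            rank_precedence(perturbed, "weighted")
        )
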