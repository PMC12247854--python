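# Methods

## The procedure

`genetriage` ranks a validated gene list G (N genes) along two
independent axes and combines the ranks.

**Precedence.** For each gene g and search term t the tool records
c(g, t), the number of PubMed records matching the query
`"g"[tiab] AND "t"[tiab]` — both as exact quoted phrases restricted to
title/abstract fields.  Two rankings are offered:

* *weighted* (default): sort genes by descending c(·, t₁); break ties by
  c(·, t₂), then t₃, …, in the user-given term order; final ties break
  alphabetically on the symbol.  This is a lexicographic order, so a
  change in a later term's counts can never overturn a strict difference
  on an earlier term — the property that lets a highly specific first
  term control the ranking while broad context terms only discriminate
  among its ties.
* *total*: sort by descending Σ_t c(g, t), ties alphabetical.

Both produce strict ranks 1..N (rank 1 = most precedented).

**Connectivity.** The interaction network is the subgraph of STRING
interactions induced on G: every input gene is a node (unrecognised
genes stay as isolated nodes), and only edges joining two input genes
with combined score ≥ the threshold (default 400, STRING's medium
confidence) are kept.  Metrics are computed on the unweighted thresholded
graph.  For a gene with degree k and E_ego edges in its ego network
({g} ∪ N(g), so E_ego = k + edges among neighbours):

    connectivity(g) = 100 · E_ego / (k(k+1)/2)   (k ≥ 1)
    connectivity(g) = 0                           (k = 0)

Genes are ranked by descending degree, then descending connectivity,
ties alphabetical — a hub in a dense neighbourhood outranks an equally
dense node with fewer partners.

**Combination.** With band size k = ⌈tN⌉ at threshold t ∈ (0, 0.5]
(default 0.20):

* `high_conn_high_prec`: connectivity rank ≤ k and precedence rank ≤ k;
* `high_conn_low_prec`: connectivity rank ≤ k and precedence rank ≥ N−k+1;
* `other`: everything else.

When t = 0.5 and N is small the two bands can overlap on the precedence
axis; the high-precedence class wins.  The ceiling guarantees at least
one gene qualifies for any N ≥ 1, and each named class is bounded by k.

## Choice of the connectivity definition

The ego-network formula above includes the centre node and its spokes.
The textbook local clustering coefficient excludes them
(100·2E_nb/(k(k−1)), neighbours only), and the two disagree sharply —
the middle of a path scores 66.7% versus 0%.  The ego reading follows
the method's plain description ("the subnetwork comprised of the node
and its neighbours"); the clustering variant remains available through
`compute_connectivity(..., method="clustering")` and the CLI's
`--connectivity-method` flag for comparison.  Two consequences of the
ego convention are documented rather than hidden: an isolated gene
scores 0 (degenerate case, no possible edges involving it are defined),
and a degree-1 gene scores 100 (one edge out of one possible).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| ranking method | weighted | precedence sort (see above) |
| quadrant threshold | 0.20 | band fraction t; valid range (0, 0.5] |
| STRING score threshold | 400 | combined-score cutoff, 0–1000 scale |
| species taxon | 9606 | NCBI taxonomy ID for STRING queries |
| query field tag | `tiab` | PubMed field restriction; configurable because all-field counts differ |
| rate limit | 3/s (10/s with API key) | documented NCBI E-utilities limits; 3 retries with exponential backoff on 429/5xx |

Counts are cached on disk keyed by (gene, term, query-template version)
with no expiry: PubMed counts drift, so a pinned cache — exportable and
re-importable as a `gene⇥term⇥count` TSV — is the reproducibility unit.

## Synthetic data

The fixture generator emulates the two external inputs offline:

* **Networks**: Erdős–Rényi G(n, p), or a planted-clique model — a fully
  connected subset of ⌈0.2n⌉ genes (a seeded random draw, not a prefix)
  over a sparse background (p = 0.05 by default).  Edges carry a
  STRING-style score of 900.
* **Counts**: negative binomial with mean 5 and gamma-shape dispersion 5
  per (gene, term) pair — publication counts are strongly overdispersed,
  and at these parameters the variance is roughly double the mean.
  Planted genes draw their first-term counts with the mean multiplied by
  50, mimicking a field's marquee genes.  As dispersion → ∞ the model
  collapses to Poisson (checked in the tests).

Planting the same genes as clique members and first-term outliers gives
the end-to-end recovery check: across 20 seeds at n = 50 the pipeline
classifies essentially all planted genes `high_conn_high_prec`.  What
this does *not* show: real PubMed counts correlate with real STRING
degree (well-studied genes are both cited and annotated more), gene
symbols collide with English words in abstracts, and STRING evidence
channels differ in reliability — none of which the generator models.
Passing fixtures therefore validates the ranking and classification
machinery, not literature-mining accuracy on real text.

## Numerical and design choices

* **Strict ranks.**  Every ranking is a permutation of 1..N with
  alphabetical tie-breaks at the last level.  Shared ranks would make
  the quadrant bands ambiguous and the rank–rank scatter ill-defined.
* **Ceiling for the band size.**  ⌈tN⌉ rather than ⌊tN⌋ or percentile
  interpolation, so every list, even N = 1, has a non-empty top band.
* **Symbols uppercased.**  HGNC symbols are conventionally uppercase and
  PubMed/STRING matching must agree on one form.  Duplicates in the
  input are dropped with a warning (omics exports commonly repeat
  symbols); no alias or ortholog mapping is attempted.
* **Unweighted metrics.**  STRING scores gate edge existence only;
  degree and connectivity are counts and percentages on the thresholded
  graph.
* **Heatmap scale.**  log10(count+1) by default — counts span orders of
  magnitude; linear available by flag.  Gene tick labels are suppressed
  above 100 genes for readability; the sidecar TSV always carries the
  full data.
* **Sidecar TSVs.**  Every figure writes its exact plotted coordinates
  and classes next to the image.  They are the testable surface (tests
  never parse images) and the route for regenerating figures elsewhere.
* **Determinism.**  Offline runs are fully deterministic: tables and
  sidecars are byte-identical across reruns, and the manifest omits the
  output path and timestamps so manifests compare equal too.
* **Problem sizes.**  The bundled checks use 20–50 gene lists, 100+
  random graphs up to n = 50 for the connectivity oracle, and 20 seeds
  for the recovery study — sizes at which exact brute-force oracles are
  cheap and failures are attributable.

## Limitations

* Precedence counts raw co-occurrence; it cannot judge relevance, and a
  gene never mentioned in the literature scores 0 on every term, so
  completely uncharacterised genes are still invisible to the precedence
  axis (connectivity partially compensates, but STRING annotation is
  itself precedence-correlated).
* Only interactions *within* the hit list count; a gene hub whose
  partners were not enriched scores low.
* No composite score is produced by design — the two rankings stay
  separate and the quadrant plot is the decision surface.
* Live results depend on the state of PubMed and STRING on the day of
  the query; pin the exported count table and edge list for
  reproducibility.
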