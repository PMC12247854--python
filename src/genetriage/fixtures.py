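"""Seeded synthetic data so every pipeline stage runs and is testable offline.

Two generators emulate the tool's external inputs:

* a network fixture — an Erdős–Rényi random graph or a planted-clique
  graph (a dense clique over random background edges), written in the
  local edge-list format;
* a counts fixture — an overdispersed gene x term publication-count
  matrix (negative binomial: real publication counts have variance well
  above their mean), optionally with a planted subset of genes whose
  first-term counts are inflated by a constant factor, written in the
  cached-counts TSV format.

Planting the same genes as both clique members and first-term outliers
gives a known answer the full pipeline should recover as
``high_conn_high_prec``.  Ground truth is written alongside every
fixture as JSON so tests never re-derive it.  All randomness flows from
the seed in :class:`FixtureSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import GeneList, InputError, TermList

#: Background count model: mean publications per (gene, term) pair.
DEFAULT_COUNT_MEAN = 5.0
#: Negative-binomial dispersion (gamma shape); variance = m + m^2/r.
DEFAULT_DISPERSION = 5.0
#: First-term count multiplier for planted high-precedence genes.
DEFAULT_PLANT_FACTOR = 50.0
#: Background edge probability for planted-clique graphs (sparse).
DEFAULT_P_BACKGROUND = 0.05
#: STRING-style combined score assigned to fixture edges.
FIXTURE_EDGE_SCORE = 900


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; ``seed`` fixes all randomness."""

    n_genes: int = 50
    n_terms: int = 3
    graph_model: str = "planted_clique"  # or "erdos_renyi"
    p_background: float = DEFAULT_P_BACKGROUND
    clique_size: int | None = None  # default ceil(0.2 * n_genes)
    count_mean: float = DEFAULT_COUNT_MEAN
    dispersion: float = DEFAULT_DISPERSION
    plant_factor: float = DEFAULT_PLANT_FACTOR
    n_planted_precedent: int | None = None  # default = clique members
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_terms < 1:
            raise InputError("need at least one gene and one term")
        if self.graph_model not in ("planted_clique", "erdos_renyi"):
            raise InputError(f"unknown graph model {self.graph_model!r}")
        if not (0 <= self.p_background <= 1):
            raise InputError("edge probability outside [0, 1]")
        if self.count_mean <= 0 or self.dispersion <= 0:
            raise InputError("count mean and dispersion must be positive")
        if self.plant_factor < 1:
            raise InputError("plant factor must be >= 1")
        if self.resolved_clique_size > self.n_genes:
            raise InputError(
                f"clique size {self.resolved_clique_size} exceeds "
                f"{self.n_genes} genes"
            )

    @property
    def resolved_clique_size(self) -> int:
        if self.clique_size is not None:
            return self.clique_size
        return int(np.ceil(0.2 * self.n_genes))

    @property
    def genes(self) -> GeneList:
        return GeneList(tuple(f"GENE{i:03d}" for i in range(1, self.n_genes + 1)))

    @property
    def terms(self) -> TermList:
        return TermList(tuple(f"term{j}" for j in range(1, self.n_terms + 1)))

    @property
    def planted_genes(self) -> tuple[str, ...]:
        """Genes planted as clique members and (by default) high-precedence.

        The planted subset is a seeded random draw, not a prefix, so tests
        cannot pass by accident of alphabetical ordering.
        """
        if self.graph_model != "planted_clique":
            return ()
        rng = np.random.default_rng(self.seed)
        idx = rng.choice(
            self.n_genes, size=self.resolved_clique_size, replace=False
        )
        symbols = self.genes.symbols
        return tuple(sorted(symbols[i] for i in idx))


def generate_network_fixture(spec: FixtureSpec, out_dir: Path) -> tuple[Path, Path]:
    """Write ``edges.tsv`` + ``network_truth.json``; returns both paths.

    Planted-clique graphs contain every within-clique edge plus
    Bernoulli(p_background) background edges; Erdős–Rényi graphs are pure
    background.  Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    symbols = spec.genes.symbols
    planted = set(spec.planted_genes)

    edges: list[tuple[str, str]] = []
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            u, v = symbols[i], symbols[j]
            if u in planted and v in planted:
                edges.append((u, v))
            elif rng.random() < spec.p_background:
                edges.append((u, v))

    edge_path = out_dir / "edges.tsv"
    lines = ["geneA\tgeneB\tscore"]
    lines += [f"{u}\t{v}\t{FIXTURE_EDGE_SCORE}" for u, v in edges]
    edge_path.write_text("\n".join(lines) + "\n")

    truth_path = out_dir / "network_truth.json"
    truth = {
        "graph_model": spec.graph_model,
        "n_genes": spec.n_genes,
        "p_background": spec.p_background,
        "clique_members": sorted(planted),
        "n_edges": len(edges),
        "seed": spec.seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return edge_path, truth_path


def generate_counts_fixture(spec: FixtureSpec, out_dir: Path) -> tuple[Path, Path]:
    """Write ``counts.tsv`` + ``counts_truth.json``; returns both paths.

    Counts are negative binomial with mean ``count_mean`` and gamma-shape
    dispersion ``dispersion``; planted genes draw their first-term counts
    with the mean multiplied by ``plant_factor``.  Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 2)))

    if spec.n_planted_precedent is None:
        planted = set(spec.planted_genes)
    else:
        planted = set(spec.genes.symbols[: spec.n_planted_precedent])

    counts: dict[tuple[str, str], int] = {}
    terms = list(spec.terms)
    for gene in spec.genes:
        for j, term in enumerate(terms):
            mean = spec.count_mean
            if j == 0 and gene in planted:
                mean *= spec.plant_factor
            counts[(gene, term)] = int(
                sample_negative_binomial(rng, mean, spec.dispersion)
            )

    counts_path = out_dir / "counts.tsv"
    lines = ["gene\tterm\tcount"]
    for gene in spec.genes:  # gene-major, term order preserved
        for term in terms:
            lines.append(f"{gene}\t{term}\t{counts[(gene, term)]}")
    counts_path.write_text("\n".join(lines) + "\n")

    truth_path = out_dir / "counts_truth.json"
    truth = {
        "count_mean": spec.count_mean,
        "dispersion": spec.dispersion,
        "plant_factor": spec.plant_factor,
        "planted_precedent_genes": sorted(planted),
        "seed": spec.seed,
    }
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return counts_path, truth_path


def sample_negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float
) -> int:
    """One NB(mean, dispersion) draw; dispersion -> inf approaches Poisson."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def evaluate_recovery(
    spec: FixtureSpec, work_dir: Path, threshold: float = 0.20
) -> dict:
    """Run the full offline pipeline on one fixture and score recovery.

    Returns the fraction of planted genes classified ``high_conn_high_prec``
    plus the quadrant class counts — the end-to-end "does the method find
    what it should" check.
    """
    from .combine import classify_quadrants, combine_ranks
    from .literature import CountSource, build_literature_matrix, rank_precedence
    from .model import QUADRANT_HIGH_HIGH
    from .network import compute_metrics, load_edge_list, rank_network

    bundle = generate_fixture_bundle(spec, Path(work_dir))
    genes = spec.genes
    source = CountSource.from_counts_file(bundle["counts"])
    matrix = build_literature_matrix(genes, spec.terms, source)
    precedence = rank_precedence(matrix, "weighted")
    net = load_edge_list(bundle["edges"], genes)
    conn_ranks, _ = rank_network(compute_metrics(net))
    combined = classify_quadrants(
        combine_ranks(precedence, conn_ranks), threshold
    )
    planted = spec.planted_genes
    classes = combined.table["quadrant_class"]
    recovered = sum(1 for g in planted if classes[g] == QUADRANT_HIGH_HIGH)
    return {
        "n_planted": len(planted),
        "n_recovered": recovered,
        "recovery": recovered / len(planted) if planted else float("nan"),
        "class_counts": combined.class_counts(),
    }


def generate_fixture_bundle(spec: FixtureSpec, out_dir: Path) -> dict[str, Path]:
    """Write gene list, edge list, counts and ground truth into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_path = out_dir / "genes.txt"
    gene_path.write_text("\n".join(spec.genes.symbols) + "\n")
    edge_path, net_truth = generate_network_fixture(spec, out_dir)
    counts_path, count_truth = generate_counts_fixture(spec, out_dir)
    return {
        "genes": gene_path,
        "edges": edge_path,
        "network_truth": net_truth,
        "counts": counts_path,
        "counts_truth": count_truth,
    }
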