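"""Pipeline driver: configuration, stage orchestration and table export.

``run_pipeline`` executes literature -> network -> combine -> viz on a
validated :class:`RunConfig` and writes, into the output directory:

* ``literature_matrix.<fmt>`` — gene x term counts plus totals;
* ``network_metrics.<fmt>`` — degree / connectivity, connectivity-ranked;
* ``combined.<fmt>`` — the classified table (one row per gene);
* the three plots with ``.data.tsv`` sidecars;
* ``manifest.json`` — config echo, package/library versions and input
  provenance, so a run can be audited and reproduced;
* ``run.log`` — the logged audit trail.

Tables export as TSV (default), CSV or XLSX.  Reruns on identical inputs
produce byte-identical tables and sidecars.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import matplotlib
import networkx
import numpy
import pandas as pd
import yaml

from . import combine as combine_mod
from . import literature, network, viz
from .model import CombinedTable, GeneList, InputError, TermList, validate_gene_list

logger = logging.getLogger("genetriage")

EXPORT_FORMATS = ("tsv", "csv", "xlsx")

#: Stable column order of the combined export.
COMBINED_LEADING = ["gene", "degree", "connectivity_pct"]
COMBINED_TRAILING = [
    "total",
    "precedence_rank",
    "connectivity_rank",
    "quadrant_class",
    "connectivity_pct_full",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; flags override config-file values."""

    gene_list_path: Path
    terms: tuple[str, ...]
    gene_column: str | None = None  # CSV/TSV column; None = one symbol/line
    ranking_method: str = "weighted"
    threshold: float = 0.20
    species_taxon: int = 9606
    score_threshold: int = network.DEFAULT_SCORE_THRESHOLD
    counts_file: Path | None = None  # None = live PubMed
    edges_file: Path | None = None  # None = STRING API
    output_dir: Path = Path("genetriage-out")
    output_formats: tuple[str, ...] = ("tsv",)
    connectivity_method: str = "ego"
    api_key: str | None = None
    email: str | None = None
    cache_dir: Path | None = None
    plot: viz.PlotConfig = field(default_factory=viz.PlotConfig)
    seed: int = 0
    verbosity: int = 0

    def validate(self) -> None:
        if not self.terms:
            raise InputError("at least one search term is required")
        if self.ranking_method not in ("weighted", "total"):
            raise InputError(f"unknown ranking method {self.ranking_method!r}")
        for fmt in self.output_formats:
            if fmt not in EXPORT_FORMATS:
                raise InputError(f"unknown output format {fmt!r}")
        for path, flag in (
            (self.gene_list_path, "gene list"),
            (self.counts_file, "--counts-file"),
            (self.edges_file, "--edges-file"),
        ):
            if path is not None and not Path(path).exists():
                raise InputError(f"{flag} path does not exist: {path}")


def load_config_file(path: Path) -> dict:
    """Read a TOML or YAML config file into a flat mapping of options."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        return tomllib.loads(path.read_text())
    return yaml.safe_load(path.read_text()) or {}


def read_gene_list(path: Path, column: str | None = None) -> GeneList:
    """Read gene symbols from plain text (one per line, ``#`` comments) or
    from a named column of a CSV/TSV file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene list file not found: {path}")
    if column is not None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
        if column not in df.columns:
            raise InputError(
                f"column {column!r} not in {path} (columns: {list(df.columns)})"
            )
        return validate_gene_list([str(s) for s in df[column].dropna()])
    symbols = [
        line for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return validate_gene_list(symbols)


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

def export_table(table: pd.DataFrame, path: Path, fmt: str) -> Path:
    """Write ``table`` as TSV, CSV or XLSX with a header row.

    ``connectivity_pct`` is rendered with 2 decimal places for reading;
    the full-precision value is carried in ``connectivity_pct_full`` so a
    re-parse round-trips exactly.
    """
    if fmt not in EXPORT_FORMATS:
        raise InputError(f"unknown export format {fmt!r}")
    path = Path(path)
    if not path.parent.exists():
        raise InputError(f"output directory does not exist: {path.parent}")
    out = table.reset_index() if table.index.name else table.copy()
    if "connectivity_pct" in out.columns:
        out["connectivity_pct_full"] = out["connectivity_pct"]
        out["connectivity_pct"] = out["connectivity_pct"].map(lambda v: f"{v:.2f}")
    if fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            out.to_excel(writer, sheet_name=path.stem[:31], index=False)
    else:
        out.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False,
                   lineterminator="\n")
    return path


def build_combined_export(
    combined: CombinedTable,
    metrics: network.NetworkMetrics,
    matrix: literature.LiteratureMatrix,
) -> pd.DataFrame:
    """Assemble the full combined table in the documented column order:
    gene, degree, connectivity_pct, per-term counts, total, ranks, class."""
    df = combined.table.copy()
    df = df.join(metrics.table)
    counts = matrix.to_frame()
    df = df.join(counts)
    term_cols = list(matrix.terms)
    ordered = (
        COMBINED_LEADING[1:]
        + term_cols
        + [c for c in COMBINED_TRAILING if c != "connectivity_pct_full"]
    )
    df = df[[c for c in ordered if c in df.columns]]
    df.index.name = "gene"
    return df


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _versions() -> dict[str, str]:
    try:
        own = metadata.version("genetriage")
    except metadata.PackageNotFoundError:
        own = "unknown"
    return {
        "genetriage": own,
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "matplotlib": matplotlib.__version__,
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a name -> path map of outputs.

    Any stage's fatal error aborts the run with a stage-tagged message and
    leaves a ``FAILED`` marker naming the stage in the output directory.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    stage = "setup"
    try:
        genes = read_gene_list(config.gene_list_path, config.gene_column)
        terms = TermList(tuple(config.terms))
        outputs: dict[str, Path] = {}

        stage = "literature"
        if config.counts_file is not None:
            source = literature.CountSource.from_counts_file(config.counts_file)
            counts_provenance = {"mode": "cached", "file": str(config.counts_file)}
        else:
            cache = (
                literature.CountCache(Path(config.cache_dir) / "pubmed-counts.json")
                if config.cache_dir
                else None
            )
            source = literature.CountSource(
                mode="live", cache=cache, api_key=config.api_key,
                email=config.email,
            )
            counts_provenance = {
                "mode": "live",
                "cache": str(config.cache_dir) if config.cache_dir else None,
                "query_template": literature.QUERY_TEMPLATE_VERSION,
            }
        matrix = literature.build_literature_matrix(genes, terms, source)
        precedence = literature.rank_precedence(matrix, config.ranking_method)

        stage = "network"
        if config.edges_file is not None:
            net = network.load_edge_list(
                config.edges_file, genes, config.score_threshold
            )
            edges_provenance = {"mode": "file", "file": str(config.edges_file)}
        else:
            string_config = network.StringFetchConfig(
                species_taxon=config.species_taxon,
                score_threshold=config.score_threshold,
                cache_path=config.cache_dir,
            )
            net = network.fetch_string_network(genes, string_config)
            edges_provenance = {
                "mode": "string",
                "species": config.species_taxon,
                "score_threshold": config.score_threshold,
            }
        metrics = network.compute_metrics(net, method=config.connectivity_method)
        conn_ranks, ranked_table = network.rank_network(metrics)

        stage = "combine"
        rank_table = combine_mod.combine_ranks(
            precedence, conn_ranks, config.ranking_method
        )
        combined = combine_mod.classify_quadrants(rank_table, config.threshold)

        stage = "export"
        lit_frame = matrix.to_frame()
        combined_frame = build_combined_export(combined, metrics, matrix)
        for fmt in config.output_formats:
            outputs[f"literature_matrix.{fmt}"] = export_table(
                lit_frame, out / f"literature_matrix.{fmt}", fmt
            )
            outputs[f"network_metrics.{fmt}"] = export_table(
                ranked_table.rename_axis("gene"), out / f"network_metrics.{fmt}", fmt
            )
            outputs[f"combined.{fmt}"] = export_table(
                combined_frame, out / f"combined.{fmt}", fmt
            )

        stage = "viz"
        ext = config.plot.output_format
        outputs["heatmap"] = viz.plot_heatmap(
            matrix, precedence, out / f"heatmap.{ext}", config.plot
        )
        outputs["network_scatter"] = viz.plot_network_scatter(
            metrics, out / f"network_scatter.{ext}", config.plot
        )
        outputs["rank_scatter"] = viz.plot_rank_scatter(
            combined, out / f"rank_scatter.{ext}", config.plot
        )

        stage = "manifest"
        manifest = {
            "config": _config_echo(config),
            "versions": _versions(),
            "inputs": {
                "n_genes": len(genes),
                "n_terms": len(terms),
                "counts": counts_provenance,
                "edges": edges_provenance,
            },
            "results": {
                "n_edges": net.n_edges,
                "class_counts": combined.class_counts(),
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        outputs["manifest"] = manifest_path
        if marker.exists():
            marker.unlink()
        logger.info("pipeline complete: %d genes, %d edges", len(genes), net.n_edges)
        return outputs
    except Exception as exc:
        marker.write_text(f"stage={stage}: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        exc.pipeline_stage = stage  # type: ignore[attr-defined]
        raise
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    # where the manifest sits is self-evident; omitting it keeps manifests
    # comparable across reruns into different directories
    echo.pop("output_dir", None)
    for key, value in echo.items():
        if isinstance(value, Path):
            echo[key] = str(value)
    echo["plot"] = dataclasses.asdict(config.plot)
    return echo
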