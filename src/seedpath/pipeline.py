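"""End-to-end orchestration: parse -> build -> betweenness -> FDR -> filter.

A run consumes a STRING-dialect links file (or a pre-built edge table) plus
a seed gene list, and produces an edge table, a betweenness table, an FDR
table, a candidate table and a run report.  Every output embeds the
effective configuration and package version, and a run is byte-for-byte
reproducible from its inputs and RNG seed.

Permutation runs are independent, so per-permutation betweenness tables
can be checkpointed to disk and a partial run resumed later; the random
sets are pre-generated from the RNG seed, which makes resumed runs
identical to single-shot runs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO, Any, Iterable, Mapping

import networkx as nx
import yaml

from . import __version__
from .network_io import (
    SeedSet,
    ValidationError,
    _as_sink,
    build_network,
    normalize_records,
    parse_string_links,
    read_edge_table,
    read_seed_list,
    write_edge_table,
)
from .path_core import (
    MODES,
    BetweennessTable,
    seed_pair_betweenness,
    write_betweenness_table,
)
from .permutation import (
    CandidateReport,
    FdrTable,
    PermutationConfig,
    filter_candidates,
    permutation_fdr,
    sample_random_sets,
    write_fdr_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage, with context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Effective configuration of one analysis run.

    ``taxon_prefix`` filters the multi-organism links dump and is stripped
    from identifiers when ``strip_prefix`` is on; ``collapse_isoforms``
    additionally drops trailing ``.<digits>`` isoform suffixes so results
    are reported at gene level.  The remaining fields mirror
    :class:`~seedpath.permutation.PermutationConfig` plus the counting
    mode and the candidate FDR threshold (strict ``<``).
    """

    taxon_prefix: str = ""
    strip_prefix: bool = True
    collapse_isoforms: bool = True
    mode: str = "all-paths"
    n_permutations: int = 1000
    threshold: float = 0.05
    universe_policy: str = "all-nodes"
    comparison: str = "gt"
    smoothing: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 < self.threshold <= 1:
            raise ValidationError("threshold must lie in (0, 1]")

    def permutation_config(self, set_size: int | None = None) -> PermutationConfig:
        return PermutationConfig(
            n_permutations=self.n_permutations,
            set_size=set_size,
            universe_policy=self.universe_policy,
            rng_seed=self.rng_seed,
            comparison=self.comparison,
            smoothing=self.smoothing,
        )

    def echo(self) -> dict[str, Any]:
        out = asdict(self)
        out["version"] = __version__
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C401
        extra = set(data) - known - {"version"}
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        return cls(**{k: v for k, v in data.items() if k in known})

    @classmethod
    def from_yaml(cls, source: str | Path | IO[str]) -> "PipelineConfig":
        if isinstance(source, (str, Path)):
            with open(source, "r", encoding="utf-8") as handle:
                data = yaml.safe_load(handle)
        else:
            data = yaml.safe_load(source)
        return cls.from_dict(data or {})


@dataclass
class RunReport:
    """Summary counts of one run; additivity is enforced on construction."""

    n_records_parsed: int
    n_nodes: int
    n_edges: int
    n_seeds_requested: int
    n_seeds_in_network: int
    n_extracted_genes: int
    n_extracted_validated: int
    n_extracted_novel: int
    n_candidates: int
    n_candidate_validated: int
    n_candidate_novel: int
    skipped_pairs: int
    n_permutations_completed: int
    config_echo: dict[str, Any]

    def __post_init__(self) -> None:
        if self.n_extracted_validated + self.n_extracted_novel != self.n_extracted_genes:
            raise ValidationError("extracted counts are not additive")
        if self.n_candidate_validated + self.n_candidate_novel != self.n_candidates:
            raise ValidationError("candidate counts are not additive")
        if self.n_candidates > self.n_extracted_genes:
            raise ValidationError("more candidates than extracted genes")

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class RunArtifacts:
    """In-memory products of a run, alongside the report."""

    network: nx.Graph
    seeds: SeedSet
    observed: BetweennessTable
    fdr_table: FdrTable
    candidates: CandidateReport
    report: RunReport


# ---------------------------------------------------------------------------
# Checkpointing

def _network_fingerprint(network: nx.Graph) -> str:
    digest = hashlib.sha1()
    for a, b, data in sorted(
        (min(a, b), max(a, b), d["weight"]) for a, b, d in network.edges(data=True)
    ):
        digest.update(f"{a}\t{b}\t{data}\n".encode())
    return digest.hexdigest()


def _checkpoint_meta(network: nx.Graph, config: PipelineConfig, set_size: int) -> dict:
    return {
        "network_sha1": _network_fingerprint(network),
        "set_size": set_size,
        "mode": config.mode,
        "n_permutations": config.n_permutations,
        "universe_policy": config.universe_policy,
        "rng_seed": config.rng_seed,
        "version": __version__,
    }


def _write_perm_table(path: Path, counts: Mapping[str, int]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as out:
        out.write("gene\tbetweenness\n")
        for gene in sorted(counts):
            out.write(f"{gene}\t{counts[gene]}\n")


def _read_perm_table(path: Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line == "gene\tbetweenness":
                continue
            gene, value = line.split("\t")
            counts[gene] = int(value)
    return counts


def run_permutations(
    network: nx.Graph,
    seeds: SeedSet,
    config: PipelineConfig,
    checkpoint_dir: str | Path | None = None,
    max_permutations: int | None = None,
) -> list[BetweennessTable]:
    """Compute per-permutation betweenness tables, optionally checkpointed.

    All ``n_permutations`` random sets are pre-generated from the RNG seed;
    with a checkpoint directory, completed permutations are persisted as
    small TSV files and reloaded on resume (after validating that network,
    seed-set size and configuration match).  ``max_permutations`` caps how
    many *new* permutations this call computes, so long runs can be split
    across invocations without waste.
    """
    set_size = len(seeds.in_network)
    perm_config = config.permutation_config(set_size=set_size)
    random_sets = sample_random_sets(network, perm_config, seeds=seeds)

    ckpt: Path | None = None
    if checkpoint_dir is not None:
        ckpt = Path(checkpoint_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
        meta = _checkpoint_meta(network, config, set_size)
        meta_path = ckpt / "meta.yaml"
        if meta_path.exists():
            existing = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
            if existing != meta:
                raise ValidationError(
                    f"checkpoint directory {ckpt} was written under a "
                    "different network or configuration; refusing to resume"
                )
        else:
            meta_path.write_text(
                yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
            )

    tables: list[BetweennessTable] = []
    computed = 0
    for i, gene_set in enumerate(random_sets):
        path = ckpt / f"perm_{i:05d}.tsv" if ckpt is not None else None
        if path is not None and path.exists():
            tables.append(BetweennessTable(_read_perm_table(path), config.mode))
            continue
        if max_permutations is not None and computed >= max_permutations:
            break
        table = seed_pair_betweenness(network, gene_set, mode=config.mode)
        computed += 1
        if path is not None:
            _write_perm_table(path, table.counts)
        tables.append(table)
    logger.info(
        "permutations: %d available (%d computed now, %d requested)",
        len(tables), computed, config.n_permutations,
    )
    return tables


# ---------------------------------------------------------------------------
# Orchestration

def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc


def _analyse(
    network: nx.Graph,
    seeds: SeedSet,
    config: PipelineConfig,
    n_records: int,
    out_dir: str | Path | None,
    checkpoint_dir: str | Path | None,
    max_permutations: int | None,
) -> RunArtifacts:
    observed = _stage(
        "betweenness", seed_pair_betweenness, network, seeds, config.mode
    )
    permuted = _stage(
        "permutation",
        run_permutations,
        network,
        seeds,
        config,
        checkpoint_dir,
        max_permutations,
    )
    perm_config = config.permutation_config(set_size=len(seeds.in_network))
    fdr_table = _stage("fdr", permutation_fdr, observed, permuted, perm_config)
    candidates = _stage(
        "filter", filter_candidates, fdr_table, config.threshold, seeds
    )

    extracted = set(observed.counts)
    extracted_validated = extracted & seeds.in_network
    report = RunReport(
        n_records_parsed=n_records,
        n_nodes=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        n_seeds_requested=len(seeds.requested),
        n_seeds_in_network=len(seeds.in_network),
        n_extracted_genes=len(extracted),
        n_extracted_validated=len(extracted_validated),
        n_extracted_novel=len(extracted) - len(extracted_validated),
        n_candidates=len(candidates.candidates),
        n_candidate_validated=len(candidates.validated),
        n_candidate_novel=len(candidates.novel),
        skipped_pairs=observed.skipped_pairs,
        n_permutations_completed=fdr_table.n_permutations,
        config_echo=config.echo(),
    )
    artifacts = RunArtifacts(network, seeds, observed, fdr_table, candidates, report)
    if out_dir is not None:
        _stage("write-outputs", write_outputs, artifacts, out_dir)
    return artifacts


def run_analysis(
    links_source: str | Path | IO[str] | Iterable[str],
    seeds_source: str | Path | IO[str] | Iterable[str],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    checkpoint_dir: str | Path | None = None,
    max_permutations: int | None = None,
) -> RunArtifacts:
    """Run the full chain from a raw links file and a seed list."""
    records = _stage(
        "parse", parse_string_links, links_source, config.taxon_prefix
    )
    n_records = len(records)
    if config.strip_prefix or config.collapse_isoforms:
        prefix = config.taxon_prefix if config.strip_prefix else ""
        records = _stage(
            "normalize", normalize_records, records, prefix, config.collapse_isoforms
        )
    network = _stage("build", build_network, records)
    seeds = _stage("seeds", read_seed_list, seeds_source, network)
    return _analyse(
        network, seeds, config, n_records, out_dir, checkpoint_dir, max_permutations
    )


def run_from_network(
    network_source: str | Path | IO[str] | nx.Graph,
    seeds_source: str | Path | IO[str] | Iterable[str],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    checkpoint_dir: str | Path | None = None,
    max_permutations: int | None = None,
) -> RunArtifacts:
    """Run the chain from a pre-built edge table (deposited network)."""
    if isinstance(network_source, nx.Graph):
        network = network_source
    else:
        network = _stage("read-network", read_edge_table, network_source)
    n_records = network.graph.get("n_records", network.number_of_edges())
    seeds = _stage("seeds", read_seed_list, seeds_source, network)
    return _analyse(
        network, seeds, config, n_records, out_dir, checkpoint_dir, max_permutations
    )


# ---------------------------------------------------------------------------
# Output

def _header_comments(config: PipelineConfig) -> list[str]:
    echo = config.echo()
    return [
        f"seedpath {__version__}",
        "; ".join(f"{k}={echo[k]}" for k in sorted(echo) if k != "version"),
    ]


def write_outputs(artifacts: RunArtifacts, out_dir: str | Path) -> dict[str, Path]:
    """Write all run products under ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig.from_dict(artifacts.report.config_echo)
    comments = _header_comments(config)
    paths = {
        "network": out / "network.tsv",
        "betweenness": out / "betweenness.tsv",
        "fdr": out / "fdr.tsv",
        "candidates": out / "candidates.tsv",
        "report": out / "report.yaml",
        "summary": out / "summary.txt",
    }
    write_edge_table(artifacts.network, paths["network"], comments)
    write_betweenness_table(
        artifacts.observed, artifacts.seeds, paths["betweenness"], comments
    )
    write_fdr_table(
        artifacts.observed,
        artifacts.fdr_table,
        artifacts.seeds,
        artifacts.candidates,
        paths["fdr"],
        comments,
    )
    write_fdr_table(
        artifacts.observed,
        artifacts.fdr_table,
        artifacts.seeds,
        artifacts.candidates,
        paths["candidates"],
        comments,
        candidates_only=True,
    )
    with open(paths["report"], "w", encoding="utf-8", newline="\n") as handle:
        yaml.safe_dump(artifacts.report.as_dict(), handle, sort_keys=True)
    summarize(artifacts.report, paths["summary"])
    return paths


def summarize(report: RunReport, sink: str | Path | IO[str]) -> None:
    """Write a human-readable run summary with all counts and conventions."""
    echo = report.config_echo
    comparison = "strict" if echo["comparison"] == "gt" else "or-equal"
    lines = [
        f"seedpath {echo.get('version', __version__)} run summary",
        f"records parsed:            {report.n_records_parsed}",
        f"network nodes:             {report.n_nodes}",
        f"network edges:             {report.n_edges}",
        f"seeds requested:           {report.n_seeds_requested}",
        f"seeds in network:          {report.n_seeds_in_network}",
        f"extracted genes:           {report.n_extracted_genes}",
        f"  validated (seed):        {report.n_extracted_validated}",
        f"  novel:                   {report.n_extracted_novel}",
        f"candidates:                {report.n_candidates}",
        f"  validated (seed):        {report.n_candidate_validated}",
        f"  novel:                   {report.n_candidate_novel}",
        f"disconnected seed pairs skipped: {report.skipped_pairs}",
        f"permutations completed:    {report.n_permutations_completed}"
        f" of {echo['n_permutations']}",
        f"counting mode:             {echo['mode']}",
        f"null universe:             {echo['universe_policy']}",
        f"candidate filter:          fdr < {echo['threshold']} ({comparison})",
        f"rng seed:                  {echo['rng_seed']}",
    ]
    with _as_sink(sink) as out:
        out.write("\n".join(lines) + "\n")
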