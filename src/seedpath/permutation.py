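"""Permutation null model and per-gene permutation FDR.

Genes that are topological hubs lie on many shortest paths regardless of
which seed set is chosen, so raw betweenness alone would promote them.  The
null model draws random gene sets of the same size as the seed set, reruns
the betweenness computation for each, and asks — gene by gene — how often a
random set produces a betweenness exceeding the observed one:

    FDR(g) = M / N

where N is the number of permutations and M the number of permutation runs
whose betweenness for g exceeds the observed value.  A gene absent from a
permutation's table has betweenness 0 in that run.  Genes whose FDR falls
strictly below the threshold (default 0.05) are retained as candidates.

Defaults follow the study conventions: N = 1000 random sets, strict ">"
exceedance, sampling from all network nodes, no pseudocount.  The more
conservative ">=" comparison, a seed-excluding universe, and (M+1)/(N+1)
smoothing are available as explicit options and recorded in every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np

from .network_io import SeedSet, ValidationError, _as_sink
from .path_core import BetweennessTable

logger = logging.getLogger(__name__)

COMPARISONS = ("gt", "ge")
UNIVERSE_POLICIES = ("all-nodes", "non-seed-nodes")

_COMPARISON_ALIASES = {">": "gt", ">=": "ge", "≥": "ge", "gt": "gt", "ge": "ge"}


def canonical_comparison(comparison: str) -> str:
    try:
        return _COMPARISON_ALIASES[comparison]
    except KeyError:
        raise ValidationError(
            f"unknown comparison {comparison!r}; expected one of {COMPARISONS}"
        ) from None


@dataclass(frozen=True)
class PermutationConfig:
    """Parameters of the random-set null.

    ``set_size`` defaults to the in-network seed count when left ``None``.
    ``comparison`` selects whether a permutation run counts toward M when
    its betweenness is strictly greater ("gt") or greater-or-equal ("ge")
    than the observed value.  ``smoothing`` applies the (M+1)/(N+1)
    pseudocount convention instead of the plain M/N ratio.
    """

    n_permutations: int = 1000
    set_size: int | None = None
    universe_policy: str = "all-nodes"
    rng_seed: int = 0
    comparison: str = "gt"
    smoothing: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.universe_policy not in UNIVERSE_POLICIES:
            raise ValidationError(
                f"unknown universe policy {self.universe_policy!r}; "
                f"expected one of {UNIVERSE_POLICIES}"
            )
        object.__setattr__(
            self, "comparison", canonical_comparison(self.comparison)
        )


@dataclass
class FdrTable:
    """Per-gene permutation FDR on the grid {0, 1/N, ..., 1}.

    FDR values are exact rationals (:class:`fractions.Fraction`) so that
    ``fdr[g] * n_permutations == exceed_count[g]`` holds identically (when
    smoothing is off) with no floating-point round-off; the domain equals
    that of the observed betweenness table.
    """

    fdr: dict[str, Fraction]
    exceed_count: dict[str, int]
    n_permutations: int
    comparison: str = "gt"
    smoothing: bool = False


@dataclass
class CandidateReport:
    """Genes surviving the FDR filter, split into validated and novel."""

    candidates: tuple[str, ...]
    validated: tuple[str, ...]
    novel: tuple[str, ...]
    threshold: float

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def sampling_universe(
    network: nx.Graph,
    seeds: SeedSet | Iterable[str] | None,
    policy: str,
) -> list[str]:
    """The sorted list of genes eligible for random-set membership."""
    nodes = sorted(network.nodes)
    if policy == "non-seed-nodes":
        if seeds is None:
            raise ValidationError("non-seed-nodes policy requires a seed set")
        members = seeds.in_network if isinstance(seeds, SeedSet) else set(seeds)
        nodes = [n for n in nodes if n not in members]
    return nodes


def sample_random_sets(
    network: nx.Graph,
    config: PermutationConfig,
    seeds: SeedSet | Iterable[str] | None = None,
) -> list[frozenset[str]]:
    """Draw ``n_permutations`` gene sets uniformly without replacement.

    Sets are drawn from the universe selected by ``config.universe_policy``
    and are fully reproducible from ``config.rng_seed`` (the universe is
    sorted before sampling so node insertion order is irrelevant).
    """
    universe = sampling_universe(network, seeds, config.universe_policy)
    set_size = config.set_size
    if set_size is None:
        if seeds is None:
            raise ValidationError("set_size unset and no seed set given")
        set_size = len(
            seeds.in_network if isinstance(seeds, SeedSet) else set(seeds)
        )
    if set_size < 1:
        raise ValidationError("set_size must be >= 1")
    if set_size > len(universe):
        raise ValidationError(
            f"set_size {set_size} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(config.rng_seed)
    universe_arr = np.asarray(universe, dtype=object)
    sets = []
    for _ in range(config.n_permutations):
        idx = rng.choice(len(universe_arr), size=set_size, replace=False)
        sets.append(frozenset(universe_arr[idx]))
    return sets


def permutation_fdr(
    observed: BetweennessTable,
    permuted: Sequence[BetweennessTable],
    config: PermutationConfig,
) -> FdrTable:
    """Compute FDR(g) = M / N per gene in the observed table.

    ``permuted`` must come from the same network and counting mode as
    ``observed``; each gene's observed betweenness is compared against that
    same gene's betweenness across all permutation runs (0 when absent).
    """
    if not permuted:
        raise ValidationError("permutation_fdr requires at least one permuted table")
    for table in permuted:
        if table.mode != observed.mode:
            raise ValidationError(
                f"permuted table mode {table.mode!r} != observed mode "
                f"{observed.mode!r}"
            )
    comparison = canonical_comparison(config.comparison)
    n = len(permuted)
    exceed: dict[str, int] = {}
    fdr: dict[str, Fraction] = {}
    for gene, obs in observed.counts.items():
        if comparison == "gt":
            m = sum(1 for t in permuted if t.counts.get(gene, 0) > obs)
        else:
            m = sum(1 for t in permuted if t.counts.get(gene, 0) >= obs)
        exceed[gene] = m
        fdr[gene] = Fraction(m + 1, n + 1) if config.smoothing else Fraction(m, n)
    return FdrTable(fdr, exceed, n, comparison=comparison, smoothing=config.smoothing)


def filter_candidates(
    fdr_table: FdrTable,
    threshold: float,
    seeds: SeedSet | Iterable[str],
) -> CandidateReport:
    """Retain genes with FDR strictly below ``threshold``.

    The boundary is exclusive: a gene with FDR exactly equal to the
    threshold is dropped.  A float threshold is interpreted as the decimal
    number it was written as (0.05 means exactly 1/20), so the comparison
    against the exact rational FDR grid has no round-off at the boundary.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    cutoff = (
        Fraction(str(threshold)) if isinstance(threshold, float)
        else Fraction(threshold)
    )
    seed_members = (
        seeds.in_network if isinstance(seeds, SeedSet) else frozenset(seeds)
    )
    retained = sorted(g for g, v in fdr_table.fdr.items() if v < cutoff)
    validated = tuple(g for g in retained if g in seed_members)
    novel = tuple(g for g in retained if g not in seed_members)
    return CandidateReport(tuple(retained), validated, novel, threshold)


FDR_TABLE_HEADER = "gene\tbetweenness\tM\tfdr\tis_seed\tcandidate"


def write_fdr_table(
    observed: BetweennessTable,
    fdr_table: FdrTable,
    seeds: SeedSet | Iterable[str],
    candidates: CandidateReport,
    sink: str | Path | IO[str],
    header_comments: Sequence[str] = (),
    candidates_only: bool = False,
) -> None:
    """Write TSV ``gene  betweenness  M  fdr  is_seed  candidate``.

    Rows are ordered by ascending FDR, then descending betweenness, then
    gene identifier; FDR values are printed with six decimals so the file
    is byte-stable across runs.
    """
    seed_members = (
        seeds.in_network if isinstance(seeds, SeedSet) else frozenset(seeds)
    )
    candidate_set = set(candidates.candidates)
    rows = sorted(
        observed.counts.items(),
        key=lambda kv: (fdr_table.fdr[kv[0]], -kv[1], kv[0]),
    )
    with _as_sink(sink) as out:
        for comment in header_comments:
            out.write(f"# {comment}\n")
        out.write(FDR_TABLE_HEADER + "\n")
        for gene, count in rows:
            is_candidate = gene in candidate_set
            if candidates_only and not is_candidate:
                continue
            out.write(
                f"{gene}\t{count}\t{fdr_table.exceed_count[gene]}\t"
                f"{float(fdr_table.fdr[gene]):.6f}\t"
                f"{'yes' if gene in seed_members else 'no'}\t"
                f"{'yes' if is_candidate else 'no'}\n"
            )
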