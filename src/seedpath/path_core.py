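"""Shortest paths among seed pairs and seed-restricted path betweenness.

For a set of seed genes, every unordered seed pair (s, t) contributes the
collection of *all* minimum-weight s-t paths.  A gene appearing strictly
inside such a path (an inner node, never an endpoint of that pair) is
credited, and the per-gene total is its betweenness.  This is not classical
all-pairs betweenness centrality: only seed pairs act as terminals, credits
are raw integer counts, and no normalization is applied.

Two counting conventions are supported:

``all-paths``
    An inner node v is credited with the number of distinct shortest s-t
    paths passing through v, computed combinatorially as
    ``sigma_s(v) * sigma_t(v)`` whenever ``dist_s(v) + dist_t(v) ==
    dist_s(t)``, where sigma is the shortest-path count from the pair
    endpoint.  No path is ever enumerated explicitly.

``per-pair``
    An inner node on any shortest s-t path is credited exactly once for
    that pair, regardless of how many tied paths traverse it.

Path counts can grow combinatorially, so sigma values are Python integers
(arbitrary precision); all distances are exact integer sums of edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from heapq import heappop, heappush
from itertools import combinations
from pathlib import Path
from typing import IO, Iterable, Sequence

import networkx as nx

from .network_io import SeedSet, ValidationError, _as_sink

logger = logging.getLogger(__name__)

MODES = ("all-paths", "per-pair")

#: Largest graph brute_force_betweenness will accept; beyond this the
#: exhaustive simple-path enumeration is no longer a practical oracle.
MAX_BRUTE_FORCE_NODES = 14


@dataclass
class SsspResult:
    """Single-source shortest distances and shortest-path counts.

    ``dist[v]`` is the minimum total edge weight from ``source`` to v and
    ``sigma[v]`` the number of distinct minimum-weight paths; nodes absent
    from ``dist`` are unreachable (implicitly sigma 0).
    """

    source: str
    dist: dict[str, int]
    sigma: dict[str, int]

    @property
    def reachable(self) -> frozenset[str]:
        return frozenset(self.dist)


@dataclass
class BetweennessTable:
    """Per-gene count of seed-pair shortest paths through that gene."""

    counts: dict[str, int]
    mode: str
    skipped_pairs: int = 0
    n_pairs: int = 0


def dijkstra_sssp(network: nx.Graph, source: str) -> SsspResult:
    """Exact Dijkstra with shortest-path counting.

    Sigma is accumulated over the shortest-path predecessor structure: when
    a settled node v relaxes neighbour u, sigma flows along the edge iff it
    lies on some shortest path to u.  Positive integer weights guarantee a
    settled node is never relaxed again, so each count is added exactly
    once and the result is independent of node iteration order.
    """
    if source not in network:
        raise ValidationError(f"source {source!r} not in network")
    adj = network.adj
    dist: dict[str, int] = {source: 0}
    sigma: dict[str, int] = {source: 1}
    settled: set[str] = set()
    counter = 0  # heap tie-break; keeps pops deterministic and label-agnostic
    heap: list[tuple[int, int, str]] = [(0, counter, source)]
    while heap:
        d, _, v = heappop(heap)
        if v in settled:
            continue
        settled.add(v)
        sigma_v = sigma[v]
        for u, attrs in adj[v].items():
            nd = d + attrs["weight"]
            du = dist.get(u)
            if du is None or nd < du:
                dist[u] = nd
                sigma[u] = sigma_v
                counter += 1
                heappush(heap, (nd, counter, u))
            elif nd == du:
                sigma[u] += sigma_v
    return SsspResult(source, dist, sigma)


def _seed_nodes(network: nx.Graph, seeds: SeedSet | Iterable[str]) -> list[str]:
    if isinstance(seeds, SeedSet):
        members: Iterable[str] = seeds.in_network
    else:
        members = seeds
    nodes = sorted(g for g in set(members) if g in network)
    if len(nodes) < 2:
        raise ValidationError(
            f"need at least 2 in-network seeds, got {len(nodes)}"
        )
    return nodes


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValidationError(f"unknown counting mode {mode!r}; expected one of {MODES}")


def seed_pair_betweenness(
    network: nx.Graph,
    seeds: SeedSet | Iterable[str],
    mode: str = "all-paths",
) -> BetweennessTable:
    """Count, per gene, the seed-pair shortest paths it lies inside.

    Runs one Dijkstra per seed, then for each connected unordered seed pair
    (s, t) credits every node v with ``dist_s(v) + dist_t(v) == dist_s(t)``
    other than s and t themselves.  Seed genes acting as inner nodes for
    *other* pairs are credited normally.  Disconnected pairs are skipped
    and tallied in ``skipped_pairs``.
    """
    _check_mode(mode)
    seed_list = _seed_nodes(network, seeds)
    sssp = {s: dijkstra_sssp(network, s) for s in seed_list}
    counts: dict[str, int] = {}
    skipped = 0
    n_pairs = 0
    for s, t in combinations(seed_list, 2):
        res_s, res_t = sssp[s], sssp[t]
        d_st = res_s.dist.get(t)
        if d_st is None:
            skipped += 1
            continue
        n_pairs += 1
        dist_t = res_t.dist
        if mode == "all-paths":
            sig_s, sig_t = res_s.sigma, res_t.sigma
            for v, dv in res_s.dist.items():
                if v == s or v == t:
                    continue
                dvt = dist_t.get(v)
                if dvt is not None and dv + dvt == d_st:
                    counts[v] = counts.get(v, 0) + sig_s[v] * sig_t[v]
        else:
            for v, dv in res_s.dist.items():
                if v == s or v == t:
                    continue
                dvt = dist_t.get(v)
                if dvt is not None and dv + dvt == d_st:
                    counts[v] = counts.get(v, 0) + 1
    if skipped:
        logger.info("skipped %d disconnected seed pairs", skipped)
    return BetweennessTable(counts, mode, skipped_pairs=skipped, n_pairs=n_pairs)


def brute_force_betweenness(
    network: nx.Graph,
    seeds: SeedSet | Iterable[str],
    mode: str = "all-paths",
) -> BetweennessTable:
    """Oracle: exhaustive simple-path enumeration for tiny graphs.

    Enumerates every simple path per seed pair, keeps those of minimum
    total weight, and counts inner-node occurrences (once per path in
    ``all-paths`` mode, once per pair in ``per-pair`` mode).  Positive
    weights make every shortest path simple, so enumeration is exhaustive
    on its domain; graphs above :data:`MAX_BRUTE_FORCE_NODES` nodes are
    refused.
    """
    _check_mode(mode)
    if network.number_of_nodes() > MAX_BRUTE_FORCE_NODES:
        raise ValidationError(
            f"brute-force oracle refuses graphs with more than "
            f"{MAX_BRUTE_FORCE_NODES} nodes"
        )
    seed_list = _seed_nodes(network, seeds)
    counts: dict[str, int] = {}
    skipped = 0
    n_pairs = 0
    for s, t in combinations(seed_list, 2):
        best_weight: int | None = None
        best_paths: list[list[str]] = []
        for path in nx.all_simple_paths(network, s, t):
            weight = sum(
                network[a][b]["weight"] for a, b in zip(path, path[1:])
            )
            if best_weight is None or weight < best_weight:
                best_weight = weight
                best_paths = [path]
            elif weight == best_weight:
                best_paths.append(path)
        if best_weight is None:
            skipped += 1
            continue
        n_pairs += 1
        if mode == "all-paths":
            for path in best_paths:
                for v in path[1:-1]:
                    counts[v] = counts.get(v, 0) + 1
        else:
            inner = {v for path in best_paths for v in path[1:-1]}
            for v in inner:
                counts[v] = counts.get(v, 0) + 1
    return BetweennessTable(counts, mode, skipped_pairs=skipped, n_pairs=n_pairs)


BETWEENNESS_TABLE_HEADER = "gene\tbetweenness\tis_seed"


def write_betweenness_table(
    table: BetweennessTable,
    seeds: SeedSet | Iterable[str],
    sink: str | Path | IO[str],
    header_comments: Sequence[str] = (),
) -> None:
    """Write TSV ``gene<TAB>betweenness<TAB>is_seed``.

    Rows are sorted by descending betweenness, ties broken by gene
    identifier, so the output is deterministic.
    """
    seed_members = (
        seeds.in_network if isinstance(seeds, SeedSet) else frozenset(seeds)
    )
    rows = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with _as_sink(sink) as out:
        for comment in header_comments:
            out.write(f"# {comment}\n")
        out.write(BETWEENNESS_TABLE_HEADER + "\n")
        for gene, count in rows:
            is_seed = "yes" if gene in seed_members else "no"
            out.write(f"{gene}\t{count}\t{is_seed}\n")
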