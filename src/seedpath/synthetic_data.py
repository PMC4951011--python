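"""Synthetic STRING-dialect networks with a planted functional module.

The generator emulates the score semantics of a STRING ``protein.links``
dump (integer combined scores in [150, 999], each undirected interaction
listed in both directions, a single header row, ``<taxid>.<gene>.<isoform>``
identifiers) while planting a dense, high-score module of functionally
related genes inside a sparse low-score background graph.  A subset of the
module is designated as seeds; the remaining module members are *hidden*
and should be recovered by the prioritization pipeline.  Optional decoy
seeds — background nodes added to the seed list — let tests check that
seeds outside the module do not inflate module FDRs.

Scores are uniform on intervals rather than fit to STRING's empirical
score distribution: the method depends only on the ordering of path
weights, so the controlled variable is the placement of the module
interval (high scores, light edges) above the background interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping

import numpy as np

from .network_io import SCORE_MAX, SCORE_MIN, ValidationError

logger = logging.getLogger(__name__)

TAXON = "9999"
TAXON_PREFIX = TAXON + "."

ROLE_BACKGROUND = "background"
ROLE_MODULE_SEED = "module-seed"
ROLE_MODULE_HIDDEN = "module-hidden"
ROLE_DECOY_SEED = "decoy-seed"
ROLES = (ROLE_BACKGROUND, ROLE_MODULE_SEED, ROLE_MODULE_HIDDEN, ROLE_DECOY_SEED)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-module benchmark.

    Defaults are the benchmark conditions used throughout the test suite:
    a 400-node Erdos-Renyi background at edge probability 0.02 with weak
    scores U[150, 400], a 30-node module at edge probability 0.6 with
    strong scores U[850, 999], and 15 module members designated as seeds.
    Score ranges are inclusive integer intervals within [150, 999].
    """

    n_background: int = 400
    background_edge_prob: float = 0.02
    background_score_range: tuple[int, int] = (150, 400)
    module_size: int = 30
    module_edge_prob: float = 0.6
    module_score_range: tuple[int, int] = (850, 999)
    n_seed_members: int = 15
    n_decoy_seeds: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("background_score_range", self.background_score_range),
            ("module_score_range", self.module_score_range),
        ):
            if not (SCORE_MIN <= lo <= hi <= SCORE_MAX):
                raise ValidationError(
                    f"{name} {lo, hi} must be an interval within "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )
        if not 0 <= self.n_seed_members <= self.module_size:
            raise ValidationError("n_seed_members must lie in [0, module_size]")
        if not 0 <= self.n_decoy_seeds <= self.n_background:
            raise ValidationError("n_decoy_seeds must lie in [0, n_background]")
        for name, p in (
            ("background_edge_prob", self.background_edge_prob),
            ("module_edge_prob", self.module_edge_prob),
        ):
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must be a probability, got {p}")
        if self.module_score_range[0] < self.background_score_range[1]:
            logger.warning(
                "module scores overlap background scores; the planted module "
                "will not be cleanly separable"
            )


@dataclass
class GeneratedData:
    """Generator output: STRING-dialect text, seed list text, ground truth."""

    links_text: str
    seed_text: str
    truth: dict[str, str]  # node -> role
    n_nodes: int  # nodes incident to at least one edge
    n_edges: int  # undirected edge count (each edge emitted in both directions)
    spec: SyntheticSpec

    @property
    def hidden_members(self) -> frozenset[str]:
        return frozenset(
            n for n, role in self.truth.items() if role == ROLE_MODULE_HIDDEN
        )

    @property
    def seed_genes(self) -> frozenset[str]:
        return frozenset(
            n
            for n, role in self.truth.items()
            if role in (ROLE_MODULE_SEED, ROLE_DECOY_SEED)
        )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Recovery of hidden module members by a candidate gene set.

    Recall is over the hidden members; precision is over the *non-seed*
    candidates (seed-role genes are known inputs, not discoveries).
    Precision is NaN when there are no non-seed candidates to score.
    """

    recall: float
    precision: float
    n_hidden: int
    n_recovered: int
    n_nonseed_candidates: int


def _random_edges(
    rng: np.random.Generator,
    nodes: list[str],
    edge_prob: float,
    score_range: tuple[int, int],
) -> dict[tuple[str, str], int]:
    """Erdos-Renyi edges over ``nodes`` with uniform integer scores."""
    n = len(nodes)
    if n < 2 or edge_prob == 0:
        return {}
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < edge_prob
    lo, hi = score_range
    scores = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return {
        (nodes[i], nodes[j]): int(s)
        for i, j, s in zip(iu[mask], ju[mask], scores)
    }


def generate(spec: SyntheticSpec) -> GeneratedData:
    """Generate links text, seed list and truth table from ``spec``.

    The background and module graphs are drawn edgewise at their
    respective probabilities and score ranges; every module node is then
    wired to the background by at least one bridging edge carrying a
    background-range score, so no module node is isolated from the rest of
    the network.  Output is byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.rng_seed)
    background = [f"SYNB{i:04d}" for i in range(spec.n_background)]
    module = [f"SYNM{i:03d}" for i in range(spec.module_size)]

    edges = _random_edges(
        rng, background, spec.background_edge_prob, spec.background_score_range
    )
    edges.update(
        _random_edges(rng, module, spec.module_edge_prob, spec.module_score_range)
    )
    if spec.n_background:
        lo, hi = spec.background_score_range
        partners = rng.integers(0, spec.n_background, size=spec.module_size)
        bridge_scores = rng.integers(lo, hi + 1, size=spec.module_size)
        for m, p, s in zip(module, partners, bridge_scores):
            edges[(background[int(p)], m)] = int(s)

    seed_idx = rng.choice(spec.module_size, size=spec.n_seed_members, replace=False)
    module_seeds = {module[int(i)] for i in seed_idx}
    decoys: set[str] = set()
    if spec.n_decoy_seeds:
        decoy_idx = rng.choice(
            spec.n_background, size=spec.n_decoy_seeds, replace=False
        )
        decoys = {background[int(i)] for i in decoy_idx}

    truth: dict[str, str] = {}
    for node in background:
        truth[node] = ROLE_DECOY_SEED if node in decoys else ROLE_BACKGROUND
    for node in module:
        truth[node] = (
            ROLE_MODULE_SEED if node in module_seeds else ROLE_MODULE_HIDDEN
        )

    lines = ["protein1 protein2 combined_score"]
    for (a, b), score in sorted(edges.items()):
        pa, pb = f"{TAXON_PREFIX}{a}.1", f"{TAXON_PREFIX}{b}.1"
        lines.append(f"{pa} {pb} {score}")
        lines.append(f"{pb} {pa} {score}")
    links_text = "\n".join(lines) + "\n"

    seed_lines = ["# synthetic seed list (planted-module benchmark)"]
    seed_lines.extend(sorted(module_seeds | decoys))
    seed_text = "\n".join(seed_lines) + "\n"

    incident = {n for pair in edges for n in pair}
    data = GeneratedData(
        links_text=links_text,
        seed_text=seed_text,
        truth=truth,
        n_nodes=len(incident),
        n_edges=len(edges),
        spec=spec,
    )
    logger.info(
        "generated synthetic network: %d nodes, %d undirected edges, "
        "%d module seeds, %d hidden members, %d decoy seeds",
        data.n_nodes, data.n_edges, len(module_seeds),
        spec.module_size - spec.n_seed_members, len(decoys),
    )
    return data


def recovery_metrics(
    candidates: Iterable[str],
    truth: Mapping[str, str],
) -> RecoveryMetrics:
    """Score hidden-member recovery of a candidate gene set against truth."""
    hidden = {n for n, role in truth.items() if role == ROLE_MODULE_HIDDEN}
    if not hidden:
        raise ValidationError(
            "truth table contains no hidden module members to recover"
        )
    seed_roles = {ROLE_MODULE_SEED, ROLE_DECOY_SEED}
    candidate_set = set(candidates)
    nonseed = {c for c in candidate_set if truth.get(c) not in seed_roles}
    recovered = candidate_set & hidden
    recall = len(recovered) / len(hidden)
    precision = len(recovered) / len(nonseed) if nonseed else float("nan")
    return RecoveryMetrics(
        recall=recall,
        precision=precision,
        n_hidden=len(hidden),
        n_recovered=len(recovered),
        n_nonseed_candidates=len(nonseed),
    )


def expected_background_edges(spec: SyntheticSpec) -> float:
    """Binomial expectation of the background edge count."""
    return spec.background_edge_prob * comb(spec.n_background, 2)
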