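"""Readers, writers and builders for STRING-style interaction networks.

The STRING ``protein.links`` dialect is a whitespace-separated table of
``protein_a protein_b combined_score`` rows, optionally preceded by a single
header row whose third token is non-numeric.  Protein identifiers carry a
``<taxid>.`` prefix (e.g. ``3702.AT5G63310.1``) and combined scores are
integers in [150, 999]; a higher score means stronger evidence that the two
proteins interact.

The working network is an undirected :class:`networkx.Graph` whose edges
carry an integer ``weight`` of ``1000 - score``, so that high-confidence
interactions are *short* and shortest paths preferentially traverse strong
functional links.  Weights therefore lie in [1, 850].
"""

from __future__ import annotations

import logging
import re
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

SCORE_MIN = 150
SCORE_MAX = 999
WEIGHT_OFFSET = 1000

_ISOFORM_RE = re.compile(r"\.\d+$")


class ParseError(ValueError):
    """A malformed line in an input stream (reported with its line number)."""


class ValidationError(ValueError):
    """Input that parses but violates a documented invariant."""


@dataclass(frozen=True)
class InteractionRecord:
    """One parsed interaction line: two protein identifiers and a score."""

    protein_a: str
    protein_b: str
    score: int


@dataclass(frozen=True)
class SeedSet:
    """A seed (validated) gene list intersected with the network nodes.

    ``requested`` preserves the de-duplicated order of the input file;
    ``in_network`` is the usable subset; ``dropped_count`` is how many
    requested identifiers were absent from the network.
    """

    requested: tuple[str, ...]
    in_network: frozenset[str]
    dropped_count: int

    def __post_init__(self) -> None:
        if not self.in_network <= set(self.requested):
            raise ValidationError("in_network must be a subset of requested")


@contextmanager
def _as_lines(source: str | Path | IO[str] | Iterable[str]) -> Iterator[Iterable[str]]:
    """Yield an iterable of lines from a path, an open file, or raw lines."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield handle
    else:
        yield source


@contextmanager
def _as_sink(sink: str | Path | IO[str]) -> Iterator[IO[str]]:
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="\n") as handle:
            yield handle
    else:
        yield sink


def parse_string_links(
    source: str | Path | IO[str] | Iterable[str],
    taxon_prefix: str = "",
) -> list[InteractionRecord]:
    """Parse a STRING-dialect ``protein.links`` stream.

    Parameters
    ----------
    source
        Path, open text file, or iterable of lines.
    taxon_prefix
        When non-empty (e.g. ``"3702."``), keep only lines in which *both*
        protein identifiers start with the prefix; the multi-organism STRING
        dump mixes taxa in one file.  An empty prefix keeps every line.

    Returns
    -------
    list of InteractionRecord
        One record per kept data line.  Scores are parsed but not yet
        range-validated (that happens in :func:`build_network`).

    Raises
    ------
    ParseError
        On a data line with fewer than three tokens or a non-integer score.
    """
    records: list[InteractionRecord] = []
    seen_data_line = False
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise ParseError(
                    f"line {lineno}: expected 3 whitespace-separated tokens, "
                    f"got {len(tokens)}: {line!r}"
                )
            try:
                score = int(tokens[2])
            except ValueError:
                if not seen_data_line:
                    # Single leading header row ("protein1 protein2 combined_score").
                    seen_data_line = True
                    continue
                raise ParseError(
                    f"line {lineno}: non-integer score {tokens[2]!r}"
                ) from None
            seen_data_line = True
            a, b = tokens[0], tokens[1]
            if taxon_prefix and not (
                a.startswith(taxon_prefix) and b.startswith(taxon_prefix)
            ):
                continue
            records.append(InteractionRecord(a, b, score))
    logger.info("parsed %d interaction records", len(records))
    return records


def normalize_id(
    token: str,
    taxon_prefix: str = "",
    collapse_isoform: bool = False,
) -> str:
    """Normalize a STRING protein identifier to a gene-level identifier.

    Strips ``taxon_prefix`` when present and, with ``collapse_isoform``,
    removes one trailing ``.<digits>`` isoform suffix (``3702.AT5G63310.1``
    becomes ``AT5G63310``).  The operation is idempotent.
    """
    if not token:
        raise ValidationError("empty identifier token")
    out = token
    if taxon_prefix and out.startswith(taxon_prefix):
        out = out[len(taxon_prefix):]
    if collapse_isoform:
        out = _ISOFORM_RE.sub("", out, count=1)
    if not out:
        raise ValidationError(
            f"identifier {token!r} is empty after stripping prefix {taxon_prefix!r}"
        )
    return out


def normalize_records(
    records: Iterable[InteractionRecord],
    taxon_prefix: str = "",
    collapse_isoform: bool = False,
) -> list[InteractionRecord]:
    """Apply :func:`normalize_id` to both endpoints of every record."""
    return [
        InteractionRecord(
            normalize_id(r.protein_a, taxon_prefix, collapse_isoform),
            normalize_id(r.protein_b, taxon_prefix, collapse_isoform),
            r.score,
        )
        for r in records
    ]


def build_network(records: Iterable[InteractionRecord]) -> nx.Graph:
    """Build the undirected weighted network from validated records.

    Self-loops are dropped; reciprocal duplicates ``{a, b}`` / ``{b, a}``
    collapse into one undirected edge; when the same pair appears with
    conflicting scores the maximum score (minimum weight) wins and the
    conflict is logged.  Each kept edge gets ``weight = 1000 - score``.

    Raw bookkeeping (record, self-loop, duplicate and conflict counts) is
    stored in ``graph.graph`` so that directed-line and undirected-edge
    tallies can both be reported.
    """
    best: dict[tuple[str, str], int] = {}
    n_records = 0
    n_self_loops = 0
    n_duplicates = 0
    n_conflicts = 0
    for rec in records:
        n_records += 1
        if not SCORE_MIN <= rec.score <= SCORE_MAX:
            raise ValidationError(
                f"score {rec.score} outside [{SCORE_MIN}, {SCORE_MAX}] for "
                f"pair ({rec.protein_a}, {rec.protein_b})"
            )
        if rec.protein_a == rec.protein_b:
            n_self_loops += 1
            continue
        key = (
            (rec.protein_a, rec.protein_b)
            if rec.protein_a < rec.protein_b
            else (rec.protein_b, rec.protein_a)
        )
        prev = best.get(key)
        if prev is None:
            best[key] = rec.score
        else:
            n_duplicates += 1
            if prev != rec.score:
                n_conflicts += 1
                logger.warning(
                    "conflicting scores %d and %d for pair %s; keeping max",
                    prev, rec.score, key,
                )
                best[key] = max(prev, rec.score)
    graph = nx.Graph()
    for (a, b), score in best.items():
        graph.add_edge(a, b, weight=WEIGHT_OFFSET - score)
    graph.graph.update(
        n_records=n_records,
        n_self_loops=n_self_loops,
        n_duplicates=n_duplicates,
        n_conflicts=n_conflicts,
    )
    logger.info(
        "built network: %d nodes, %d undirected edges from %d records "
        "(%d self-loops, %d duplicates, %d score conflicts)",
        graph.number_of_nodes(), graph.number_of_edges(),
        n_records, n_self_loops, n_duplicates, n_conflicts,
    )
    return graph


def read_seed_list(
    source: str | Path | IO[str] | Iterable[str],
    network: nx.Graph,
) -> SeedSet:
    """Read a seed gene list (one identifier per line, ``#`` comments).

    Duplicates collapse; identifiers absent from the network are counted and
    logged but not fatal.  An empty in-network set is an error because the
    analysis cannot run without seeds.
    """
    requested: list[str] = []
    seen: set[str] = set()
    with _as_lines(source) as lines:
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line not in seen:
                seen.add(line)
                requested.append(line)
    in_network = frozenset(g for g in requested if g in network)
    dropped = len(requested) - len(in_network)
    if dropped:
        logger.warning(
            "%d of %d seed identifiers not found in network", dropped, len(requested)
        )
    if not in_network:
        raise ValidationError("no seed identifiers present in the network")
    return SeedSet(tuple(requested), in_network, dropped)


EDGE_TABLE_HEADER = "node_a\tnode_b\tweight"


def write_edge_table(
    network: nx.Graph,
    sink: str | Path | IO[str],
    header_comments: Sequence[str] = (),
) -> None:
    """Write the network as a TSV edge table, lexicographically ordered.

    Rows are ``node_a<TAB>node_b<TAB>weight`` with ``node_a < node_b``; the
    ordering is deterministic so repeated writes are byte-identical.
    Optional comment lines (without the leading ``#``) precede the header.
    """
    rows = sorted(
        (min(a, b), max(a, b), data["weight"])
        for a, b, data in network.edges(data=True)
    )
    with _as_sink(sink) as out:
        for comment in header_comments:
            out.write(f"# {comment}\n")
        out.write(EDGE_TABLE_HEADER + "\n")
        for a, b, w in rows:
            out.write(f"{a}\t{b}\t{w}\n")


def read_edge_table(source: str | Path | IO[str] | Iterable[str]) -> nx.Graph:
    """Read an edge table written by :func:`write_edge_table`.

    Weights are validated against [1, 850]; comment lines are ignored.  The
    write/read round trip is an identity on the network.
    """
    graph = nx.Graph()
    with _as_lines(source) as lines:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line == EDGE_TABLE_HEADER:
                continue
            tokens = line.split("\t")
            if len(tokens) != 3:
                raise ParseError(f"line {lineno}: expected 3 tab-separated fields")
            a, b, weight_str = tokens
            try:
                weight = int(weight_str)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer weight {weight_str!r}"
                ) from None
            if not 1 <= weight <= WEIGHT_OFFSET - SCORE_MIN:
                raise ValidationError(
                    f"line {lineno}: weight {weight} outside [1, 850]"
                )
            if a == b:
                raise ValidationError(f"line {lineno}: self-loop on {a!r}")
            graph.add_edge(a, b, weight=weight)
    return graph
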