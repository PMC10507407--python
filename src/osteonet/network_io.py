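"""Scored protein-protein interaction networks: containers, I/O, and filtering.

The analyzed object is a simple undirected graph whose nodes are protein
symbols and whose edges carry a STRING-style combined confidence score in
[0, 1].  Networks are built from STRING export TSV files (``node1``,
``node2``, ``combined_score``; both the 0-1 and the 0-1000 integer score
dialects are accepted), restricted to high-confidence edges, and optionally
pruned down to a small connected core around a roster of seed proteins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

ORIGIN_SEED = "seed"
ORIGIN_PARTNER = "predicted_partner"

__all__ = [
    "ProteinNode",
    "ScoredEdge",
    "InteractionNetwork",
    "StringFormatError",
    "InfeasibleReductionError",
    "read_string_tsv",
    "write_network",
    "read_roster",
    "filter_by_confidence",
    "reduce_to_connected_core",
    "assign_origins",
]


class StringFormatError(ValueError):
    """A STRING export file is missing a required column or malformed."""


class InfeasibleReductionError(ValueError):
    """Seed proteins do not sit in a single connected component."""


@dataclass
class ProteinNode:
    """A protein in the interaction network.

    ``origin`` records provenance: a seed protein selected from the
    experimental proteome, or a functional partner predicted by the
    interaction database.  It is ``None`` until rosters are applied.
    """

    identifier: str
    display_name: str = ""
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        self.identifier = self.identifier.strip()
        if not self.identifier:
            raise ValueError("node identifier must be non-empty")
        if self.origin not in (None, ORIGIN_SEED, ORIGIN_PARTNER):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass(frozen=True)
class ScoredEdge:
    """An undirected scored interaction between two distinct proteins."""

    endpoint_a: str
    endpoint_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.endpoint_a == self.endpoint_b:
            raise ValueError(f"self-loop on {self.endpoint_a!r}")
        if not 0.0 <= self.combined_score <= 1.0:
            raise ValueError(f"combined_score {self.combined_score} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        a, b = sorted((self.endpoint_a, self.endpoint_b))
        return (a, b)


class InteractionNetwork:
    """Simple undirected graph with scored edges and node provenance.

    No self-loops, no parallel edges.  Iteration orders (nodes, edges,
    neighbors) are sorted by identifier so every computation downstream is
    independent of insertion order.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, ProteinNode] = {}
        self._adj: dict[str, dict[str, float]] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node: ProteinNode | str) -> ProteinNode:
        if isinstance(node, str):
            node = ProteinNode(identifier=node)
        existing = self._nodes.get(node.identifier)
        if existing is not None:
            return existing
        self._nodes[node.identifier] = node
        self._adj[node.identifier] = {}
        return node

    def add_edge(self, a: str, b: str, score: float) -> None:
        a, b = a.strip(), b.strip()
        edge = ScoredEdge(a, b, float(score))  # validates
        self.add_node(a)
        self.add_node(b)
        self._adj[a][b] = edge.combined_score
        self._adj[b][a] = edge.combined_score

    def remove_node(self, identifier: str) -> None:
        for other in list(self._adj[identifier]):
            del self._adj[other][identifier]
        del self._adj[identifier]
        del self._nodes[identifier]

    # -- queries -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._nodes

    def node(self, identifier: str) -> ProteinNode:
        return self._nodes[identifier]

    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    def neighbors(self, identifier: str) -> list[str]:
        return sorted(self._adj[identifier])

    def degree(self, identifier: str) -> int:
        return len(self._adj[identifier])

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, ())

    def score(self, a: str, b: str) -> float:
        return self._adj[a][b]

    def edges(self) -> Iterator[ScoredEdge]:
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield ScoredEdge(a, b, self._adj[a][b])

    def isolated_nodes(self) -> list[str]:
        return sorted(v for v in self._nodes if not self._adj[v])

    # -- structure ---------------------------------------------------------
    def component_of(self, start: str) -> set[str]:
        """Breadth-first connected component containing ``start``."""
        seen = {start}
        queue = [start]
        while queue:
            v = queue.pop()
            for u in self._adj[v]:
                if u not in seen:
                    seen.add(u)
                    queue.append(u)
        return seen

    def connected_components(self) -> list[set[str]]:
        """Components in order of their smallest member identifier."""
        remaining = set(self._nodes)
        comps = []
        for v in sorted(self._nodes):
            if v in remaining:
                comp = self.component_of(v)
                remaining -= comp
                comps.append(comp)
        return comps

    def is_connected(self) -> bool:
        if not self._nodes:
            return True
        return len(self.component_of(next(iter(sorted(self._nodes))))) == self.n_nodes

    def subgraph(self, keep: Iterable[str]) -> "InteractionNetwork":
        keep = set(keep)
        sub = InteractionNetwork()
        for v in sorted(keep):
            sub.add_node(self._nodes[v])
        for e in self.edges():
            if e.endpoint_a in keep and e.endpoint_b in keep:
                sub.add_edge(e.endpoint_a, e.endpoint_b, e.combined_score)
        return sub

    def copy(self) -> "InteractionNetwork":
        return self.subgraph(self._nodes)


# ---------------------------------------------------------------------------
# I/O

_REQUIRED = ("node1", "node2", "combined_score")


def _normalize_header(name: str) -> str:
    return name.strip().lstrip("#").lower()


def read_string_tsv(path: str | Path) -> InteractionNetwork:
    """Parse a STRING export TSV into an :class:`InteractionNetwork`.

    Requires columns ``node1``, ``node2``, ``combined_score`` (a leading
    ``#`` on the header, as in raw STRING exports, is tolerated; extra
    columns are ignored).  Scores given on the 0-1000 integer scale are
    divided by 1000.  Duplicate unordered pairs collapse to the maximum
    score; self-loop rows are skipped with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [_normalize_header(c) for c in df.columns]
    for col in _REQUIRED:
        if col not in df.columns:
            raise StringFormatError(f"missing required column {col!r} in {path}")

    try:
        scores = df["combined_score"].astype(float)
    except ValueError as exc:
        raise StringFormatError(f"non-numeric combined_score in {path}: {exc}") from exc
    if scores.max() > 1.0:
        scores = scores / 1000.0  # STRING integer dialect

    net = InteractionNetwork()
    for idx, (a, b, s) in enumerate(zip(df["node1"], df["node2"], scores)):
        line_no = idx + 2  # header is line 1
        a, b = str(a).strip(), str(b).strip()
        if not 0.0 <= s <= 1.0:
            raise ValueError(
                f"combined_score {s} outside [0, 1] at line {line_no} of {path}"
            )
        if a == b:
            warnings.warn(f"skipping self-loop {a!r} at line {line_no} of {path}")
            continue
        if net.has_edge(a, b):
            s = max(s, net.score(a, b))
        net.add_edge(a, b, s)
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> Path:
    """Write the network in the STRING TSV dialect (scores on [0, 1]).

    Edges are written in sorted order with full float precision, so
    ``read_string_tsv(write_network(net))`` reproduces the node set, edge
    set, and scores exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for e in net.edges():
            fh.write(f"{e.endpoint_a}\t{e.endpoint_b}\t{e.combined_score!r}\n")
        # isolated nodes have no edge row; record them as comments so the
        # round trip preserves the node set
        for v in net.isolated_nodes():
            fh.write(f"# isolated\t{v}\n")
    return path


def read_roster(path: str | Path) -> list[str]:
    """Read a protein roster: one identifier per line, ``#`` comments allowed.

    Duplicates are removed (keeping first occurrence) with a warning; an
    empty roster is an error.
    """
    seen: dict[str, None] = {}
    n_dups = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in seen:
            n_dups += 1
        else:
            seen[line] = None
    if n_dups:
        warnings.warn(f"{n_dups} duplicate roster entries in {path} removed")
    if not seen:
        raise ValueError(f"roster {path} is empty")
    return list(seen)


def assign_origins(
    net: InteractionNetwork, seeds: Iterable[str], partners: Iterable[str] = ()
) -> None:
    """Mark each node as experimental seed or predicted partner, in place.

    Nodes not named in either roster default to predicted partners (the
    interaction database added them).
    """
    seeds = set(seeds)
    partners = set(partners)
    for v in net.node_ids():
        net.node(v).origin = ORIGIN_SEED if v in seeds else ORIGIN_PARTNER
    missing = seeds - set(net.node_ids())
    if missing:
        warnings.warn(f"seed proteins absent from network: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Filtering and reduction


def filter_by_confidence(
    net: InteractionNetwork, min_score: float = 0.9
) -> InteractionNetwork:
    """Keep exactly the edges with ``combined_score >= min_score``.

    The comparison is inclusive — a score equal to the confidence level
    survives.  All nodes are retained; nodes left without any edge are
    reported by :meth:`InteractionNetwork.isolated_nodes` so the caller
    decides their fate.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError(f"min_score {min_score} outside [0, 1]")
    out = InteractionNetwork()
    for v in net.node_ids():
        out.add_node(net.node(v))
    for e in net.edges():
        if e.combined_score >= min_score:
            out.add_edge(e.endpoint_a, e.endpoint_b, e.combined_score)
    return out


def reduce_to_connected_core(
    net: InteractionNetwork, seeds: list[str], max_partners: int
) -> InteractionNetwork:
    """Prune predicted partners down to a small connected core of seeds.

    Deterministic stand-in for the interactive procedure of repeatedly
    re-querying the interaction database with fewer allowed interactors:
    non-seed nodes are removed greedily in increasing-degree order (ties
    broken lexicographically) as long as the remaining subgraph stays a
    single connected component containing every seed, stopping once at most
    ``max_partners`` non-seed nodes remain or no further removal preserves
    connectivity.
    """
    if max_partners < 0:
        raise ValueError("max_partners must be >= 0")
    missing = [s for s in seeds if s not in net]
    if missing:
        raise KeyError(f"seed proteins not in network: {missing}")
    seed_set = set(seeds)

    comp = net.component_of(seeds[0]) if seeds else set()
    outside = sorted(seed_set - comp)
    if outside:
        raise InfeasibleReductionError(
            f"seed proteins disconnected from the rest: {outside}"
        )
    sub = net.subgraph(comp)

    while True:
        non_seeds = [v for v in sub.node_ids() if v not in seed_set]
        if len(non_seeds) <= max_partners:
            break
        candidates = sorted(non_seeds, key=lambda v: (sub.degree(v), v))
        removed = False
        for v in candidates:
            trial = sub.subgraph(set(sub.node_ids()) - {v})
            if trial.n_nodes and trial.is_connected():
                sub = trial
                removed = True
                break
        if not removed:
            break
    return sub
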