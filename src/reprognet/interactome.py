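"""Cleaning raw interaction records into a simple undirected interactome.

The cleaned interactome is the control network for every connectivity
statistic downstream.  Cleaning applies, in order per row: drop genetic
interactions (keep physical only), drop rows with either interactor from a
different species than the requested taxon, drop self-loops, and collapse
duplicate edges (A-B and B-A are the same unordered pair, regardless of
evidence metadata).  Nodes are the endpoints of surviving edges: proteins
that appear only in removed rows are not kept as isolated nodes.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import EdgeRecord, normalize_symbol

logger = logging.getLogger(__name__)


class Interactome:
    """A simple undirected graph over protein symbols.

    Thin wrapper around :class:`networkx.Graph` that guarantees the graph is
    simple (no self-loops, no parallel edges), carries per-rule removal
    counts from cleaning, and caches an integer-indexed adjacency for the
    resampling-heavy operations.
    """

    def __init__(self, graph: nx.Graph, provenance: Mapping[str, int] | None = None):
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"interactome must be simple; found self-loops {loops[:3]}")
        self._graph = graph
        self.provenance: dict[str, int] = dict(provenance or {})
        self._index_cache: tuple[list[str], dict[str, int], list[set[int]]] | None = None

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        provenance: Mapping[str, int] | None = None,
    ) -> "Interactome":
        g = nx.Graph()
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                raise ValueError(f"self-loop {a}-{b} not allowed in a cleaned interactome")
            g.add_edge(a, b)
        return cls(g, provenance)

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self._graph.edges}

    def number_of_nodes(self) -> int:
        return self._graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._graph

    def degree_histogram(self) -> dict[int, int]:
        """Map degree k -> number of nodes with that degree.

        Counts sum to the number of nodes; this is the raw P(k) used for the
        log-log power-law fit.
        """
        return dict(Counter(d for _, d in self._graph.degree()))

    # -- fast integer view ----------------------------------------------
    def indexed(self) -> tuple[list[str], dict[str, int], list[set[int]]]:
        """Return (labels, label->index, adjacency-as-int-sets), cached.

        Node order is sorted by symbol so the view, and everything seeded on
        it, is deterministic for a given edge set.
        """
        if self._index_cache is None:
            labels = sorted(self._graph.nodes)
            index = {s: i for i, s in enumerate(labels)}
            adjacency: list[set[int]] = [
                {index[nb] for nb in self._graph.adj[s]} for s in labels
            ]
            self._index_cache = (labels, index, adjacency)
        return self._index_cache

    # -- persistence -----------------------------------------------------
    def to_edge_tsv(self, path: str | Path) -> None:
        """Write the cleaned graph as a two-column TSV edge list."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("symbol_a\tsymbol_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in self._graph.edges):
                handle.write(f"{a}\t{b}\n")

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "Interactome":
        g = nx.Graph()
        with open(path, encoding="utf-8") as handle:
            header = handle.readline()
            if not header.startswith("symbol_a"):
                raise ValueError(f"{path}: expected a 'symbol_a\\tsymbol_b' header")
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = line.rstrip("\n").split("\t")[:2]
                g.add_edge(normalize_symbol(a), normalize_symbol(b))
        return cls(g)


def clean_interactome(records: Sequence[EdgeRecord], taxon: int) -> Interactome:
    """Apply the cleaning rules and return the resulting interactome.

    Keeps physical interactions with both interactors from ``taxon``, drops
    self-loops, and collapses duplicate unordered pairs.  ``provenance``
    counts removals per rule (first matching rule wins per row) and sums to
    ``len(records) - number_of_edges``.
    """
    if taxon <= 0:
        raise ValueError("taxon must be a positive NCBI taxonomy ID")
    provenance: Counter[str] = Counter()
    g = nx.Graph()
    for r in records:
        if r.system_type != "physical":
            provenance["genetic"] += 1
        elif r.organism_a != taxon or r.organism_b != taxon:
            provenance["off_species"] += 1
        elif r.symbol_a == r.symbol_b:
            provenance["self_loop"] += 1
        elif g.has_edge(r.symbol_a, r.symbol_b):
            provenance["duplicate"] += 1
        else:
            g.add_edge(r.symbol_a, r.symbol_b)
    if not records:
        logger.warning("clean_interactome called with no input records")
    return Interactome(g, provenance)
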