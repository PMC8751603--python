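"""The interconnectivity statistic and joint chemical-protein networks.

Interconnectivity of a query set is the fraction of its mapped members that
lie in the largest connected component of the subgraph induced by the query
on the interactome.  Components are found by breadth-first search restricted
to the query; the denominator is the number of query symbols present in the
interactome (not the raw query size), and a query is de-duplicated before
counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .interactome import Interactome
from .io import ChemTargetRecord, normalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InterconnectivityResult:
    """Size accounting for one interconnectivity evaluation.

    ``fraction`` is ``n_lcc / n_mapped``, or ``None`` when no query symbol
    maps into the interactome (undefined, not an error).
    """

    n_input: int
    n_mapped: int
    n_lcc: int
    fraction: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_lcc <= self.n_mapped <= self.n_input:
            raise ValueError(
                f"inconsistent sizes: lcc={self.n_lcc} mapped={self.n_mapped} "
                f"input={self.n_input}"
            )


def largest_component_size(adjacency: Sequence[set[int]], members: set[int]) -> int:
    """Size of the largest connected component of the induced subgraph.

    ``adjacency`` is an integer-indexed neighbour-set list; ``members`` the
    induced node set.  Iterative BFS, O(sum of member degrees).
    """
    best = 0
    seen: set[int] = set()
    for start in members:
        if start in seen:
            continue
        seen.add(start)
        stack = [start]
        size = 0
        while stack:
            node = stack.pop()
            size += 1
            for nb in adjacency[node]:
                if nb in members and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if size > best:
            best = size
    return best


def largest_connected_fraction(
    g: Interactome, query: Iterable[str]
) -> InterconnectivityResult:
    """Interconnectivity of ``query`` on interactome ``g``.

    A singleton mapped query is connected by definition (fraction 1.0).
    """
    symbols = {normalize_symbol(s) for s in query}
    if not symbols:
        raise ValueError("query must be non-empty")
    _, index, adjacency = g.indexed()
    members = {index[s] for s in symbols if s in index}
    if not members:
        logger.warning("no query symbol maps into the interactome; fraction undefined")
        return InterconnectivityResult(len(symbols), 0, 0, None)
    n_lcc = largest_component_size(adjacency, members)
    return InterconnectivityResult(len(symbols), len(members), n_lcc, n_lcc / len(members))


@dataclass(frozen=True)
class JointNetwork:
    """Bipartite chemical-target edges plus the induced PPI layer.

    ``chem_target_edges`` connect chemicals to proteins only; ``ppi_edges``
    are the interactome edges induced among the protein targets.
    """

    protein_nodes: frozenset[str]
    chemical_nodes: frozenset[str]
    ppi_edges: frozenset[frozenset[str]]
    chem_target_edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for chem, prot in self.chem_target_edges:
            if chem not in self.chemical_nodes or prot not in self.protein_nodes:
                raise ValueError(f"edge {chem}-{prot} does not join a chemical to a protein")

    def protein_interconnectivity(self, g: Interactome) -> InterconnectivityResult:
        """Interconnectivity of the protein layer, ignoring chemical links."""
        return largest_connected_fraction(g, self.protein_nodes)


def build_joint_network(
    g: Interactome,
    table: Sequence[ChemTargetRecord],
    chemicals: Iterable[str],
    score_threshold: float = 0.4,
) -> JointNetwork:
    """Build the joint chemical-protein network for a set of chemicals.

    Protein nodes are the targets of the listed chemicals at or above the
    confidence threshold (default 0.4, medium stringency); PPI edges are the
    interactome edges induced among those targets.  Proteins absent from the
    interactome are still protein nodes (they simply carry no PPI edges).
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must be on [0, 1]")
    wanted = {str(c) for c in chemicals}
    chem_edges: set[tuple[str, str]] = set()
    proteins: set[str] = set()
    matched: set[str] = set()
    for r in table:
        if r.chemical_id in wanted and r.combined_score >= score_threshold:
            matched.add(r.chemical_id)
            proteins.add(r.protein)
            chem_edges.add((r.chemical_id, r.protein))
    if not matched:
        logger.warning("no chemical in %s matched the table at threshold %.2f",
                       sorted(wanted)[:5], score_threshold)
    adj = g.graph.adj
    ppi_edges: set[frozenset[str]] = set()
    for p in proteins:
        if p in adj:
            for nb in adj[p]:
                if nb in proteins:
                    ppi_edges.add(frozenset((p, nb)))
    return JointNetwork(
        protein_nodes=frozenset(proteins),
        chemical_nodes=frozenset(matched),
        ppi_edges=frozenset(ppi_edges),
        chem_target_edges=frozenset(chem_edges),
    )
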