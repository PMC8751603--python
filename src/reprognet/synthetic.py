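"""Synthetic interactomes, chemical-target tables and compound universes.

These generators reproduce the statistical structure the analysis assumes,
so every stage is testable without database downloads:

* a preferential-attachment graph with the heavy-tailed degree distribution
  of real interactomes (and an Erdos-Renyi control of matched density);
* chemical-target tables whose targets are either scattered uniformly
  (null behaviour) or drawn from a densely wired *planted module*,
  emulating the elevated interconnectivity observed for reprogramming-SM
  targets;
* compound universes with exactly controlled overlap for Fisher tests.

The planted module is chosen greedily as a high-internal-degree node set of
the *existing* graph (no edges are added), so the null degree sequence is
untouched and calibration tests against random sampling stay honest.  All
generators take explicit seeds and never touch global random state.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .interactome import Interactome
from .io import ChemTargetRecord


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic benchmark instance.

    Defaults describe the standard benchmark: a 3000-node preferential-
    attachment interactome (2 edges per new node), a 100-node planted
    module, and 5 chemicals with 30 targets each drawn from the module with
    probability ``purity``.
    """

    n_nodes: int = 3000
    attachment_edges: int = 2
    er_edge_prob: float = 0.0013
    planted_module_size: int = 100
    purity: float = 1.0
    n_chemicals: int = 5
    targets_per_chemical: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be on [0, 1]")
        if self.planted_module_size > self.n_nodes:
            raise ValueError("planted module cannot exceed the graph")


def _label(i: int) -> str:
    return f"P{i:05d}"


def gen_scale_free(n: int, m: int, seed: int) -> Interactome:
    """Preferential-attachment (Barabasi-Albert) interactome.

    Each new node attaches to ``m`` existing nodes with probability
    proportional to degree; the result is connected and simple.  ``m = 1``
    grows a tree.
    """
    if n <= m:
        raise ValueError(f"need n > m >= 1, got n={n}, m={m}")
    g = nx.barabasi_albert_graph(n, m, seed=seed)
    return Interactome(nx.relabel_nodes(g, _label))


def gen_er(n: int, p: float, seed: int) -> Interactome:
    """Erdos-Renyi G(n, p) control graph (no heavy tail)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    g = nx.fast_gnp_random_graph(n, p, seed=seed)
    return Interactome(nx.relabel_nodes(g, _label))


def planted_module(g: Interactome, size: int) -> frozenset[str]:
    """Deterministic dense node set: greedy maximisation of internal degree.

    Starts from the highest-degree node and repeatedly adds the node with
    the most edges into the current set (ties broken by higher total degree,
    then lexicographically smaller symbol), giving a well-interconnected
    module without altering the graph.
    """
    if not 1 <= size <= g.number_of_nodes():
        raise ValueError("module size must be between 1 and the number of nodes")
    labels, _, adjacency = g.indexed()
    degree = [len(a) for a in adjacency]
    start = max(range(len(labels)), key=lambda i: (degree[i], labels[i]))
    chosen = {start}
    internal = [0] * len(labels)  # edges from each node into `chosen`
    heap: list[tuple[int, int, str, int]] = []

    def absorb(node: int) -> None:
        for nb in adjacency[node]:
            if nb not in chosen:
                internal[nb] += 1
                heapq.heappush(heap, (-internal[nb], -degree[nb], labels[nb], nb))

    absorb(start)
    while len(chosen) < size:
        best: int | None = None
        while heap:
            neg_internal, _, _, i = heapq.heappop(heap)
            if i not in chosen and -neg_internal == internal[i]:
                best = i
                break
        if best is None:  # module exhausted its component; take the best leftover hub
            best = max(
                (i for i in range(len(labels)) if i not in chosen),
                key=lambda i: (degree[i], labels[i]),
            )
        chosen.add(best)
        absorb(best)
    return frozenset(labels[i] for i in chosen)


def gen_planted_target_map(
    g: Interactome, spec: SyntheticSpec
) -> tuple[list[ChemTargetRecord], frozenset[str]]:
    """Chemical-target table with targets concentrated in a planted module.

    Each chemical draws ``targets_per_chemical`` distinct proteins: a
    Binomial(targets, purity) number from the module, the rest uniformly
    from outside it.  Scores are fixed at combined 0.9 with experimental
    evidence only (text-mining and prediction channels zero), so the table
    survives the standard channel/confidence filters.
    """
    module = sorted(planted_module(g, spec.planted_module_size))
    rest = sorted(g.nodes - set(module))
    t = spec.targets_per_chemical
    if t > len(module) or (spec.purity < 1.0 and t > len(rest)):
        raise ValueError("targets_per_chemical exceeds the available protein pool")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    channels = {"experimental": 0.9, "database": 0.0, "textmining": 0.0, "prediction": 0.0}
    records: list[ChemTargetRecord] = []
    for c in range(spec.n_chemicals):
        k = int(rng.binomial(t, spec.purity))
        inside = rng.choice(len(module), size=k, replace=False) if k else []
        outside = rng.choice(len(rest), size=t - k, replace=False) if t - k else []
        targets = [module[int(i)] for i in inside] + [rest[int(i)] for i in outside]
        for protein in targets:
            records.append(
                ChemTargetRecord(
                    chemical_id=f"CHEM{c:03d}",
                    protein=protein,
                    channel_scores=dict(channels),
                    combined_score=0.9,
                )
            )
    return records, frozenset(module)


def gen_overlap_universes(
    n_universe: int, n_a: int, n_b: int, n_overlap: int, seed: int
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """A compound universe and two subsets with exact overlap cardinality."""
    if n_overlap > min(n_a, n_b):
        raise ValueError("requested overlap exceeds the smaller set")
    if n_a + n_b - n_overlap > n_universe:
        raise ValueError("sets cannot fit in the universe with that overlap")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    compounds = [f"M{i:05d}" for i in range(n_universe)]
    order = rng.permutation(n_universe)
    a = [compounds[int(i)] for i in order[:n_a]]
    b = a[:n_overlap] + [compounds[int(i)] for i in order[n_a : n_a + n_b - n_overlap]]
    return frozenset(compounds), frozenset(a), frozenset(b)
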