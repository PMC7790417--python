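"""pathFinder-style seed expansion through a prior interaction network.

Selected-module genes are expanded to every gene reachable in ``k`` or fewer
steps in the prior network (edges traversed as undirected: interaction
databases mix directed and undirected evidence), and the differential
expression list is unioned in afterwards. Provenance is tracked per gene
with priority module > DE > expanded.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

__all__ = ["SeedSet", "expand_seeds"]


@dataclass
class SeedSet:
    """Seeding genes for predictive-network learning."""

    genes: set[str]
    provenance: dict[str, str] = field(default_factory=dict)  # module|DE|expanded
    k_used: int = 0

    def by_provenance(self, tag: str) -> set[str]:
        return {g for g, t in self.provenance.items() if t == tag}


def expand_seeds(
    prior: nx.Graph,
    seeds: Iterable[str],
    k: int = 3,
    de_genes: Iterable[str] | None = None,
) -> SeedSet:
    """Multi-source BFS from the module seeds, depth ``k``, over the prior.

    Seeds absent from the prior are kept (provenance "module") with a
    warning. DE genes are added after expansion; a gene that is both DE and
    expanded keeps the DE tag, and module membership beats both.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if prior.number_of_nodes() == 0:
        raise ValueError("prior network is empty")
    graph = prior.to_undirected(as_view=True) if prior.is_directed() else prior
    seeds = set(map(str, seeds))
    missing = seeds - set(graph.nodes)
    if missing:
        warnings.warn(
            f"{len(missing)} seed gene(s) absent from the prior network; kept"
        )
    provenance = {g: "module" for g in seeds}
    dist = {g: 0 for g in seeds}
    queue = deque(g for g in seeds if g in graph)
    while queue:
        node = queue.popleft()
        if dist[node] == k:
            continue
        for nbr in graph.neighbors(node):
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                provenance.setdefault(nbr, "expanded")
                queue.append(nbr)
    for g in set(map(str, de_genes or ())):
        if provenance.get(g) != "module":
            provenance[g] = "DE"
    return SeedSet(genes=set(provenance), provenance=provenance, k_used=k)
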