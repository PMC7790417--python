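"""Key driver analysis (KDA) and the two prioritization scores.

Given a causal network and a target gene list (DE genes or selected-module
genes), KDA first restricts to a background sub-network -- the targets plus
every node with a directed path of length <= K to a target -- and then, for
every node in that sub-network and every step size h in 1..K, tests the
enrichment of the node's h-step downstream neighborhood for the target list
with a one-sided Fisher exact (hypergeometric upper-tail) test, BH-corrected
across all (node, h) tests. A node's own target membership is excluded from
both its neighborhood and its overlap so a target cannot enrich for itself.

Two ranking scores summarize a key driver's position:

* DE proximity: sum over reachable DE genes of 1/d where d is the shortest
  directed path length from the key driver,
* KD dominance: the downstream-minus-upstream difference of the analogous
  inverse-path-length sums taken over the other key drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .causalnet import CausalNetwork
from .de import bh_adjust

__all__ = [
    "KdaTable",
    "downstream_neighborhood",
    "background_subnetwork",
    "run_kda",
    "count_appearances",
    "de_proximity",
    "kd_dominance",
    "kd_score_table",
]


@dataclass
class KdaTable:
    """Per (node, step size) enrichment results and the key-driver call set."""

    table: pd.DataFrame  # node, h, neighborhood, overlap, universe, p, fdr
    kd_set: set[str] = field(default_factory=set)
    universe: set[str] = field(default_factory=set)


def _as_graph(network: CausalNetwork | nx.DiGraph) -> nx.DiGraph:
    return network.graph if isinstance(network, CausalNetwork) else network


def downstream_neighborhood(
    network: CausalNetwork | nx.DiGraph, node: str, h: int
) -> set[str]:
    """Nodes reachable from ``node`` by a directed path of length <= h,
    excluding the node itself."""
    graph = _as_graph(network)
    if node not in graph:
        raise KeyError(f"unknown node {node!r}")
    dist = nx.single_source_shortest_path_length(graph, node, cutoff=h)
    return {g for g, d in dist.items() if d > 0}


def background_subnetwork(
    network: CausalNetwork | nx.DiGraph, targets: Iterable[str], K: int = 6
) -> nx.DiGraph:
    """Induced subgraph on in-network targets plus their K-step upstream
    neighborhoods."""
    graph = _as_graph(network)
    present = {t for t in targets if t in graph}
    if not present:
        raise ValueError("no target gene is present in the network")
    keep = set(present)
    rev = graph.reverse(copy=False)
    for t in present:
        up = nx.single_source_shortest_path_length(rev, t, cutoff=K)
        keep.update(up)
    return graph.subgraph(keep).copy()


def run_kda(
    network: CausalNetwork | nx.DiGraph,
    targets: Iterable[str],
    K: int = 6,
    fdr: float = 0.05,
    universe: str = "network",
    min_targets: int = 10,
) -> KdaTable:
    """Fisher-exact key driver analysis at step sizes 1..K.

    Candidate nodes come from the background sub-network (targets plus
    their K-step upstream neighborhoods); the Fisher universe is the whole
    network's node set by default (``universe="background"`` restricts it
    to the sub-network, but when most sub-network nodes are targets that
    choice saturates the universe and no enrichment can be detected). Key
    drivers are the nodes whose downstream neighborhood is enriched
    (BH FDR < ``fdr``) at any step size 1..K. Target lists smaller than
    ``min_targets`` (in-network) are refused with a warning -- enrichment
    statistics on a handful of genes are not meaningful (the same reason
    gene-set tools enforce a minimum set size).
    """
    graph = _as_graph(network)
    targets = set(targets)
    present = targets & set(graph.nodes)
    if present and len(present) < min_targets:
        warnings.warn(
            f"only {len(present)} in-network target gene(s); KDA skipped"
        )
        present = set()
    if not present:
        return KdaTable(
            table=pd.DataFrame(
                columns=["node", "h", "neighborhood", "overlap", "universe",
                         "targets", "p", "fdr"]
            ),
            kd_set=set(),
            universe=set(),
        )
    sub = background_subnetwork(graph, present, K=K)
    univ = set(graph.nodes) if universe == "network" else set(sub.nodes)
    test_graph = graph if universe == "network" else sub
    if len(univ - targets) < 2:
        warnings.warn("degenerate universe: fewer than 2 non-target nodes")
    rows = []
    for node in sorted(sub.nodes):
        node_targets = (present & univ) - {node}
        n_univ = len(univ) - 1  # candidate node itself excluded
        k_targ = len(node_targets)
        dist = nx.single_source_shortest_path_length(test_graph, node, cutoff=K)
        for h in range(1, K + 1):
            neigh = {g for g, d in dist.items() if 0 < d <= h}
            overlap = len(neigh & node_targets)
            p = float(hypergeom.sf(overlap - 1, n_univ, k_targ, len(neigh)))
            rows.append((node, h, len(neigh), overlap, n_univ, k_targ, p))
    table = pd.DataFrame(
        rows,
        columns=["node", "h", "neighborhood", "overlap", "universe", "targets", "p"],
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    kd_set = set(table.loc[table["fdr"] < fdr, "node"])
    return KdaTable(table=table, kd_set=kd_set, universe=univ)


def count_appearances(
    kda_results: Mapping[str, KdaTable],
    threshold: int = 3,
) -> tuple[pd.Series, set[str], set[str]]:
    """Appearance counts across networks, plus the AS/ApP intersection.

    ``kda_results`` keys are ``"<network>|<target list>"`` (e.g.
    ``"AS_IR|de"``); a gene "appears" in a network when it is called a key
    driver for any of that network's target lists. Returns (per-gene
    appearance counts over networks, the intersection of AS-stream and
    ApP-stream key drivers, and the genes with >= ``threshold`` appearances).
    """
    if not kda_results:
        raise ValueError("no KDA results supplied")
    per_network: dict[str, set[str]] = {}
    per_stream: dict[str, set[str]] = {}
    for key, result in kda_results.items():
        network = key.split("|")[0]
        per_network.setdefault(network, set()).update(result.kd_set)
        stream = network.split("_")[0]
        per_stream.setdefault(stream, set()).update(result.kd_set)
    all_genes = sorted(set().union(*per_network.values())) if per_network else []
    counts = pd.Series(
        {g: sum(g in kds for kds in per_network.values()) for g in all_genes},
        dtype=int,
        name="appearances",
    )
    streams = list(per_stream.values())
    intersection = set.intersection(*streams) if len(streams) > 1 else set()
    top = set(counts.index[counts >= threshold])
    return counts, intersection, top


def _inverse_path_sum(graph: nx.DiGraph, source: str, targets: set[str]) -> float:
    dist = nx.single_source_shortest_path_length(graph, source)
    return sum(1.0 / d for g, d in dist.items() if g in targets and d > 0)


def de_proximity(
    network: CausalNetwork | nx.DiGraph, kd: str, de_genes: Iterable[str]
) -> float:
    """Sum of inverse shortest-directed-path lengths from ``kd`` to the DE
    genes; unreachable genes contribute 0, the key driver itself is
    excluded."""
    graph = _as_graph(network)
    if kd not in graph:
        raise KeyError(f"unknown node {kd!r}")
    targets = set(de_genes) - {kd}
    return _inverse_path_sum(graph, kd, targets)


def kd_dominance(
    network: CausalNetwork | nx.DiGraph, kd: str, kd_set: Iterable[str]
) -> float:
    """Downstream-minus-upstream inverse-path-length balance among the other
    key drivers (positive = this driver sits above its peers)."""
    graph = _as_graph(network)
    if kd not in graph:
        raise KeyError(f"unknown node {kd!r}")
    others = set(kd_set) - {kd}
    down = _inverse_path_sum(graph, kd, others)
    rev = graph.reverse(copy=False)
    up = _inverse_path_sum(rev, kd, others)
    return down - up


def kd_score_table(
    networks: Mapping[str, CausalNetwork | nx.DiGraph],
    de_lists: Mapping[str, Sequence[str]],
    kda_results: Mapping[str, KdaTable],
    threshold: int = 3,
) -> pd.DataFrame:
    """Ranked key-driver summary: appearances, DE proximity, KD dominance.

    DE proximity and dominance are summed over the networks in which the
    gene was called a key driver, using each network's own DE list
    (``de_lists`` keyed like ``networks``, by network name).
    """
    counts, _intersection, _top = count_appearances(kda_results, threshold)
    kd_by_network: dict[str, set[str]] = {}
    for key, result in kda_results.items():
        network = key.split("|")[0]
        kd_by_network.setdefault(network, set()).update(result.kd_set)
    rows = []
    for gene in counts.index:
        prox = 0.0
        dom = 0.0
        for name, net in networks.items():
            kds = kd_by_network.get(name, set())
            if gene not in kds:
                continue
            graph = _as_graph(net)
            if gene not in graph:
                continue
            prox += de_proximity(graph, gene, de_lists.get(name, ()))
            dom += kd_dominance(graph, gene, kds)
        rows.append((gene, int(counts[gene]), prox, dom))
    table = pd.DataFrame(
        rows, columns=["gene", "appearances", "de_proximity", "kd_dominance"]
    )
    return table.sort_values(
        ["appearances", "de_proximity"], ascending=False
    ).reset_index(drop=True)


def prioritize_key_drivers(
    scores: pd.DataFrame, appearance_threshold: int = 3
) -> list[str]:
    """Final key-driver call: replicated candidates with high DE proximity.

    Candidates are genes called a key driver in >= ``appearance_threshold``
    networks; among them, those whose DE-proximity reaches at least half of
    the best candidate's are kept. A master regulator sits close, in
    directed-path terms, to many DE genes, so co-dominant hubs score within
    a factor of each other, while replicated pathway intermediates and
    peripheral regulators trail the hubs by an order of magnitude. With
    <= 1 candidate no score filter is applied.
    """
    cand = scores[scores["appearances"] >= appearance_threshold]
    if len(cand) <= 1:
        return cand["gene"].tolist()
    cutoff = 0.5 * cand["de_proximity"].max()
    return cand.loc[cand["de_proximity"] >= cutoff, "gene"].tolist()
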