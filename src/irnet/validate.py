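"""Perturbation-based network validation.

After inhibiting a network node (in the study design, a statin inhibiting a
cholesterol-biosynthesis hub), downstream genes are grouped into layers by
shortest directed distance from the target, and per-layer differential
expression statistics (%DE, mean |log2FC|, mean -log10 FDR) are expected to
decay with layer if the network's topology is causally meaningful. A Fisher
test of DE enrichment among directed descendants versus the rest of the
measured universe complements the layer profile, and a Venn-style partition
compares the IR and IS response gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .causalnet import CausalNetwork

__all__ = [
    "PerturbationReport",
    "assign_layers",
    "layerwise_summary",
    "downstream_enrichment",
    "overlap_partition",
]


def _as_graph(network: CausalNetwork | nx.DiGraph) -> nx.DiGraph:
    return network.graph if isinstance(network, CausalNetwork) else network


@dataclass
class PerturbationReport:
    """Per-layer decay statistics downstream of a perturbed node."""

    table: pd.DataFrame  # layer, n_genes, n_measured, pct_de, mean_abs_lfc, ...
    monotone: dict[str, bool] = field(default_factory=dict)
    n_missing: int = 0


def assign_layers(network: CausalNetwork | nx.DiGraph, target: str) -> dict[str, int]:
    """Layer = shortest directed path length from the perturbed target
    (target itself is layer 0; unreachable genes are absent)."""
    graph = _as_graph(network)
    if target not in graph:
        raise KeyError(f"unknown target {target!r}")
    return dict(nx.single_source_shortest_path_length(graph, target))


def layerwise_summary(
    layers: Mapping[str, int],
    de: pd.DataFrame,
    fdr: float = 0.05,
    max_layer: int = 6,
) -> PerturbationReport:
    """Per-layer %DE, mean |log2FC| and mean -log10(FDR) decay profile.

    Layers beyond ``max_layer`` are pooled into a final ">=max" row. Genes
    without DE measurements are excluded (their count is reported). The
    monotonicity flags record whether each statistic is non-increasing from
    layer 1 through ``max_layer`` (ignoring empty layers).
    """
    rows = []
    n_missing = 0
    by_layer: dict[int, list[str]] = {}
    for gene, layer in layers.items():
        if layer == 0:
            continue
        by_layer.setdefault(min(layer, max_layer), []).append(gene)
    for layer in range(1, max_layer + 1):
        genes = by_layer.get(layer, [])
        measured = [g for g in genes if g in de.index]
        n_missing += len(genes) - len(measured)
        if not measured:
            rows.append((layer, len(genes), 0, np.nan, np.nan, np.nan))
            continue
        sub = de.loc[measured]
        pct = 100.0 * float((sub["fdr"] < fdr).mean())
        mean_lfc = float(sub["log2fc"].abs().mean())
        mean_sig = float(-np.log10(np.maximum(sub["fdr"], 1e-300)).mean())
        rows.append((layer, len(genes), len(measured), pct, mean_lfc, mean_sig))
    table = pd.DataFrame(
        rows,
        columns=["layer", "n_genes", "n_measured", "pct_de", "mean_abs_lfc",
                 "mean_neglog_fdr"],
    )
    monotone = {}
    for col in ("pct_de", "mean_abs_lfc", "mean_neglog_fdr"):
        vals = table[col].dropna().to_numpy()
        monotone[col] = bool(np.all(np.diff(vals) <= 1e-12)) if len(vals) > 1 \
            else True
    return PerturbationReport(table=table, monotone=monotone, n_missing=n_missing)


def downstream_enrichment(
    network: CausalNetwork | nx.DiGraph,
    target: str,
    de_genes: Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-sided Fisher exact p for DE enrichment among the target's directed
    descendants within the measured universe."""
    graph = _as_graph(network)
    if target not in graph:
        raise KeyError(f"unknown target {target!r}")
    universe = set(universe) - {target}
    descendants = (nx.descendants(graph, target) & universe)
    if not descendants:
        raise ValueError(f"{target!r} has no descendants in the universe")
    de_in_univ = set(de_genes) & universe
    overlap = len(descendants & de_in_univ)
    return float(
        hypergeom.sf(overlap - 1, len(universe), len(de_in_univ), len(descendants))
    )


def overlap_partition(
    de_a: Iterable[str], de_b: Iterable[str]
) -> tuple[tuple[int, int, int], tuple[set[str], set[str], set[str]]]:
    """Exact (a-only, shared, b-only) partition of two DE gene lists."""
    a, b = set(de_a), set(de_b)
    a_only, shared, b_only = a - b, a & b, b - a
    return (len(a_only), len(shared), len(b_only)), (a_only, shared, b_only)
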