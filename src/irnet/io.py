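"""Plain-text readers/writers for the pipeline's exchange formats.

Everything is TSV/CSV/JSON/SIF/GMT so that any stage can be rerun standalone
and outputs stay diffable. Counts are genes x samples with a header row of
sample ids; networks are edge lists; gene sets are GMT.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

# ---------------------------------------------------------------- matrices


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------- networks


def write_sif(graph: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    """Write an edge list as SIF (``source<TAB>interaction<TAB>target``)."""
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def read_sif(path: str | Path, directed: bool = False) -> nx.Graph:
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:
                graph.add_edge(parts[0], parts[2])
            elif len(parts) == 2:
                graph.add_edge(parts[0], parts[1])
    return graph


def write_edge_list(graph: nx.DiGraph, path: str | Path) -> None:
    """Directed edge list TSV with the per-edge orientation provenance."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\torientation_source\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('orientation_source', 'score')}\n")


def read_edge_list(path: str | Path) -> nx.DiGraph:
    graph = nx.DiGraph()
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        graph.add_edge(row.source, row.target,
                       orientation_source=getattr(row, "orientation_source", "score"))
    return graph


def write_tom(tom: pd.DataFrame, path: str | Path,
              min_value: float = 1e-4) -> None:
    """Upper-triangle TOM in MatrixMarket coordinate format plus a JSON
    sidecar recording the gene order (entries below ``min_value`` and the
    unit diagonal are implicit)."""
    from scipy import io as spio, sparse

    values = np.triu(tom.to_numpy(dtype=float), k=1)
    values[values < min_value] = 0.0
    spio.mmwrite(str(path), sparse.coo_matrix(values))
    write_json({"genes": list(tom.index), "min_value": min_value},
               str(path) + ".json")


def read_tom(path: str | Path) -> pd.DataFrame:
    from scipy import io as spio

    meta = read_json(str(path) + ".json")
    dense = np.asarray(spio.mmread(str(path)).todense())
    dense = dense + dense.T
    np.fill_diagonal(dense, 1.0)
    return pd.DataFrame(dense, index=meta["genes"], columns=meta["genes"])


# ---------------------------------------------------------------- gene sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(set(gene_sets[name])))
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                gene_sets[parts[0]] = set(g for g in parts[2:] if g)
    return gene_sets


# ---------------------------------------------------------------- json


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
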