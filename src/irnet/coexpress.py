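"""Weighted co-expression networks: soft threshold, TOM, modules, enrichment.

The adjacency is unsigned, ``a_ij = |cor(i,j)|**power``, with the soft power
chosen by the scale-free topology criterion (smallest power whose signed
R^2 for the log-log connectivity-frequency regression reaches the cutoff,
with a plateau rule for near-misses). Topological overlap

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

drives average-linkage hierarchical clustering on 1 - TOM with a static
tree cut. Pairwise-correlation significance is assessed against a pooled
permutation null, and modules are selected by hypergeometric enrichment for
configured "relevant" gene sets (glucose/lipid/cholesterol/electron
transport and similar metabolic terms) at FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from ._rng import substream
from .de import bh_adjust
from .normalize import ResidualMatrix

__all__ = [
    "CoexpressionNetwork",
    "pick_soft_threshold",
    "adjacency_and_tom",
    "detect_modules",
    "permutation_background",
    "module_enrichment",
    "DEFAULT_RELEVANT_TERMS",
]

DEFAULT_RELEVANT_TERMS = (
    "GLUCOSE",
    "HEXOSE",
    "GLYCOLY",
    "LIPID",
    "CHOLESTEROL",
    "STEROL",
    "ELECTRON_TRANSPORT",
    "MITOCHOND",
    "INSULIN",
)

DEFAULT_POWERS = tuple(np.arange(1.0, 12.5, 0.5))


@dataclass
class CoexpressionNetwork:
    """One group-specific weighted co-expression network."""

    group: str
    stream: str
    power: float
    tom: pd.DataFrame
    module_assignment: pd.Series  # gene -> int label, 0 = unassigned
    selected_modules: set[int] = field(default_factory=set)
    enrichment_table: pd.DataFrame | None = None

    def module_genes(self, modules: Sequence[int] | None = None) -> list[str]:
        modules = set(self.selected_modules if modules is None else modules)
        mask = self.module_assignment.isin(modules)
        return self.module_assignment.index[mask].tolist()


def _abs_correlation(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant gene(s): correlation set to 0")
    safe = np.where(sd == 0, 1.0, sd)
    centered = (values - values.mean(axis=1, keepdims=True)) / safe[:, None]
    cor = centered @ centered.T / values.shape[1]
    cor[sd == 0, :] = 0.0
    cor[:, sd == 0] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.abs(np.clip(cor, -1.0, 1.0))


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) on log10(mean connectivity) over equal-width
    connectivity bins (negated when the slope is positive)."""
    k = connectivity[connectivity > 0]
    if k.size < 4 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    residuals: ResidualMatrix | pd.DataFrame,
    candidate_powers: Sequence[float] = DEFAULT_POWERS,
    r2_cutoff: float = 0.8,
    plateau_r2: float = 0.78,
    plateau_gain: float = 0.01,
) -> float:
    """Smallest candidate power reaching the scale-free fit cutoff.

    A lower power is accepted when its R^2 is already >= ``plateau_r2`` and
    the next candidate improves R^2 by less than ``plateau_gain`` (a curve
    plateau). If no candidate reaches R^2 >= 0.5 a warning is issued and the
    argmax is returned.
    """
    values = (residuals.values if isinstance(residuals, ResidualMatrix)
              else residuals).to_numpy(dtype=float)
    if values.shape[0] < 20:
        raise ValueError("need >= 20 genes to assess scale-free fit")
    powers = list(candidate_powers)
    if len(powers) == 1:
        return float(powers[0])
    acor = _abs_correlation(values)
    r2s = []
    for p in powers:
        adj = acor**p
        np.fill_diagonal(adj, 0.0)
        r2s.append(_scale_free_r2(adj.sum(axis=1)))
    r2s = np.asarray(r2s)
    for i, p in enumerate(powers):
        if r2s[i] >= r2_cutoff:
            return float(p)
        if (
            r2s[i] >= plateau_r2
            and i + 1 < len(powers)
            and r2s[i + 1] - r2s[i] < plateau_gain
        ):
            return float(p)
    if r2s.max() < 0.5:
        warnings.warn("no candidate power reaches scale-free R^2 of 0.5")
    return float(powers[int(np.argmax(r2s))])


def adjacency_and_tom(
    residuals: ResidualMatrix | pd.DataFrame, power: float
) -> pd.DataFrame:
    """Topological overlap matrix of the unsigned adjacency at ``power``."""
    if power < 1:
        raise ValueError("power must be >= 1")
    df = residuals.values if isinstance(residuals, ResidualMatrix) else residuals
    adj = _abs_correlation(df.to_numpy(dtype=float)) ** power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    denom = np.minimum.outer(k, k) + 1.0 - adj
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + adj) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=df.index, columns=df.index)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static tree cut.

    When ``cut_height`` is not given, candidate cuts between consecutive
    merge heights are scanned and the highest cut maximizing the number of
    clusters of size >= ``min_module_size`` is chosen (an adaptive static
    cut: too low fragments modules, too high absorbs them into the
    background; among equally good levels the highest keeps straggler
    members attached). A module larger than twice ``min_module_size`` can
    in principle be split by this objective; pass an explicit
    ``cut_height`` to override. Clusters smaller than ``min_module_size``
    get label 0; remaining labels are ordered by decreasing module size.
    """
    genes = tom.index
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        heights = np.unique(link[:, 2])
        mids = (heights[:-1] + heights[1:]) / 2.0
        if len(mids) > 200:  # cap the scan on large trees
            mids = mids[np.linspace(0, len(mids) - 1, 200).astype(int)]
        best_count, cut_height = -1, float(heights[-1] + 1.0)
        for cand in mids:
            labels = hierarchy.fcluster(link, t=cand, criterion="distance")
            sizes = np.bincount(labels)
            count = int((sizes >= min_module_size).sum())
            if count >= best_count:  # ascending scan: keeps the highest cut
                best_count, cut_height = count, float(cand)
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    ordered = sorted(keep, key=lambda lab: (-sizes[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(ordered)}
    return labels.map(lambda lab: remap.get(lab, 0)).astype(int)


def permutation_background(
    residuals: ResidualMatrix | pd.DataFrame,
    module_assignment: pd.Series,
    n_perm: int = 10,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Permutation p-values for within-module gene-pair correlations.

    Each permutation shuffles every gene row independently over samples,
    destroying all inter-gene correlation while preserving marginals; the
    pooled permuted |correlations| within each module form its null, and the
    p-value of an observed pair is ``(1 + #{null >= obs}) / (1 + #null)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    df = residuals.values if isinstance(residuals, ResidualMatrix) else residuals
    rng = substream(seed, "perm_background")
    out: dict[int, pd.DataFrame] = {}
    for label in sorted(set(module_assignment) - {0}):
        genes = module_assignment.index[module_assignment == label]
        if len(genes) < 2:
            continue
        values = df.loc[genes].to_numpy(dtype=float)
        n_genes, n_samples = values.shape
        iu = np.triu_indices(n_genes, k=1)
        obs_cor = np.corrcoef(values)[iu]
        null: list[np.ndarray] = []
        for _ in range(n_perm):
            perm = values.copy()
            for row in perm:
                rng.shuffle(row)
            null.append(np.abs(np.corrcoef(perm)[iu]))
        pooled = np.sort(np.concatenate(null))
        obs_abs = np.abs(obs_cor)
        n_ge = pooled.size - np.searchsorted(pooled, obs_abs, side="left")
        pvals = (1.0 + n_ge) / (1.0 + pooled.size)
        out[label] = pd.DataFrame(
            {
                "gene_i": np.asarray(genes)[iu[0]],
                "gene_j": np.asarray(genes)[iu[1]],
                "cor": obs_cor,
                "p": pvals,
            }
        )
    return out


def module_enrichment(
    module_assignment: pd.Series,
    gene_sets: Mapping[str, set[str]],
    universe: Sequence[str] | None = None,
    relevant_terms: Sequence[str] = DEFAULT_RELEVANT_TERMS,
    fdr_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, set[int]]:
    """Hypergeometric module x gene-set enrichment and module selection.

    The universe defaults to all analyzed genes (the assignment's index).
    A module is selected when any gene set whose name contains a configured
    relevant term passes BH FDR < ``fdr_cutoff``.
    """
    universe = set(universe if universe is not None else module_assignment.index)
    n_univ = len(universe)
    rows = []
    for label in sorted(set(module_assignment) - {0}):
        members = set(module_assignment.index[module_assignment == label]) & universe
        for name, genes in sorted(gene_sets.items()):
            in_univ = set(genes) & universe
            if not in_univ:
                warnings.warn(f"gene set {name!r} has no overlap with the universe")
                continue
            overlap = len(members & in_univ)
            p = float(hypergeom.sf(overlap - 1, n_univ, len(in_univ), len(members)))
            rows.append((label, name, overlap, len(in_univ), len(members), p))
    table = pd.DataFrame(
        rows, columns=["module", "gene_set", "overlap", "set_size", "module_size", "p"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    else:
        table["fdr"] = []
    upper = [t.upper() for t in relevant_terms]
    relevant = table["gene_set"].str.upper().map(
        lambda s: any(term in s for term in upper)
    ) if len(table) else pd.Series(dtype=bool)
    selected = set(
        table.loc[relevant & (table["fdr"] < fdr_cutoff), "module"].astype(int)
    ) if len(table) else set()
    return table, selected
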