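"""Differential expression on covariate-adjusted residuals.

Implements a two-group (IR vs IS) per-gene linear model with empirical-Bayes
moderated variances: gene-wise sample variances are shrunk toward a common
prior fitted by the standard inverse-gamma (scaled F) scheme, the residual
degrees of freedom are augmented by the estimated prior df, and p-values come
from the t distribution on the augmented df. A paired mode (one-sample
moderated t on within-pair differences) supports treated-vs-control designs
paired by cell line.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .normalize import ResidualMatrix

__all__ = ["fit_de", "bh_adjust", "compare_rankings", "squeeze_var"]


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / np.maximum(y, 1e-12)) < 1e-8:
            break
    return y


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene variances.

    Fits a scaled inverse-chi-square prior (df0, s0^2) to the observed
    variances by matching moments of log(s2), then returns the posterior
    variances ``(df0*s0^2 + df*s2) / (df0 + df)`` together with the prior
    df and prior variance. ``df0`` is ``inf`` when the observed spread of
    log-variances is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0, float(np.median(s2[ok])) if ok.any() else 0.0
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    expected = special.polygamma(1, df / 2)
    excess = e_var - expected
    if excess <= 0:
        df0 = np.inf
        s02 = float(np.exp(e_mean))
        post = np.full_like(s2, s02)
        post[~ok] = s02
        return post, df0, s02
    df0 = float(2 * _trigamma_inverse(np.array([excess]))[0])
    s02 = float(np.exp(e_mean + special.digamma(df0 / 2) - np.log(df0 / 2)))
    post = (df0 * s02 + df * s2) / (df0 + df)
    post[~ok] = s02 * df0 / (df0 + df) if df0 > 0 else 0.0
    return post, df0, s02


def _rank_first(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def fit_de(
    residuals: ResidualMatrix | pd.DataFrame,
    groups: pd.Series | Sequence[str],
    contrast: tuple[str, str] = ("IR", "IS"),
    moderate: bool = True,
    paired: pd.Series | Sequence | None = None,
) -> pd.DataFrame:
    """Per-gene two-group differential expression on residuals.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (first minus
    second contrast label), ``t``, ``p``, ``fdr`` and ``rank`` (by p-value,
    ties broken by gene order). With ``moderate`` on, variances are shrunk by
    :func:`squeeze_var`. With ``paired`` given (unit -> pair label), a
    one-sample moderated t is applied to within-pair differences.
    """
    values = residuals.values if isinstance(residuals, ResidualMatrix) else residuals
    groups = pd.Series(np.asarray(groups, dtype=object), index=values.columns) \
        if not isinstance(groups, pd.Series) else groups.reindex(values.columns)
    g1, g2 = contrast
    m1 = (groups == g1).to_numpy()
    m2 = (groups == g2).to_numpy()
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError(f"both contrast groups must be non-empty: {contrast}")
    y = values.to_numpy(dtype=float)

    if paired is not None:
        pairs = pd.Series(np.asarray(paired, dtype=object), index=values.columns) \
            if not isinstance(paired, pd.Series) else paired.reindex(values.columns)
        diffs = []
        for pair in pd.unique(pairs):
            sel = pairs == pair
            a = y[:, (sel & pd.Series(m1, index=values.columns)).to_numpy()]
            b = y[:, (sel & pd.Series(m2, index=values.columns)).to_numpy()]
            if a.shape[1] != 1 or b.shape[1] != 1:
                raise ValueError(f"pair {pair!r} must have one unit per group")
            diffs.append(a[:, 0] - b[:, 0])
        d = np.column_stack(diffs)
        n = d.shape[1]
        if n < 2:
            raise ValueError("paired design needs >= 2 pairs")
        fc = d.mean(axis=1)
        s2 = d.var(axis=1, ddof=1)
        df = n - 1
        stderr_unit = 1.0 / np.sqrt(n)
    else:
        n1, n2 = int(m1.sum()), int(m2.sum())
        if (n1 < 2 or n2 < 2) and not moderate:
            raise ValueError("group of size 1 requires moderation")
        mu1 = y[:, m1].mean(axis=1)
        mu2 = y[:, m2].mean(axis=1)
        fc = mu1 - mu2
        ss1 = ((y[:, m1] - mu1[:, None]) ** 2).sum(axis=1)
        ss2 = ((y[:, m2] - mu2[:, None]) ** 2).sum(axis=1)
        df = n1 + n2 - 2
        s2 = (ss1 + ss2) / df
        stderr_unit = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderate:
        s2_post, df0, _s02 = squeeze_var(s2, df)
        df_total = df + df0 if np.isfinite(df0) else np.inf
    else:
        s2_post, df_total = s2, df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (np.sqrt(s2_post) * stderr_unit)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isfinite(df_total):
        p = 2 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {"log2fc": fc, "t": t, "p": p, "fdr": fdr, "rank": _rank_first(p)},
        index=values.index,
    )
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties equal)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_genes(de: pd.DataFrame, fdr: float = 0.05,
                      top_n_fallback: int | None = None) -> list[str]:
    """Genes at FDR < cutoff; optionally fall back to the top N by p-value
    when nothing passes (the ApP convention)."""
    hits = de.index[de["fdr"] < fdr].tolist()
    if not hits and top_n_fallback:
        hits = de.sort_values("rank").head(top_n_fallback).index.tolist()
    return hits


def compare_rankings(
    de_a: pd.DataFrame, de_b: pd.DataFrame, top_n: int = 500
) -> tuple[float, float, pd.DataFrame]:
    """Rank concordance of two DE analyses over the union of their top genes.

    Takes the union of each result's ``top_n`` smallest-p genes, and reports
    the Spearman correlation of the (full-result) ranks plus a paired
    Wilcoxon signed-rank test of the rank differences.
    """
    common = de_a.index.intersection(de_b.index)
    if len(common) < len(de_a) or len(common) < len(de_b):
        de_a, de_b = de_a.loc[common], de_b.loc[common]
    if top_n > len(common):
        raise ValueError("top_n exceeds the shared gene universe")
    top = set(de_a.sort_values("rank").head(top_n).index) | set(
        de_b.sort_values("rank").head(top_n).index
    )
    genes = [g for g in common if g in top]
    ra = de_a.loc[genes, "rank"].to_numpy(dtype=float)
    rb = de_b.loc[genes, "rank"].to_numpy(dtype=float)
    rho = float(stats.spearmanr(ra, rb).statistic)
    diffs = ra - rb
    if np.allclose(diffs, 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(ra, rb, zero_method="wilcox").pvalue)
    table = pd.DataFrame({"rank_a": ra, "rank_b": rb}, index=genes)
    return rho, wilcoxon_p, table
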