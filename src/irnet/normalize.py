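"""Expression filtering, normalization and covariate residualization.

The pipeline keeps genes with >= 1 CPM in >= 30% of samples, computes
trimmed-mean-of-M-values (TMM) scale factors, transforms to log2-CPM and
then removes technical and biological covariates per gene:

* fixed effects (reprogramming source cell, sex, ethnicity, age, BMI) by
  ordinary least squares,
* random effects (sequencing batch, RNA kit) as ridge-shrunken level
  effects whose single shared penalty is profiled per gene by REML on a
  grid, solved through Henderson's mixed-model equations so that the
  residuals are exactly orthogonal to the fixed-effect design.

Residuals are produced at sample level (AS, all samples) and can be
averaged per donor (ApP, average-per-patient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ResidualMatrix",
    "classify_insulin_status",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "adjust_covariates",
    "average_per_patient",
    "DEFAULT_FIXED_COVARIATES",
    "DEFAULT_RANDOM_COVARIATES",
]

DEFAULT_FIXED_COVARIATES = ("source_cell", "sex", "ethnicity", "age", "bmi")
DEFAULT_RANDOM_COVARIATES = ("batch", "rna_kit")

SSPG_CUTOFF = 140.0  # mg/dl


@dataclass
class ResidualMatrix:
    """Covariate-adjusted log2-CPM residuals.

    ``unit_kind`` is ``"sample"`` for the all-samples (AS) stream or
    ``"donor"`` for the average-per-patient (ApP) stream.
    """

    values: pd.DataFrame  # genes x units
    unit_kind: str = "sample"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def unit_ids(self) -> pd.Index:
        return self.values.columns

    def subset_units(self, units: Sequence[str]) -> "ResidualMatrix":
        return ResidualMatrix(self.values[list(units)], self.unit_kind)


def classify_insulin_status(sspg, cutoff: float = SSPG_CUTOFF):
    """IR/IS call from steady-state plasma glucose (mg/dl).

    SSPG at or above the cutoff is called insulin resistant; the boundary
    value itself is assigned to IR (the resistant class is closed).
    """
    arr = np.asarray(sspg, dtype=float)
    if np.any(arr < 0):
        raise ValueError("SSPG must be non-negative")
    out = np.where(arr >= cutoff, "IR", "IS")
    if np.isscalar(sspg) or arr.ndim == 0:
        return str(out.item() if arr.ndim == 0 else out[0])
    return out


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_frac: float = 0.30
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in >= ceil(min_frac * n) samples."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    cpm = counts.div(lib, axis=1) * 1e6
    need = int(np.ceil(min_frac * counts.shape[1]))
    keep = (cpm >= min_cpm).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("no genes pass the low-expression filter")
    return counts.loc[keep]


def _ref_column(counts: np.ndarray, lib: np.ndarray) -> int:
    # sample whose 75th expression quantile (relative to library size) is
    # closest to the mean across samples
    q75 = np.quantile(counts / lib[None, :], 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(counts: pd.DataFrame, ref_column: str | None = None) -> pd.Series:
    """Trimmed mean of M-values scale factors (Robinson & Oshlack).

    M-values (log2 expression ratios vs the reference sample) are doubly
    trimmed -- 30% on M, 5% on A (average abundance) -- and averaged with
    inverse asymptotic-variance weights. Factors are normalized so their
    product is 1.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero total counts")
    if ref_column is None:
        ref = _ref_column(x, lib)
    else:
        ref = counts.columns.get_loc(ref_column)
    yr, nr = x[:, ref], lib[ref]
    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        yj, nj = x[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            continue
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_m = np.floor(n * 0.30) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            continue
        log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0 ** (log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-scaled effective library sizes:
    ``log2((count + prior) / (lib * factor + 2 * prior) * 1e6)``."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    return np.log2(
        (counts + prior_count).div(lib + 2 * prior_count, axis=1) * 1e6
    )


# --------------------------------------------------------------------------
# covariate residualization
# --------------------------------------------------------------------------


def _is_continuous(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and series.nunique() > 8


def _fixed_design(metadata: pd.DataFrame, fixed: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(metadata))]
    for cov in fixed:
        s = metadata[cov]
        if _is_continuous(s):
            v = s.to_numpy(dtype=float)
            sd = v.std()
            cols.append((v - v.mean()) / (sd if sd > 0 else 1.0))
        else:
            levels = sorted(map(str, s.unique()))
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {cov!r} has < 2 levels")
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def _random_design(metadata: pd.DataFrame, random: Sequence[str]) -> np.ndarray:
    cols = []
    for cov in random:
        s = metadata[cov].astype(str)
        levels = sorted(s.unique())
        if len(levels) < 2:
            raise ValueError(f"random-effect covariate {cov!r} has < 2 levels")
        for lev in levels:
            cols.append((s == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def _warn_confounded(metadata: pd.DataFrame, covs: Sequence[str]) -> None:
    cats = [c for c in covs if not _is_continuous(metadata[c])]
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            tab = pd.crosstab(metadata[a].astype(str), metadata[b].astype(str))
            if ((tab > 0).sum(axis=1) == 1).all() and tab.shape[0] > 1:
                warnings.warn(
                    f"covariates {a!r} and {b!r} are confounded "
                    f"({a!r} constant within levels of {b!r})"
                )


def adjust_covariates(
    logcpm: pd.DataFrame,
    metadata: pd.DataFrame,
    fixed: Sequence[str] = DEFAULT_FIXED_COVARIATES,
    random: Sequence[str] = DEFAULT_RANDOM_COVARIATES,
) -> ResidualMatrix:
    """Per-gene covariate-adjusted residuals (AS stream).

    Fixed-effect terms enter an OLS design; random-effect terms get
    ridge-shrunken level effects with a per-gene REML-profiled penalty
    (partial pooling, a light-weight stand-in for a full mixed model).
    Residuals have mean 0 per gene and are exactly orthogonal to the
    fixed-effect design columns.
    """
    meta = metadata.set_index("sample_id").loc[logcpm.columns] \
        if "sample_id" in metadata.columns else metadata.loc[logcpm.columns]
    fixed = [c for c in fixed if c in meta.columns]
    random = [c for c in random if c in meta.columns]
    missing = [c for c in list(fixed) + list(random) if c not in meta.columns]
    if missing:
        raise ValueError(f"covariates missing from metadata: {missing}")
    _warn_confounded(meta, list(fixed) + list(random))

    y = logcpm.to_numpy(dtype=float)  # genes x samples
    n = y.shape[1]
    x = _fixed_design(meta, fixed)
    xtx_inv = np.linalg.pinv(x.T @ x)
    hat = x @ xtx_inv @ x.T
    m_proj = np.eye(n) - hat  # annihilator of the fixed design

    if not random:
        resid = y @ m_proj.T
        return ResidualMatrix(
            pd.DataFrame(resid, index=logcpm.index, columns=logcpm.columns),
            unit_kind="sample",
        )

    z = _random_design(meta, random)
    zs = m_proj @ z
    u_svd, s_svd, vt_svd = np.linalg.svd(zs, full_matrices=False)
    s2 = s_svd**2
    rank_x = int(np.linalg.matrix_rank(x))
    n_free = n - rank_x

    ys = y @ m_proj.T  # residualized responses, genes x n
    a = ys @ u_svd  # genes x q, coordinates along the random-effect directions
    total = np.sum(ys**2, axis=1)
    rest = total - np.sum(a**2, axis=1)

    # profile REML criterion for lambda = sigma_u^2 / sigma_e^2 on a grid
    grid = np.exp(np.linspace(-8.0, 8.0, 81))
    d = 1.0 + grid[:, None] * s2[None, :]  # grid x q
    quad = (a**2)[:, None, :] / d[None, :, :]  # genes x grid x q
    sigma2 = (quad.sum(axis=2) + rest[:, None]) / max(n_free, 1)
    sigma2 = np.maximum(sigma2, 1e-300)
    crit = n_free * np.log(sigma2) + np.log(d).sum(axis=1)[None, :]
    best = np.argmin(crit, axis=1)
    lam = grid[best]  # per-gene variance ratio

    # Henderson solution: u = (Zs'Zs + I/lambda)^-1 Zs' ys, then refit fixed
    shrink = s_svd[None, :] / (s2[None, :] + 1.0 / lam[:, None])  # genes x q
    u_hat = (a * shrink) @ vt_svd  # genes x q_z
    fitted_random = u_hat @ z.T
    y_minus = y - fitted_random
    beta = y_minus @ x @ xtx_inv  # genes x k
    resid = y_minus - beta @ x.T
    return ResidualMatrix(
        pd.DataFrame(resid, index=logcpm.index, columns=logcpm.columns),
        unit_kind="sample",
    )


def average_per_patient(
    residuals: ResidualMatrix, donor_map: Mapping[str, str] | pd.Series
) -> ResidualMatrix:
    """ApP stream: average each donor's clone columns.

    ``donor_map`` maps sample id -> donor id and must cover every column.
    """
    if residuals.unit_kind != "sample":
        raise ValueError("expected sample-level (AS) residuals")
    donor_map = pd.Series(dict(donor_map)) if not isinstance(donor_map, pd.Series) \
        else donor_map
    missing = [s for s in residuals.unit_ids if s not in donor_map.index]
    if missing:
        raise ValueError(f"samples without donor mapping: {missing[:5]}")
    donors = donor_map.loc[residuals.unit_ids]
    if (donor_map.value_counts() == 0).any():  # pragma: no cover - defensive
        raise ValueError("donor with zero samples")
    averaged = residuals.values.T.groupby(donors.values).mean().T
    averaged = averaged[sorted(averaged.columns)]
    return ResidualMatrix(averaged, unit_kind="donor")
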