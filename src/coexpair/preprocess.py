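"""Expression normalization and covariate residualization.

The network stages assume expression on a "residualized log2" scale:
quantile-normalized across samples, log2 transformed, then per-gene
least-squares residuals after regressing out technical and biological
covariates (sex, age, batch indicators, ancestry PCs, ...).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy.stats import rankdata


def quantile_normalize(m: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Force every sample column onto the across-sample mean quantile vector.

    Ties within a column receive the mean of the quantile values they span
    (mean-rank convention). With ``groups`` (sample -> batch label) the
    normalization is applied separately within each batch.

    Parameters
    ----------
    m : genes x samples matrix without missing values.
    groups : optional per-sample grouping for within-batch normalization.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if m.isna().any().any():
        raise ValueError("missing values in expression matrix")
    if groups is not None:
        groups = groups.reindex(m.columns)
        parts = [quantile_normalize(m.loc[:, groups == g]) for g in groups.unique()]
        return pd.concat(parts, axis=1)[m.columns]

    x = m.to_numpy(float)
    order = np.sort(x, axis=0)
    mean_quantiles = order.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1-based, ties -> mean rank
        # fractional ranks interpolate between adjacent mean quantiles
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), mean_quantiles)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def log2_transform(m: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise log2(x + offset); variance stabilization for RPKM-like data."""
    x = m.to_numpy(float) + offset
    if (x <= 0).any():
        i, j = np.argwhere(x <= 0)[0]
        raise ValueError(
            f"non-positive value for gene {m.index[i]!r}, sample {m.columns[j]!r} "
            f"(value + offset = {x[i, j]})"
        )
    return pd.DataFrame(np.log2(x), index=m.index, columns=m.columns)


def encode_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical columns (first level dropped); pass numerics."""
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    parts = []
    for c in cov.columns:
        col = cov[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True).astype(float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def residualize(m: pd.DataFrame, cov: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene OLS residuals on intercept + covariates.

    With no covariates this centers every gene. The design (with intercept)
    must be full column rank; collinear columns are reported by name.
    """
    x = m.to_numpy(float)
    n = x.shape[1]
    if cov is None or cov.shape[1] == 0:
        res = x - x.mean(axis=1, keepdims=True)
        return pd.DataFrame(res, index=m.index, columns=m.columns)

    cov = encode_covariates(cov.reindex(m.columns))
    design = np.column_stack([np.ones(n), cov.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = ["(intercept)"] + list(cov.columns)
        collinear = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    # residual-maker applied to all genes at once: R = X - X P,  P = D (D'D)^-1 D'
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    res = x - (design @ coef).T
    return pd.DataFrame(res, index=m.index, columns=m.columns)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    keep: list[int] = []
    bad: list[str] = []
    for j in range(design.shape[1]):
        cols = keep + [j]
        if np.linalg.matrix_rank(design[:, cols]) == len(cols):
            keep.append(j)
        else:
            bad.append(names[j])
    return bad
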