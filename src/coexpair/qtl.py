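"""Eigengene QTL scanning.

Each SNP is tested by ordinary least squares of the module eigengene on
additive dosage (0/1/2) plus covariates — by default the first genotype
principal components, to control for population substructure. An interaction
scan adds status and dosage x status terms and reports the interaction
coefficient (the difference between the case and control slopes). P-values
are summarized by Benjamini–Hochberg q-values and the genomic inflation
factor λ (median Wald χ² over the null median 0.4549364).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

CHI2_1_MEDIAN = 0.4549364231195728  # median of the 1-df chi-square


@dataclass
class QTLScanResult:
    table: pd.DataFrame  # per passing SNP: beta, se, t, p, q (+ extras)
    excluded: pd.DataFrame  # snp, reason
    lambda_gc: float
    covariates: list


def genotype_pcs(g: pd.DataFrame, n_pcs: int = 5) -> pd.DataFrame:
    """Principal components of the column-standardized dosage matrix.

    Missing dosages are mean-imputed for the PC computation only. Returns a
    samples x n_pcs score matrix.
    """
    if n_pcs == 0:
        return pd.DataFrame(index=g.index)
    x = g.to_numpy(float).copy()
    mu = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu, inds[1])
    sd = x.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all SNPs monomorphic: no principal components")
    xs = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]
    if min(xs.shape) <= n_pcs:
        raise ValueError(f"need more than {n_pcs} samples and SNPs for {n_pcs} PCs")
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(scores, index=g.index, columns=[f"PC{i+1}" for i in range(n_pcs)])


def snp_qc(g: pd.DataFrame, maf_min: float = 0.01, callrate_min: float = 0.95):
    """Split SNPs into passing columns and an exclusion table with reasons."""
    x = g.to_numpy(float)
    callrate = 1.0 - np.isnan(x).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    reasons = []
    for j, snp in enumerate(g.columns):
        if callrate[j] < callrate_min:
            reasons.append((snp, "callrate"))
        elif not np.isfinite(maf[j]) or maf[j] < maf_min:
            reasons.append((snp, "maf"))
    excluded = pd.DataFrame(reasons, columns=["snp", "reason"])
    passing = [c for c in g.columns if c not in set(excluded.snp)]
    return passing, excluded


def qtl_scan(
    me: pd.Series,
    g: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
) -> QTLScanResult:
    """Per-SNP additive linear model ME ~ dosage + covariates.

    Missing genotypes drop samples for that SNP only. Returns Wald beta, se,
    t-test p per passing SNP, BH q-values and λ over the scan.
    """
    me, g, cov = _align(me, g, covars)
    passing, excluded = snp_qc(g, maf_min, callrate_min)
    y = me.to_numpy(float)
    rows = []
    for snp in passing:
        dose = g[snp].to_numpy(float)
        ok = ~np.isnan(dose)
        design = np.column_stack([np.ones(ok.sum()), dose[ok]] +
                                 ([cov[ok]] if cov is not None else []))
        beta, se, t, p = _ols_term(design, y[ok], term=1)
        rows.append(dict(snp=snp, n=int(ok.sum()), beta=beta, se=se, t=t, p=p))
    table = pd.DataFrame(rows, columns=["snp", "n", "beta", "se", "t", "p"])
    return _finish(table, excluded, cov)


def interaction_scan(
    me: pd.Series,
    g: pd.DataFrame,
    status: pd.Series,
    covars: pd.DataFrame | None = None,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
    min_group_n: int = 10,
) -> QTLScanResult:
    """Per-SNP model ME ~ dosage + status + dosage x status (+ covariates).

    The reported term is the interaction; per-group (case/control) slopes are
    also emitted. SNPs with fewer than ``min_group_n`` genotyped samples in
    either class are flagged, not tested.
    """
    me, g, cov = _align(me, g, covars)
    st = pd.Series(status).reindex(me.index).astype(float)
    if set(st.unique()) != {0.0, 1.0}:
        raise ValueError("status must contain both classes 0 and 1")
    passing, excluded = snp_qc(g, maf_min, callrate_min)
    y = me.to_numpy(float)
    sv = st.to_numpy(float)
    rows, flagged = [], []
    for snp in passing:
        dose = g[snp].to_numpy(float)
        ok = ~np.isnan(dose)
        if min((sv[ok] == 1).sum(), (sv[ok] == 0).sum()) < min_group_n:
            flagged.append((snp, "group_n"))
            continue
        d, s_ = dose[ok], sv[ok]
        design = np.column_stack([np.ones(ok.sum()), d, s_, d * s_] +
                                 ([cov[ok]] if cov is not None else []))
        beta, se, t, p = _ols_term(design, y[ok], term=3)
        slope_case = _group_slope(d[s_ == 1], y[ok][s_ == 1],
                                  cov[ok][s_ == 1] if cov is not None else None)
        slope_ctrl = _group_slope(d[s_ == 0], y[ok][s_ == 0],
                                  cov[ok][s_ == 0] if cov is not None else None)
        rows.append(dict(snp=snp, n=int(ok.sum()), beta=beta, se=se, t=t, p=p,
                         slope_cases=slope_case, slope_controls=slope_ctrl))
    table = pd.DataFrame(rows, columns=["snp", "n", "beta", "se", "t", "p",
                                        "slope_cases", "slope_controls"])
    excluded = pd.concat(
        [excluded, pd.DataFrame(flagged, columns=["snp", "reason"])], ignore_index=True
    )
    return _finish(table, excluded, cov)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def genomic_lambda(p=None, chi2=None) -> float:
    """Genomic inflation factor: median 1-df χ² over 0.4549364."""
    if chi2 is None:
        if p is None:
            raise ValueError("provide p or chi2")
        p = np.asarray(p, float)
        if p.size == 0:
            raise ValueError("empty input")
        chi2 = stats.chi2.isf(p, df=1)
    chi2 = np.asarray(chi2, float)
    if chi2.size == 0:
        raise ValueError("empty input")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def _align(me, g, covars):
    me = pd.Series(me)
    missing = me.index.difference(g.index)
    if len(missing):
        raise ValueError(f"samples missing from the genotype matrix: {list(missing[:5])}")
    g = g.reindex(me.index)
    cov = None
    covnames: list = []
    if covars is not None and covars.shape[1] > 0:
        covars = covars.reindex(me.index)
        if covars.isna().any().any():
            raise ValueError("missing covariate values")
        cov = covars.to_numpy(float)
    return me, g, cov


def _ols_term(design: np.ndarray, y: np.ndarray, term: int):
    n, k = design.shape
    if n <= k:
        return (np.nan,) * 4
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n - k
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[term, term])
    t = coef[term] / se if se > 0 else np.nan
    p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
    return float(coef[term]), float(se), float(t), float(p)


def _group_slope(d, y, cov):
    design = np.column_stack([np.ones(d.size), d] + ([cov] if cov is not None else []))
    beta, *_ = _ols_term(design, y, term=1)
    return beta


def _finish(table: pd.DataFrame, excluded: pd.DataFrame, cov) -> QTLScanResult:
    if len(table):
        table = table.copy()
        table["q"] = bh_fdr(table.p.to_numpy())
        lam = genomic_lambda(chi2=table.t.to_numpy() ** 2)
    else:
        lam = float("nan")
    ncov = 0 if cov is None else cov.shape[1]
    return QTLScanResult(
        table=table.set_index("snp") if len(table) else table,
        excluded=excluded,
        lambda_gc=lam,
        covariates=[f"cov{i+1}" for i in range(ncov)],
    )
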