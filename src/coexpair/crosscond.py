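"""Cross-condition comparison of modules on shared samples.

Covers: hypergeometric overlap of the two conditions' module memberships,
best-overlap module matching, logistic regression of case/control status on
module eigengenes, fixed-membership eigengene recomputation in the second
condition, and model comparison via ΔAIC and a two-coefficient Z-test.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.special import logsumexp
from scipy.stats import hypergeom, norm

from .modules import GREY, module_eigengene, module_sizes

MIN_LOG10 = math.log10(5e-324)  # anything smaller underflows float64 entirely


def hypergeom_tail_log10(N: int, K: int, n: int, x: int, strict: bool = False) -> float:
    """log10 of the hypergeometric upper tail, accurate far below 1e-300.

    ``strict=False`` gives P(X >= x); ``strict=True`` gives P(X > x), the
    convention some overlap-table tools print. Computed by log-space summation
    of the pmf so values down to ~1e-320 and their logs remain meaningful.
    """
    _check_counts(N, K, n, x)
    lo = x + 1 if strict else x
    hi = min(K, n)
    if lo > hi:
        return -math.inf
    if lo <= max(0, K + n - N):
        return 0.0
    support = np.arange(lo, hi + 1)
    logs = hypergeom.logpmf(support, N, K, n)
    return float(logsumexp(logs) / math.log(10))


def hypergeom_tail(N: int, K: int, n: int, x: int, strict: bool = False) -> float:
    """Hypergeometric tail probability as a float (0.0 once below ~1e-320)."""
    l10 = hypergeom_tail_log10(N, K, n, x, strict=strict)
    if l10 == -math.inf:
        return 0.0
    return 10.0**l10


def format_p(p: float, log10_p: float) -> str:
    if log10_p < MIN_LOG10:
        return "< 1e-308"
    return f"{p:.3g}" if p > 0 else f"1e{log10_p:.1f}"


def _check_counts(N, K, n, x):
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"x={x} outside [0, min(K, n)={min(K, n)}]")


def overlap_table(
    a: pd.Series, b: pd.Series, universe=None, strict_tail: bool = True
) -> pd.DataFrame:
    """Cross-tabulate non-grey modules of two assignments on one universe.

    Per (module_a, module_b) pair: sizes, shared count, percent of the B
    module shared, and the hypergeometric overlap P. The strict-tail
    convention P(X > shared) matches the R overlap-table output the original
    analyses printed; pass ``strict_tail=False`` for the inclusive tail.
    """
    if universe is None:
        universe = a.index
        if set(a.index) != set(b.index):
            raise ValueError("assignments cover different gene universes")
    universe = pd.Index(universe)
    a = a.reindex(universe)
    b = b.reindex(universe)
    if a.isna().any() or b.isna().any():
        raise ValueError("assignments do not cover the universe")
    N = len(universe)
    rows = []
    for ma in module_sizes(a).index:
        set_a = set(universe[a == ma])
        for mb in module_sizes(b).index:
            set_b = set(universe[b == mb])
            shared = len(set_a & set_b)
            l10 = hypergeom_tail_log10(N, len(set_a), len(set_b), shared, strict=strict_tail)
            rows.append(
                dict(
                    module_a=ma,
                    module_b=mb,
                    size_a=len(set_a),
                    size_b=len(set_b),
                    shared=shared,
                    percent_of_b=100.0 * shared / len(set_b),
                    p=0.0 if l10 == -math.inf else 10.0**l10,
                    log10_p=l10,
                )
            )
    t = pd.DataFrame(
        rows,
        columns=["module_a", "module_b", "size_a", "size_b",
                 "shared", "percent_of_b", "p", "log10_p"],
    )
    t.attrs["universe_size"] = N
    return t


def match_modules(t: pd.DataFrame) -> dict:
    """Map each condition-B module to its best-overlap condition-A module.

    Maximum shared count wins; ties break by smaller P, then lexicographic
    A-label. B modules sharing nothing with any A module keep their label.
    """
    if t.empty:
        raise ValueError("empty overlap table")
    mapping = {}
    for mb, grp in t.groupby("module_b"):
        grp = grp.sort_values(
            ["shared", "log10_p", "module_a"], ascending=[False, True, True], kind="stable"
        )
        best = grp.iloc[0]
        mapping[mb] = best.module_a if best.shared > 0 else mb
    return mapping


@dataclass
class AssociationResult:
    """Logistic ME -> status fit for one module in one condition."""

    module: str
    condition: str
    beta: float
    se: float
    wald_p: float
    aic: float
    n_cases: int
    n_controls: int
    separation: bool = False


@dataclass
class AssociationComparison:
    """ΔAIC and coefficient Z-test between the two conditions' fits."""

    module: str
    delta_aic: float
    likelihood_ratio: float
    z: float
    one_sided_p: float
    available: bool = True


def logistic_association(
    me: pd.Series, status: pd.Series, module: str = "", condition: str = ""
) -> AssociationResult:
    """Maximum-likelihood logistic regression of status on intercept + ME."""
    import statsmodels.api as sm

    me = pd.Series(me)
    y = pd.Series(status).reindex(me.index).astype(float)
    if len(y) != len(me) or y.isna().any():
        raise ValueError("status and eigengene must align on the same samples")
    classes = set(y.unique())
    if classes != {0.0, 1.0}:
        raise ValueError(f"status must contain both classes 0 and 1, got {sorted(classes)}")
    X = sm.add_constant(me.to_numpy(float))
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    try:
        fit = sm.Logit(y.to_numpy(), X).fit(disp=False, maxiter=200)
        separated = not fit.mle_retvals.get("converged", True) or abs(fit.params[1]) > 50
    except Exception:
        separated = True
        fit = None
    if separated or fit is None:
        return AssociationResult(module, condition, math.inf, math.nan, math.nan,
                                 math.nan, n_cases, n_controls, separation=True)
    return AssociationResult(
        module=module,
        condition=condition,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        wald_p=float(fit.pvalues[1]),
        aic=float(2 * 2 - 2 * fit.llf),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def recompute_fixed_membership(
    m_b: pd.DataFrame, assign: pd.Series, include_grey: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes in condition-B data for condition-A module memberships.

    The grey (unassigned) set is included as its own column by default, so it
    can be association-tested alongside the real modules.
    """
    missing = [g for g in assign.index if g not in m_b.index]
    if missing:
        raise KeyError(f"genes absent from condition-B matrix: {missing[:10]}")
    mods = list(module_sizes(assign).index)
    if include_grey and (assign == GREY).any():
        mods.append(GREY)
    mes, ve = {}, {}
    for mod in mods:
        genes = assign.index[assign == mod]
        mes[mod], ve[mod] = module_eigengene(m_b, genes)
    return pd.DataFrame(mes, index=m_b.columns), pd.Series(ve, name="variance_explained")


def compare_conditions(res_a: AssociationResult, res_b: AssociationResult) -> AssociationComparison:
    """ΔAIC = AIC_B - AIC_A, likelihood ratio exp(-ΔAIC/2), and the
    independent-SE Z-test of the two coefficients (one-sided normal tail)."""
    if res_a.separation or res_b.separation:
        return AssociationComparison(res_a.module, math.nan, math.nan, math.nan,
                                     math.nan, available=False)
    delta = res_b.aic - res_a.aic
    z = abs(res_b.beta - res_a.beta) / math.sqrt(res_a.se**2 + res_b.se**2)
    return AssociationComparison(
        module=res_a.module,
        delta_aic=delta,
        likelihood_ratio=math.exp(-delta / 2.0),
        z=z,
        one_sided_p=float(norm.sf(z)),
    )


def association_table(
    me_a: pd.DataFrame, me_b: pd.DataFrame, status: pd.Series
) -> pd.DataFrame:
    """Per-module association in both conditions plus the comparison columns,
    mirroring the shape of a two-condition association report."""
    rows = []
    for mod in me_a.columns:
        ra = logistic_association(me_a[mod], status, module=mod, condition="A")
        rb = logistic_association(me_b[mod], status, module=mod, condition="B")
        cmp_ = compare_conditions(ra, rb)
        rows.append(
            dict(
                module=mod,
                beta_a=ra.beta, se_a=ra.se, p_a=ra.wald_p, aic_a=ra.aic,
                beta_b=rb.beta, se_b=rb.se, p_b=rb.wald_p, aic_b=rb.aic,
                delta_aic=cmp_.delta_aic, z=cmp_.z, one_sided_p=cmp_.one_sided_p,
            )
        )
    return pd.DataFrame(rows).set_index("module")


def subgroup_eigengene_test(
    m_a: pd.DataFrame,
    m_b: pd.DataFrame,
    genes,
    status: pd.Series,
    parent_genes=None,
):
    """Association change for a gene subset, plus its eigengene's correlation
    with the parent module's eigengene in each condition.

    Returns (AssociationComparison, dict of per-condition results and
    parent correlations).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty subset")
    me_a, _ = module_eigengene(m_a, genes)
    me_b, _ = module_eigengene(m_b, genes)
    ra = logistic_association(me_a, status, module="subset", condition="A")
    rb = logistic_association(me_b, status, module="subset", condition="B")
    comparison = compare_conditions(ra, rb)
    detail = {"result_a": ra, "result_b": rb}
    if parent_genes is not None:
        pa, _ = module_eigengene(m_a, parent_genes)
        pb, _ = module_eigengene(m_b, parent_genes)
        detail["parent_cor_a"] = float(np.corrcoef(me_a, pa)[0, 1])
        detail["parent_cor_b"] = float(np.corrcoef(me_b, pb)[0, 1])
    return comparison, detail
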