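"""Module preservation across conditions.

For each condition-A module, connectivity profiles are computed in both
conditions and correlated across the module genes: intramodular connectivity
kIM (sum of within-module adjacencies) and eigengene-based connectivity kME
(correlation of each gene with the module eigengene). Modules are ranked per
statistic (rank 1 = best preserved) and summarized by the median rank; the
top-kIM gene per condition is reported as the module hub.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modules import GREY, eigengene_matrix, module_sizes


def kim_profile(a: pd.DataFrame, assign: pd.Series) -> pd.Series:
    """Per-gene intramodular connectivity; grey genes get NaN."""
    assign = assign.reindex(a.index)
    out = pd.Series(np.nan, index=a.index, name="kIM")
    for mod in module_sizes(assign).index:
        genes = a.index[assign == mod]
        sub = a.loc[genes, genes].to_numpy(float)
        out.loc[genes] = sub.sum(axis=1) - np.diag(sub)
    return out


def kme_profile(m: pd.DataFrame, e: pd.DataFrame) -> pd.DataFrame:
    """kME of every gene against every module eigengene (genes x modules)."""
    x = m.to_numpy(float)
    sd = x.std(axis=1)
    xc = x - x.mean(axis=1, keepdims=True)
    ev = e.to_numpy(float)
    ec = ev - ev.mean(axis=0, keepdims=True)
    esd = ev.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ ec) / (m.shape[1] * np.outer(sd, esd))
    if (sd == 0).any():
        import warnings

        warnings.warn(f"{int((sd == 0).sum())} zero-variance genes: kME set to NaN")
    return pd.DataFrame(r, index=m.index, columns=e.columns)


def preservation_summary(
    a_a: pd.DataFrame,
    a_b: pd.DataFrame,
    m_a: pd.DataFrame,
    m_b: pd.DataFrame,
    assign: pd.Series,
) -> pd.DataFrame:
    """Per-module preservation statistics of condition-A modules in B.

    Columns: cor_kIM, cor_kME, rank_kIM, rank_kME (rank 1 = best preserved,
    average ranks on ties), median_rank, hub gene per condition (top kIM,
    lexicographic tie-break), and a small-module reliability flag (< 3 genes).
    """
    if list(a_a.index) != list(a_b.index):
        raise ValueError("the two adjacency matrices must share the same genes")
    kim_a = kim_profile(a_a, assign)
    kim_b = kim_profile(a_b, assign)
    me_a, _ = eigengene_matrix(m_a, assign)
    me_b, _ = eigengene_matrix(m_b, assign)
    kme_a = kme_profile(m_a, me_a)
    kme_b = kme_profile(m_b, me_b)

    rows = []
    for mod in module_sizes(assign).index:
        genes = assign.index[assign == mod]
        ka, kb = kim_a.loc[genes], kim_b.loc[genes]
        rows.append(
            dict(
                module=mod,
                size=len(genes),
                cor_kIM=_safe_cor(ka, kb),
                cor_kME=_safe_cor(kme_a.loc[genes, mod], kme_b.loc[genes, mod]),
                hub_a=_hub(ka),
                hub_b=_hub(kb),
                unreliable=len(genes) < 3,
            )
        )
    t = pd.DataFrame(rows).set_index("module")
    t["rank_kIM"] = t.cor_kIM.rank(ascending=False)
    t["rank_kME"] = t.cor_kME.rank(ascending=False)
    t["median_rank"] = t[["rank_kIM", "rank_kME"]].median(axis=1)
    cols = ["size", "cor_kIM", "cor_kME", "rank_kIM", "rank_kME",
            "median_rank", "hub_a", "hub_b", "unreliable"]
    return t[cols]


def _safe_cor(x: pd.Series, y: pd.Series) -> float:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x.to_numpy(float), y.to_numpy(float))[0, 1])


def _hub(k: pd.Series) -> str:
    top = k[k == k.max()].index
    return sorted(map(str, top))[0]
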