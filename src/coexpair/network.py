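"""Soft-thresholded co-expression networks and topological overlap.

Adjacency between genes i and j is a power transform of the Pearson
correlation of their expression profiles across samples:

    unsigned:  a_ij = |r_ij| ** beta
    signed:    a_ij = ((1 + r_ij) / 2) ** beta

The power beta is chosen so that the connectivity distribution
k_i = sum_j a_ij approximates a power law (scale-free topology). The
topological overlap measure augments direct adjacency with shared
one-step neighbors:

    tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l_ij = sum_u a_iu a_uj

and DistTOM = 1 - TOM is the clustering dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SoftThresholdResult:
    """Per-power scale-free fit table and the selected power."""

    table: pd.DataFrame  # columns: beta, scale_free_r2, mean_k, median_k, max_k
    chosen_beta: int
    r2_target: float
    target_met: bool  # False -> chosen_beta maximizes r2 but misses the target


def _correlation(m: pd.DataFrame) -> np.ndarray:
    x = m.to_numpy(float)
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(m.index[sd == 0][:10])
        raise ValueError(f"constant gene rows (undefined correlation): {bad}")
    r = np.corrcoef(x)
    return np.clip(r, -1.0, 1.0)


def adjacency(m: pd.DataFrame, beta: int, mode: str = "unsigned") -> pd.DataFrame:
    """Power adjacency from gene x sample expression; diagonal set to 1."""
    r = _correlation(m)
    if mode == "unsigned":
        a = np.abs(r) ** beta
    elif mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    adj = pd.DataFrame(a, index=m.index, columns=m.index)
    adj.attrs.update(beta=beta, mode=mode)
    return adj


def connectivity(a: pd.DataFrame, subset=None) -> pd.Series:
    """Total (or subset-restricted) connectivity k_i = sum_{j != i} a_ij."""
    if subset is None:
        sub = a
        rows = a.index
    else:
        subset = list(subset)
        unknown = [g for g in subset if g not in a.index]
        if unknown:
            raise KeyError(f"genes not in adjacency: {unknown[:10]}")
        sub = a.loc[subset, subset]
        rows = sub.index
    vals = sub.to_numpy(float)
    k = vals.sum(axis=1) - np.diag(vals)
    return pd.Series(k, index=rows, name="k")


def pick_soft_threshold(
    m: pd.DataFrame,
    powers=tuple(range(1, 21)),
    mode: str = "unsigned",
    r2_target: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Scale-free topology fit across candidate powers.

    For each power the genes are binned into ``n_bins`` equal-width bins of
    connectivity k; log10 mean frequency is regressed on log10 mean k over the
    nonempty bins. The signed fit index is R^2 times the negative of the slope
    sign, so a proper power-law decay scores positively. The chosen power is
    the smallest one reaching ``r2_target``, falling back (with
    ``target_met=False``) to the best-scoring power.
    """
    powers = list(powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("powers must be a nonempty ascending list")
    r = _correlation(m)
    base = np.abs(r) if mode == "unsigned" else (1.0 + r) / 2.0
    np.fill_diagonal(base, 0.0)

    rows = []
    for beta in powers:
        k = (base**beta).sum(axis=1)
        rows.append(
            dict(
                beta=beta,
                scale_free_r2=_scale_free_fit(k, n_bins),
                mean_k=k.mean(),
                median_k=float(np.median(k)),
                max_k=k.max(),
            )
        )
    table = pd.DataFrame(rows)
    ok = table[table.scale_free_r2 >= r2_target]
    if len(ok):
        chosen = int(ok.beta.iloc[0])
        met = True
    else:
        chosen = int(table.beta.iloc[int(table.scale_free_r2.idxmax())])
        met = False
    return SoftThresholdResult(table=table, chosen_beta=chosen, r2_target=r2_target, target_met=met)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    lo, hi = k.min(), k.max()
    if hi <= lo:
        raise ValueError("degenerate connectivity distribution: all genes in one bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        cnt = mask.sum()
        if cnt == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(cnt / k.size))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity distribution: fewer than 3 usable bins")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, _ = np.polyfit(xs, ys, 1)
    r2 = np.corrcoef(xs, ys)[0, 1] ** 2
    return float(r2 * -np.sign(slope))


def tom(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from adjacency; diagonal 1."""
    av = a.to_numpy(float).copy()
    np.fill_diagonal(av, 0.0)
    k = av.sum(axis=1)
    l = av @ av  # l_ij = sum_u a_iu a_uj (diagonal of a zeroed, so u != i, j)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (l + av) / (kmin + 1.0 - av)
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 1.0)
    w = np.clip(w, 0.0, 1.0)
    t = pd.DataFrame(w, index=a.index, columns=a.columns)
    t.attrs.update(a.attrs)
    return t


def dist_tom(t: pd.DataFrame) -> pd.DataFrame:
    """DistTOM = 1 - TOM with an exactly zero diagonal."""
    d = 1.0 - t.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=t.index, columns=t.columns)


def export_edge_list(
    a: pd.DataFrame, threshold: float = 0.01, labels: pd.Series | None = None
) -> pd.DataFrame:
    """Cytoscape-style edge table: rows (source, target, weight, modules).

    Keeps each unordered gene pair once (i < j in matrix order) with
    a_ij >= threshold; the diagonal is never exported.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    av = a.to_numpy(float)
    iu, ju = np.triu_indices(av.shape[0], k=1)
    keep = av[iu, ju] >= threshold
    genes = np.asarray(a.index)
    out = pd.DataFrame(
        {
            "source": genes[iu[keep]],
            "target": genes[ju[keep]],
            "weight": av[iu, ju][keep],
        }
    )
    if labels is not None:
        out["source_module"] = labels.reindex(out.source).to_numpy()
        out["target_module"] = labels.reindex(out.target).to_numpy()
    return out
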