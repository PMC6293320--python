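"""Module detection: UPGMA clustering of DistTOM, dynamic branch cutting,
module eigengenes, and DistME-based module merging.

The branch-cutting step follows the dynamic hybrid idea without the PAM
outlier-reassignment stage: candidate branches are read off the UPGMA merge
tree below a conservative cut height, a branch is split into its two children
when both are large enough and the merge joining them sits clearly above the
heights inside them (gap criterion), and surviving branches smaller than the
minimum size are left unassigned ("grey"). Exact agreement with any specific
reference implementation is not a goal; planted-structure recovery is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GREY = "grey"

# module colors assigned by descending size, mirroring the field's convention
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


@dataclass
class Dendrogram:
    """Average-linkage merge tree over a fixed leaf ordering."""

    linkage: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    ids: list  # leaf gene ids in input order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list:
        order = hierarchy.leaves_list(self.linkage)
        return [self.ids[i] for i in order]

    def to_merge_table(self) -> pd.DataFrame:
        n = len(self.ids)
        rows = []
        for node, (left, right, height, count) in enumerate(self.linkage, start=n):
            rows.append(dict(node=node, left=int(left), right=int(right),
                             height=height, count=int(count)))
        return pd.DataFrame(rows)


def average_linkage(d: pd.DataFrame) -> Dendrogram:
    """UPGMA tree of a symmetric, zero-diagonal dissimilarity matrix."""
    dv = d.to_numpy(float)
    if np.isnan(dv).any():
        raise ValueError("NaN in dissimilarity matrix")
    if not np.allclose(dv, dv.T, atol=1e-10):
        raise ValueError("dissimilarity matrix is not symmetric")
    z = hierarchy.linkage(squareform(dv, checks=False), method="average")
    return Dendrogram(linkage=z, ids=list(d.index))


def cophenetic(dend: Dendrogram) -> pd.DataFrame:
    c = squareform(hierarchy.cophenet(dend.linkage))
    return pd.DataFrame(c, index=dend.ids, columns=dend.ids)


def cut_tree_dynamic(
    dend: Dendrogram,
    min_size: int = 50,
    cut_height: float = 0.99,
    split_gap: float = 0.02,
) -> pd.Series:
    """Adaptive branch pruning of the merge tree into modules.

    Parameters
    ----------
    min_size : smallest module retained; smaller branches become grey.
    cut_height : merges at or above this height never join branches.
    split_gap : branch-split sensitivity — a merge below the cut height still
        separates its children when both children hold at least ``min_size``
        leaves and the merge height exceeds each child's internal height by
        at least this gap. 0 disables within-cut splitting.

    Returns gene -> module label (colors by descending size, grey unassigned).
    """
    n = len(dend.ids)
    if min_size > n:
        raise ValueError(f"min_size {min_size} exceeds number of genes {n}")
    z = dend.linkage
    n_nodes = 2 * n - 1
    height = np.zeros(n_nodes)
    left = np.full(n_nodes, -1, dtype=int)
    right = np.full(n_nodes, -1, dtype=int)
    count = np.ones(n_nodes, dtype=int)
    for i in range(n - 1):
        node = n + i
        left[node], right[node] = int(z[i, 0]), int(z[i, 1])
        height[node] = z[i, 2]
        count[node] = count[left[node]] + count[right[node]]

    clusters: list[list[int]] = []
    stack = [n_nodes - 1]
    while stack:
        node = stack.pop()
        if node < n:
            clusters.append([node])
            continue
        l, r = left[node], right[node]
        if height[node] >= cut_height:
            stack.extend((l, r))
            continue
        child_top = max(height[l], height[r])
        if (
            split_gap > 0
            and count[l] >= min_size
            and count[r] >= min_size
            and height[node] - child_top >= split_gap
        ):
            stack.extend((l, r))
        else:
            clusters.append(_leaves(node, n, left, right))

    labels = pd.Series(GREY, index=dend.ids, name="module", dtype=object)
    kept = [c for c in clusters if len(c) >= min_size]
    # deterministic ordering: descending size, then smallest leaf index
    kept.sort(key=lambda c: (-len(c), min(c)))
    for color, cluster in zip(_color_iter(), kept):
        labels.iloc[cluster] = color
    return labels


def _leaves(node: int, n: int, left: np.ndarray, right: np.ndarray) -> list[int]:
    out: list[int] = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.extend((left[v], right[v]))
    return out


def _color_iter():
    yield from COLOR_SEQUENCE
    i = 1
    while True:
        yield f"module{i}"
        i += 1


def module_eigengene(m: pd.DataFrame, genes) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized expression.

    Genes are z-scored across samples, the eigengene is the leading right
    singular vector rescaled to unit variance, with its sign fixed so it
    correlates non-negatively with the module's mean standardized expression.
    Returns (eigengene over samples, fraction of variance explained).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in m.index]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {missing[:10]}")
    x = m.loc[genes].to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        raise ValueError(f"zero-variance genes in module: {bad[:10]}")
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = xs.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    me = me / me.std(ddof=1)
    return pd.Series(me, index=m.columns, name="ME"), var_explained


def eigengene_matrix(
    m: pd.DataFrame, assign: pd.Series, include_grey: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-module eigengenes (samples x modules) and variance explained."""
    mods = module_sizes(assign, include_grey=include_grey).index
    mes, ve = {}, {}
    for mod in mods:
        genes = assign.index[assign == mod]
        mes[mod], ve[mod] = module_eigengene(m, genes)
    me = pd.DataFrame(mes, index=m.columns)
    return me, pd.Series(ve, name="variance_explained")


def module_sizes(assign: pd.Series, include_grey: bool = False) -> pd.Series:
    sizes = assign.value_counts()
    if not include_grey and GREY in sizes.index:
        sizes = sizes.drop(GREY)
    # descending size, label as tie-break, for deterministic column order
    return sizes.sort_index().sort_values(ascending=False, kind="stable")


def merge_close_modules(
    m: pd.DataFrame, assign: pd.Series, threshold: float = 0.25
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge the closest module pair while DistME < threshold.

    DistME = 1 - cor(ME_p, ME_q). Eigengenes are recomputed after every
    single merge. The merged module keeps the larger member's label
    (lexicographic on ties); grey never participates.

    Returns the merged assignment and the final eigengene matrix.
    """
    assign = assign.copy()
    while True:
        me, _ = eigengene_matrix(m, assign, include_grey=False)
        if me.shape[1] < 2:
            break
        dist = dist_me(me)
        tri = dist.where(np.triu(np.ones(dist.shape, dtype=bool), k=1))
        min_val = np.nanmin(tri.to_numpy())
        if not (min_val < threshold):
            break
        i, j = np.unravel_index(np.nanargmin(tri.to_numpy()), tri.shape)
        a, b = dist.index[i], dist.columns[j]
        na, nb = (assign == a).sum(), (assign == b).sum()
        if na > nb:
            keep, drop = a, b
        elif nb > na:
            keep, drop = b, a
        else:
            keep, drop = sorted((a, b))
        assign[assign == drop] = keep
    me, _ = eigengene_matrix(m, assign, include_grey=False)
    return assign, me


def dist_me(me: pd.DataFrame) -> pd.DataFrame:
    """Eigengene dissimilarity 1 - Pearson r, zero diagonal."""
    if (me.std() == 0).any():
        bad = list(me.columns[me.std() == 0])
        raise ValueError(f"constant eigengene columns: {bad}")
    d = 1.0 - np.corrcoef(me.to_numpy(float).T)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=me.columns, columns=me.columns)


def eigengene_network(
    me: pd.DataFrame, extra: pd.Series | None = None
) -> tuple[pd.DataFrame, Dendrogram]:
    """DistME matrix (optionally including a trait column) and its UPGMA tree."""
    cols = me.copy()
    if extra is not None:
        cols[extra.name or "trait"] = extra.reindex(me.index).astype(float)
    if cols.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    d = dist_me(cols)
    return d, average_linkage(d)
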