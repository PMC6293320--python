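"""Risk-locus assignment and module enrichment testing.

Risk loci (e.g. genome-wide-significant GWAS hits) are assigned to genes
within a fixed genomic window. Per-module risk-gene fractions are tested
against a permutation null in which random gene sets of the same size are
drawn with selection probability proportional to total network connectivity
k, so the null respects the tendency of well-connected genes to fall in
modules. A generic Fisher's exact enrichment is provided for user-supplied
gene sets (GMT exports of GO/KEGG and the like).
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.stats import fisher_exact

from .modules import GREY, module_sizes


@dataclass
class RiskGeneSet:
    """Genes flagged as risk genes, with the locus -> gene provenance."""

    genes: set
    provenance: pd.DataFrame  # columns: locus_id, chrom, pos, gene, distance
    window_bp: int


@dataclass
class EnrichmentResult:
    module: str
    observed_fraction: float
    null_mean_fraction: float
    empirical_p: float
    n_permutations: int
    weighting: str  # "k-weighted" | "uniform"
    seed: int


def assign_risk_genes(
    annot: pd.DataFrame, loci: pd.DataFrame, window_bp: int = 250_000
) -> RiskGeneSet:
    """Flag genes whose interval lies within ``window_bp`` of any risk locus.

    ``annot``: index gene, columns chrom/start/end (1-based inclusive).
    ``loci``: columns chrom/pos/id. Distance is 0 for a locus inside the gene
    body; strand is ignored. Chromosome names must match between the tables.
    """
    if len(loci):
        bad = sorted(set(loci.chrom.astype(str)) - set(annot.chrom.astype(str)))
        if bad:
            raise ValueError(f"risk-locus chromosomes absent from annotation: {bad}")
    rows = []
    for chrom, ann in annot.groupby(annot.chrom.astype(str)):
        sub = loci[loci.chrom.astype(str) == chrom]
        if sub.empty:
            continue
        start = ann.start.to_numpy(int)
        end = ann.end.to_numpy(int)
        for locus in sub.drop_duplicates(subset=["chrom", "pos"]).itertuples():
            pos = int(locus.pos)
            dist = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
            hit = dist <= window_bp
            for gene, d in zip(ann.index[hit], dist[hit]):
                rows.append(dict(locus_id=locus.id, chrom=chrom, pos=pos,
                                 gene=gene, distance=int(d)))
    prov = pd.DataFrame(rows, columns=["locus_id", "chrom", "pos", "gene", "distance"])
    prov = prov.sort_values(["chrom", "pos", "gene"]).reset_index(drop=True)
    return RiskGeneSet(genes=set(prov.gene), provenance=prov, window_bp=window_bp)


def module_risk_fraction(assign: pd.Series, risk: RiskGeneSet) -> pd.Series:
    """Percent of each module's genes (grey included) that are risk genes."""
    out = {}
    for mod in assign.unique():
        genes = assign.index[assign == mod]
        out[mod] = 100.0 * len(set(genes) & risk.genes) / len(genes)
    return pd.Series(out, name="percent_risk").sort_index()


def weighted_permutation_test(
    module_genes,
    risk: RiskGeneSet,
    k: pd.Series,
    B: int = 10_000,
    seed: int = 0,
    weighted: bool = True,
    return_null: bool = False,
):
    """Connectivity-weighted permutation test of a module's risk fraction.

    Each permutation draws |module| genes from the universe (the index of
    ``k``) without replacement, with selection probability proportional to k
    (Efraimidis–Spirakis exponential-keys sampling, so the draw is
    order-independent and reproducible). The empirical P uses the add-one
    convention: (1 + #{null fraction >= observed}) / (B + 1); ties count
    toward the tail.
    """
    module_genes = list(module_genes)
    universe = k.index
    missing = [g for g in module_genes if g not in universe]
    if missing:
        raise KeyError(f"module genes outside the connectivity universe: {missing[:10]}")
    size = len(module_genes)
    risk_mask = np.fromiter((g in risk.genes for g in universe), bool, len(universe))
    observed = risk_mask[[universe.get_loc(g) for g in module_genes]].mean()

    w = k.to_numpy(float)
    mode = "k-weighted"
    if not weighted or w.sum() == 0:
        if weighted and w.sum() == 0:
            warnings.warn("all-zero connectivity: falling back to uniform sampling")
        w = np.ones_like(w)
        mode = "uniform" if not weighted else "k-weighted"
    if (w < 0).any():
        raise ValueError("negative connectivity weights")
    w = np.maximum(w, 1e-300)

    rng = np.random.default_rng(seed)
    null_fracs = np.empty(B)
    for b in range(B):
        keys = rng.exponential(size=w.size) / w
        chosen = np.argpartition(keys, size - 1)[:size]
        null_fracs[b] = risk_mask[chosen].mean()
    p = (1.0 + np.sum(null_fracs >= observed - 1e-12)) / (B + 1.0)
    result = EnrichmentResult(
        module="",
        observed_fraction=float(observed),
        null_mean_fraction=float(null_fracs.mean()),
        empirical_p=float(p),
        n_permutations=B,
        weighting=mode,
        seed=seed,
    )
    return (result, null_fracs) if return_null else result


def module_enrichment_table(
    assign: pd.Series,
    risk: RiskGeneSet,
    k: pd.Series,
    B: int = 10_000,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Risk fraction + permutation P for every module (grey included)."""
    fracs = module_risk_fraction(assign, risk)
    rows = []
    rng = np.random.default_rng(seed)
    for mod in module_sizes(assign, include_grey=True).index:
        genes = assign.index[assign == mod]
        res = weighted_permutation_test(
            genes, risk, k, B=B, seed=int(rng.integers(2**31)), weighted=weighted
        )
        rows.append(dict(module=mod, size=len(genes), percent_risk=fracs[mod],
                         null_mean_percent=100 * res.null_mean_fraction,
                         empirical_p=res.empirical_p))
    return pd.DataFrame(rows).set_index("module")


def fisher_gene_set_enrichment(module_genes, gene_set, universe) -> tuple[float, float, float]:
    """Fisher's exact test of a module against a gene set.

    Returns (odds ratio, two-sided exact P, fold enrichment), where fold is
    the module's in-set fraction over the universe-wide in-set fraction.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module_genes = set(module_genes) & universe
    gene_set = set(gene_set) & universe
    a = len(module_genes & gene_set)
    b = len(module_genes - gene_set)
    c = len(gene_set - module_genes)
    d = len(universe) - a - b - c
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if not module_genes or not gene_set:
        fold = float("nan")
    else:
        fold = (a / len(module_genes)) / (len(gene_set) / len(universe))
    return float(odds), float(p), float(fold)
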