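"""Synthetic paired-condition datasets with planted co-expression structure.

The generator emulates the shape of a case/control expression study measured
under two conditions on the same samples (here: a baseline and a stimulated
state). Each planted module is a single latent factor with geometrically
decaying gene loadings, which produces hub genes and an approximately
scale-free connectivity profile. The factor mean carries the case/control
shift (so the module eigengene is the natural readout), covariate effects,
and — for one designated module — an additive QTL effect from a planted SNP.
One designated "responder" module has a stronger status shift in condition 2
than in condition 1; all other modules keep the condition-1 shift in both
conditions. Background genes are independent noise.

All randomness flows through named child streams of the master seed (one per
data category), so e.g. changing the number of SNPs never perturbs the
expression draws.
"""

from __future__ import annotations

import json
import math
import os

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .modules import GREY

_STREAMS = ("samples", "params", "expr_base", "expr_stim", "genotypes", "qtl", "risk")


@dataclass
class SimConfig:
    """Study-shape and effect-size settings for the generator.

    Defaults describe the study conditions the package is exercised under:
    3,000 genes on 400 samples (200 cases / 200 controls) in two conditions,
    five hub-structured modules of 60–200 genes, unit-variance gene noise,
    and a responder module whose status shift rises from 0.25 to 0.75 latent
    standard deviations under stimulation.
    """

    n_genes: int = 3000
    n_cases: int = 200
    n_controls: int = 200
    n_modules: int = 5
    module_sizes: tuple = (200, 150, 120, 80, 60)
    loading_decay: float = 0.99  # hub structure: loading = decay ** within-module rank
    noise_sd: float = 1.0
    responder_module: int = 0
    beta_status_base: float = 0.25
    beta_status_stim: float = 0.75
    n_covariates: int = 3
    covariate_effect_sd: float = 0.2
    n_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    qtl_module: int = 1
    qtl_effect: float = 0.35
    genotype_missing_rate: float = 0.0
    risk_fraction_module: float = 0.05  # responder-module genes near a risk locus
    risk_fraction_background: float = 0.025  # non-module genes near a risk locus
    window_bp: int = 250_000
    seed: int = 0

    def validate(self) -> None:
        sizes = list(self.module_sizes)
        if len(sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if any(s < 1 for s in sizes):
            raise ValueError("all module sizes must be >= 1")
        if sum(sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(sizes)} > n_genes = {self.n_genes}"
            )
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.loading_decay <= 1:
            raise ValueError("loading_decay must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("responder_module", "qtl_module"):
            if not 0 <= getattr(self, name) < self.n_modules:
                raise ValueError(f"{name} out of range")
        if not 0 <= self.risk_fraction_module <= 1:
            raise ValueError("risk_fraction_module must be in [0, 1]")


@dataclass
class SyntheticDataset:
    expr_base: pd.DataFrame  # genes x samples
    expr_stim: pd.DataFrame
    samples: pd.DataFrame  # index id; status + covariates
    genotypes: pd.DataFrame  # samples x SNPs, 0/1/2 (NaN missing)
    snp_map: pd.DataFrame  # index snp; chrom, pos
    gene_annot: pd.DataFrame  # index gene; chrom, start, end
    risk_loci: pd.DataFrame  # chrom, pos, id
    truth: dict  # labels (Series), responder_module, qtl_snp, loadings (Series)


def simulate_genotypes(
    n_samples: int, mafs, seed: int = 0, missing_rate: float = 0.0
) -> np.ndarray:
    """Additive genotypes under Hardy–Weinberg proportions (samples x SNPs)."""
    mafs = np.asarray(mafs, float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("all minor-allele frequencies must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, mafs, size=(n_samples, mafs.size)).astype(float)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = np.nan
    return g


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Draw a full paired-condition dataset with ground-truth labels."""
    cfg = config
    cfg.validate()
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(_STREAMS, np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS)))
    }
    n = cfg.n_cases + cfg.n_controls
    sample_ids = [f"S{i+1:04d}" for i in range(n)]
    gene_index = pd.Index([f"G{i+1:05d}" for i in range(cfg.n_genes)], name="gene")
    gene_ids = list(gene_index)
    status = np.r_[np.ones(cfg.n_cases), np.zeros(cfg.n_controls)]

    # covariates and per-module covariate effects (shared across conditions)
    Z = streams["samples"].normal(size=(n, cfg.n_covariates))
    gammas = streams["params"].normal(
        scale=cfg.covariate_effect_sd, size=(cfg.n_modules, cfg.n_covariates)
    )

    # panel genotypes from one stream; the QTL SNP from its own stream so the
    # expression draws are invariant to the panel size
    mafs = streams["genotypes"].uniform(*cfg.maf_range, size=cfg.n_snps)
    geno = simulate_genotypes(
        n, mafs, seed=int(streams["genotypes"].integers(2**31)),
        missing_rate=cfg.genotype_missing_rate,
    )
    snp_ids = [f"rs{i+1:06d}" for i in range(cfg.n_snps)]
    qtl_idx = cfg.n_snps // 2
    qtl_maf = streams["qtl"].uniform(max(cfg.maf_range[0], 0.2), cfg.maf_range[1])
    geno[:, qtl_idx] = simulate_genotypes(
        n, [qtl_maf], seed=int(streams["qtl"].integers(2**31)),
        missing_rate=cfg.genotype_missing_rate,
    )[:, 0]
    mafs[qtl_idx] = qtl_maf
    qtl_dose = np.nan_to_num(geno[:, qtl_idx], nan=2 * qtl_maf)
    qtl_dose = qtl_dose - qtl_dose.mean()

    # module membership and loadings
    labels = pd.Series(GREY, index=gene_index, name="module", dtype=object)
    loadings = pd.Series(0.0, index=gene_index, name="loading")
    pos = 0
    blocks = []
    for m, size in enumerate(cfg.module_sizes):
        genes = gene_ids[pos:pos + size]
        labels.loc[genes] = f"M{m+1}"
        loadings.loc[genes] = cfg.loading_decay ** np.arange(size)
        blocks.append((m, pos, size))
        pos += size

    def one_condition(stream: np.random.Generator, stim: bool) -> pd.DataFrame:
        x = stream.normal(scale=cfg.noise_sd, size=(cfg.n_genes, n))
        for m, start, size in blocks:
            beta = cfg.beta_status_base
            if stim and m == cfg.responder_module:
                beta = cfg.beta_status_stim
            u = stream.normal(size=n) + beta * status + Z @ gammas[m]
            if m == cfg.qtl_module:
                u = u + cfg.qtl_effect * qtl_dose
            lam = loadings.iloc[start:start + size].to_numpy()
            x[start:start + size] += np.outer(lam, u)
        return pd.DataFrame(x, index=gene_index, columns=sample_ids)

    expr_base = one_condition(streams["expr_base"], stim=False)
    expr_stim = one_condition(streams["expr_stim"], stim=True)

    samples = pd.DataFrame(
        {"status": status.astype(int),
         **{f"cov{j+1}": Z[:, j] for j in range(cfg.n_covariates)}},
        index=pd.Index(sample_ids, name="id"),
    )
    genotypes = pd.DataFrame(geno, index=samples.index, columns=snp_ids)
    snp_map = pd.DataFrame(
        {"chrom": "2", "pos": 10_000 * (np.arange(cfg.n_snps) + 1)},
        index=pd.Index(snp_ids, name="snp"),
    )
    # genes spaced 1 Mb apart on one chromosome so each locus tags one gene
    starts = 1 + 1_000_000 * np.arange(cfg.n_genes)
    gene_annot = pd.DataFrame(
        {"chrom": "1", "start": starts, "end": starts + 9_999},
        index=pd.Index(gene_ids, name="gene"),
    )
    risk_loci = _plant_risk_loci(cfg, labels, gene_annot, streams["risk"])

    truth = dict(
        labels=labels,
        responder_module=f"M{cfg.responder_module + 1}",
        qtl_module=f"M{cfg.qtl_module + 1}",
        qtl_snp=snp_ids[qtl_idx],
        loadings=loadings,
    )
    return SyntheticDataset(
        expr_base=expr_base, expr_stim=expr_stim, samples=samples,
        genotypes=genotypes, snp_map=snp_map, gene_annot=gene_annot,
        risk_loci=risk_loci, truth=truth,
    )


def _plant_risk_loci(cfg, labels, gene_annot, rng) -> pd.DataFrame:
    responder = f"M{cfg.responder_module + 1}"
    resp_genes = list(labels.index[labels == responder])
    other_genes = list(labels.index[labels != responder])
    n_resp = math.ceil(cfg.risk_fraction_module * len(resp_genes))
    n_bg = int(round(cfg.risk_fraction_background * len(other_genes)))
    chosen = []
    if n_resp:
        chosen += list(rng.choice(resp_genes, size=n_resp, replace=False))
    if n_bg:
        chosen += list(rng.choice(other_genes, size=n_bg, replace=False))
    rows = []
    for i, gene in enumerate(sorted(chosen)):
        mid = int((gene_annot.loc[gene, "start"] + gene_annot.loc[gene, "end"]) // 2)
        rows.append(dict(chrom="1", pos=mid, id=f"locus{i+1:04d}"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id"])


DATASET_FILES = {
    "expr_base": "expression_base.tsv",
    "expr_stim": "expression_stim.tsv",
    "samples": "samples.tsv",
    "genotypes": "genotypes.tsv",
    "snp_map": "snp_map.tsv",
    "gene_annot": "gene_annotation.tsv",
    "risk_loci": "risk_loci.tsv",
}


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write every table of the dataset (plus ground truth) as TSV/JSON."""
    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in DATASET_FILES.items()}
    cio.write_expression(ds.expr_base, paths["expr_base"])
    cio.write_expression(ds.expr_stim, paths["expr_stim"])
    cio.write_sample_table(ds.samples, paths["samples"])
    cio.write_genotypes(ds.genotypes, paths["genotypes"])
    ds.snp_map.to_csv(paths["snp_map"], sep="\t", index_label="snp")
    ds.gene_annot.to_csv(paths["gene_annot"], sep="\t", index_label="gene")
    ds.risk_loci.to_csv(paths["risk_loci"], sep="\t", index=False)
    truth_path = os.path.join(directory, "truth_modules.tsv")
    cio.write_module_assignment(ds.truth["labels"], truth_path)
    meta = {k: ds.truth[k] for k in ("responder_module", "qtl_module", "qtl_snp")}
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    paths["truth_modules"] = truth_path
    paths["truth"] = os.path.join(directory, "truth.json")
    return paths


def read_dataset(directory) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    p = {k: os.path.join(directory, v) for k, v in DATASET_FILES.items()}
    with open(os.path.join(directory, "truth.json")) as fh:
        meta = json.load(fh)
    truth = dict(
        labels=cio.read_module_assignment(os.path.join(directory, "truth_modules.tsv")),
        loadings=None,
        **meta,
    )
    return SyntheticDataset(
        expr_base=cio.read_expression(p["expr_base"]),
        expr_stim=cio.read_expression(p["expr_stim"]),
        samples=cio.read_sample_table(p["samples"]),
        genotypes=cio.read_genotypes(p["genotypes"]),
        snp_map=cio.read_snp_map(p["snp_map"]),
        gene_annot=cio.read_gene_annotation(p["gene_annot"]),
        risk_loci=cio.read_risk_loci(p["risk_loci"]),
        truth=truth,
    )
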