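"""End-to-end orchestration of the paired-condition analysis.

Stages: preprocess -> network (per condition) -> module detection (per
condition) -> cross-condition association -> preservation -> risk-locus
enrichment -> QTL scan. Every stage writes TSV outputs carrying a header
comment with the tool version, config hash and seed, and the run ends with
a JSON manifest of per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import crosscond, enrich, io as cio, modules, network, preprocess, preserve, qtl


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters for a full run; defaults follow the analysis
    conventions this pipeline models (cut height 0.99, minimum module size
    50, DistME merge threshold 0.25, scale-free r2 target 0.9, 10,000
    permutations, 250 kb risk window, 0.01 edge-export threshold)."""

    data_dir: str = "."
    out_dir: str = "results"
    mode: str = "unsigned"  # adjacency: unsigned | signed
    powers: tuple = tuple(range(1, 13))
    beta: int | None = None  # fixed power; None -> pick by scale-free fit
    r2_target: float = 0.9
    min_size: int = 50
    cut_height: float = 0.99
    split_gap: float = 0.02
    merge_threshold: float = 0.25
    edge_threshold: float = 0.01
    permutations: int = 10_000
    window_bp: int = 250_000
    n_pcs: int = 5
    maf_min: float = 0.01
    callrate_min: float = 0.95
    seed: int = 0
    run_preprocess: bool = False  # residualize on the sample-table covariates
    run_enrichment: bool = True
    run_qtl: bool = True
    max_dense_genes: int = 25_000  # refuse larger dense TOM without override

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("powers",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        params = dataclasses.asdict(self)
        params.pop("data_dir")
        params.pop("out_dir")
        enc = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:12]


def run_all(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the manifest dictionary."""
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    header = (
        f"coexpair {__version__}\nconfig_hash: {cfg.config_hash()}\nseed: {cfg.seed}"
    )
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages": {},
        "files": {},
    }

    def emit(name, writer, *args):
        path = os.path.join(cfg.out_dir, name)
        writer(*args, path, header)
        manifest["files"][name] = _sha256(path)
        return path

    stage = "load"
    try:
        d = cfg.data_dir
        expr = {
            "base": cio.read_expression(os.path.join(d, "expression_base.tsv")),
            "stim": cio.read_expression(os.path.join(d, "expression_stim.tsv")),
        }
        samples = cio.read_sample_table(os.path.join(d, "samples.tsv"))
        status = samples["status"]

        stage = "preprocess"
        if cfg.run_preprocess:
            cov = samples.drop(columns=["status"])
            for cond in expr:
                m = preprocess.quantile_normalize(expr[cond])
                expr[cond] = preprocess.residualize(m, cov)
                emit(f"expression_{cond}_residualized.tsv", cio.write_expression, expr[cond])

        n_genes = expr["base"].shape[0]
        if n_genes > cfg.max_dense_genes:
            raise MemoryError(
                f"{n_genes} genes exceeds max_dense_genes={cfg.max_dense_genes}; "
                "raise the limit explicitly to run a dense TOM this large"
            )

        stage = "network"
        adj, tom_d, beta_used = {}, {}, {}
        for cond in ("base", "stim"):
            if cfg.beta is None:
                sft = network.pick_soft_threshold(
                    expr[cond], cfg.powers, cfg.mode, cfg.r2_target
                )
                beta_used[cond] = sft.chosen_beta
                emit(f"soft_threshold_{cond}.tsv",
                     lambda t, p, h: cio._write_tsv(t, p, h), sft.table)
            else:
                beta_used[cond] = cfg.beta
            adj[cond] = network.adjacency(expr[cond], beta_used[cond], cfg.mode)
            tom_d[cond] = network.dist_tom(network.tom(adj[cond]))
        manifest["stages"]["network"] = {"beta": beta_used, "mode": cfg.mode}

        stage = "modules"
        assign, me = {}, {}
        for cond in ("base", "stim"):
            dend = modules.average_linkage(tom_d[cond])
            raw = modules.cut_tree_dynamic(
                dend, cfg.min_size, cfg.cut_height, cfg.split_gap
            )
            if (raw == modules.GREY).all():
                raise ValueError(
                    f"no modules detected in condition {cond!r} at beta="
                    f"{beta_used[cond]}; try a lower power or cut settings"
                )
            assign[cond], me[cond] = modules.merge_close_modules(
                expr[cond], raw, cfg.merge_threshold
            )
            emit(f"modules_{cond}.tsv", cio.write_module_assignment, assign[cond])
            emit(f"eigengenes_{cond}.tsv", cio.write_eigengenes, me[cond])
            edges = network.export_edge_list(adj[cond], cfg.edge_threshold, assign[cond])
            emit(f"edges_{cond}.tsv",
                 lambda t, p, h: cio._write_tsv(t.set_index("source"), p, h, "source"), edges)

        stage = "cross_condition"
        overlap = crosscond.overlap_table(assign["base"], assign["stim"])
        emit("overlap.tsv",
             lambda t, p, h: cio._write_tsv(t.set_index("module_a"), p, h, "module_a"),
             overlap)
        me_fixed_base, _ = crosscond.recompute_fixed_membership(expr["base"], assign["base"])
        me_fixed_stim, _ = crosscond.recompute_fixed_membership(expr["stim"], assign["base"])
        assoc = crosscond.association_table(me_fixed_base, me_fixed_stim, status)
        emit("association.tsv",
             lambda t, p, h: cio._write_tsv(t, p, h, "module"), assoc)
        manifest["stages"]["cross_condition"] = {
            "module_match": crosscond.match_modules(overlap),
        }

        stage = "preservation"
        pres = preserve.preservation_summary(
            adj["base"], adj["stim"], expr["base"], expr["stim"], assign["base"]
        )
        emit("preservation.tsv", lambda t, p, h: cio._write_tsv(t, p, h, "module"), pres)

        stage = "enrichment"
        if cfg.run_enrichment and os.path.exists(os.path.join(d, "risk_loci.tsv")):
            annot = cio.read_gene_annotation(os.path.join(d, "gene_annotation.tsv"))
            loci = cio.read_risk_loci(os.path.join(d, "risk_loci.tsv"))
            risk = enrich.assign_risk_genes(annot, loci, cfg.window_bp)
            k = network.connectivity(adj["base"])
            enr = enrich.module_enrichment_table(
                assign["base"], risk, k, B=cfg.permutations, seed=cfg.seed
            )
            emit("enrichment.tsv", lambda t, p, h: cio._write_tsv(t, p, h, "module"), enr)

        stage = "qtl"
        if cfg.run_qtl and os.path.exists(os.path.join(d, "genotypes.tsv")):
            geno = cio.read_genotypes(os.path.join(d, "genotypes.tsv"))
            pcs = qtl.genotype_pcs(geno, cfg.n_pcs)
            # scan the module whose fit improves most under condition B,
            # mirroring the follow-up of the strongest responder
            target = assoc.delta_aic.idxmin()
            scan = qtl.qtl_scan(
                me_fixed_stim[target], geno, pcs, cfg.maf_min, cfg.callrate_min
            )
            inter = qtl.interaction_scan(
                me_fixed_stim[target], geno, status, pcs, cfg.maf_min, cfg.callrate_min
            )
            emit("qtl_scan.tsv", lambda t, p, h: cio._write_tsv(t, p, h, "snp"), scan.table)
            emit("qtl_interaction.tsv",
                 lambda t, p, h: cio._write_tsv(t, p, h, "snp"), inter.table)
            manifest["stages"]["qtl"] = {
                "module": str(target),
                "lambda": scan.lambda_gc,
                "lambda_interaction": inter.lambda_gc,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()
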