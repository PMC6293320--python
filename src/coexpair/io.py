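"""Readers and writers for the plain-text formats used throughout the package.

All tables are tab-separated. Expression matrices are genes x samples with the
gene identifier in the first column and sample identifiers in the header.
Genotypes are samples x SNPs with additive dosages 0/1/2 (NA for missing);
the PLINK ``.raw`` dialect (FID IID PAT MAT SEX PHENOTYPE, then one column
per SNP) is accepted as well.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix; index = gene ids."""
    m = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return m.astype(float)


def write_expression(m: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_tsv(m, path, header_comment, index_label="gene")


def read_sample_table(path) -> pd.DataFrame:
    """Sample table: columns id, status (0/1), then covariates."""
    t = pd.read_csv(path, sep="\t", comment="#")
    if "id" not in t.columns or "status" not in t.columns:
        raise ValueError("sample table must have 'id' and 'status' columns")
    return t.set_index("id")


def write_sample_table(t: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_tsv(t, path, header_comment, index_label="id")


def read_genotypes(path) -> pd.DataFrame:
    """Read genotypes from TSV (samples x SNPs) or PLINK .raw text.

    Returns a samples x SNPs float matrix with NaN for missing calls.
    """
    head = pd.read_csv(path, sep=r"\s+", nrows=0, comment="#")
    if list(head.columns[:6]) == PLINK_RAW_META:
        g = pd.read_csv(path, sep=r"\s+", comment="#")
        g = g.set_index("IID").drop(columns=[c for c in PLINK_RAW_META if c != "IID"])
        # .raw columns are SNP_countedAllele; strip the allele suffix
        g.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in g.columns]
        g.index.name = "id"
        return g.astype(float)
    g = pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"])
    return g.astype(float)


def write_genotypes(g: pd.DataFrame, path, header_comment: str | None = None) -> None:
    out = g.copy()
    _write_tsv(out, path, header_comment, index_label="id", na_rep="NA")


def read_snp_map(path) -> pd.DataFrame:
    """SNP map: columns snp, chrom, pos (1-based)."""
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return t.set_index("snp")


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation: columns gene, chrom, start, end (1-based inclusive)."""
    t = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return t.set_index("gene")


def read_risk_loci(path) -> pd.DataFrame:
    """Risk loci: columns chrom, pos, id."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def read_module_assignment(path) -> pd.Series:
    t = pd.read_csv(path, sep="\t", comment="#")
    return t.set_index("gene")["module"]


def write_module_assignment(assign: pd.Series, path, header_comment: str | None = None) -> None:
    t = assign.rename("module").to_frame()
    _write_tsv(t, path, header_comment, index_label="gene")


def read_eigengenes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_eigengenes(me: pd.DataFrame, path, header_comment: str | None = None) -> None:
    _write_tsv(me, path, header_comment, index_label="sample")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: one set per line — name, description, gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def _write_tsv(df: pd.DataFrame, path, header_comment, index_label=None, na_rep="") -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, na_rep=na_rep)


def frame_checksum(df: pd.DataFrame) -> str:
    """Stable content hash of a DataFrame (used by the pipeline manifest)."""
    import hashlib

    h = hashlib.sha256()
    h.update(",".join(map(str, df.index)).encode())
    h.update(",".join(map(str, df.columns)).encode())
    vals = df.to_numpy()
    if vals.dtype.kind in "fc":
        vals = np.round(vals.astype(float), 10) + 0.0  # normalize -0.0
    h.update(np.ascontiguousarray(vals).tobytes())
    return h.hexdigest()
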