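"""Readers and writers for the plain-text interchange formats.

Cell identifiers must match exactly (case-sensitive) across the expression,
context, donor-map and cluster-label files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import mmread

from scgxc.preprocessing import CellDonorMap, ContextMatrix

__all__ = [
    "read_expression",
    "read_expression_mtx",
    "read_dosages",
    "read_vcf_dosages",
    "read_contexts",
    "read_donor_map",
    "read_kinship",
    "read_cluster_labels",
    "read_gene_bed",
    "read_gene_gtf",
    "read_pair_list",
    "write_results",
]


def read_expression(path, sep: str = "\t") -> pd.DataFrame:
    """Dense genes x cells expression table (TSV/CSV, gene IDs in the first column)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"no expression data in {path}")
    return df


def read_expression_mtx(mtx_path, gene_index_path, cell_index_path) -> pd.DataFrame:
    """MatrixMarket triplet matrix plus one-ID-per-line row/column index files."""
    mat = mmread(mtx_path)
    genes = [line.strip() for line in open(gene_index_path) if line.strip()]
    cells = [line.strip() for line in open(cell_index_path) if line.strip()]
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match index files "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    return pd.DataFrame(dense, index=genes, columns=cells)


def read_dosages(path, sep: str = "\t") -> pd.DataFrame:
    """Variants x donors dosage table; values in [0, 2], 'NA' allowed."""
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    vals = df.to_numpy(dtype=float)
    valid = vals[~np.isnan(vals)]
    if valid.size and (valid.min() < 0 or valid.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    return df


def read_vcf_dosages(path) -> pd.DataFrame:
    """Minimal VCF reader: diploid GT fields to alt-allele dosage; './.' -> NA."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        gts = var.genotypes  # [allele_a, allele_b, phased]
        dosage = []
        for gt in gts:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                dosage.append(np.nan)
            else:
                dosage.append(float((a > 0) + (b > 0)))
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        rows.append(dosage)
    return pd.DataFrame(rows, index=ids, columns=donors)


def read_contexts(path, sep: str = "\t") -> tuple[ContextMatrix, list[str]]:
    """Cells x contexts TSV with a header; returns the matrix and the cell IDs."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ContextMatrix(df.to_numpy(dtype=float), labels=list(df.columns)), list(df.index)


def read_donor_map(path, sep: str = "\t") -> tuple[CellDonorMap, list[str], list[str]]:
    """Two-column TSV (cell_id, donor_id); returns the map, cell IDs and donor IDs."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("donor map needs at least two columns (cell_id, donor_id)")
    cells = df.iloc[:, 0].astype(str).tolist()
    donor_ids = df.iloc[:, 1].astype(str)
    levels = list(pd.unique(donor_ids))
    lookup = {d: i for i, d in enumerate(levels)}
    return CellDonorMap(donor_ids.map(lookup).to_numpy()), cells, levels


def read_kinship(path, sep: str = "\t", tol: float = 1e-8) -> tuple[np.ndarray, list[str]]:
    """Square donor x donor TSV with matching header / first column; must be symmetric."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship row and column donor IDs disagree")
    K = df.to_numpy(dtype=float)
    if not np.allclose(K, K.T, atol=tol):
        raise ValueError("kinship matrix is not symmetric")
    return K, list(df.index)


def read_cluster_labels(path, sep: str = "\t") -> pd.Series:
    """Two-column TSV (cell_id, cluster) -> Series indexed by cell ID."""
    df = pd.read_csv(path, sep=sep)
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))


def read_gene_bed(path) -> pd.DataFrame:
    """BED file of gene bodies (chrom, start, end, gene_id); 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id"], usecols=range(4),
    )
    return df.set_index("gene_id")


def read_gene_gtf(path) -> pd.DataFrame:
    """Gene bodies from GTF 'gene' lines; converts to 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in fields[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"GTF gene line without gene_id: {line[:80]}")
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,  # GTF is 1-based inclusive
                    "end": int(fields[4]),
                }
            )
    if not rows:
        raise ValueError(f"no gene lines found in {path}")
    return pd.DataFrame(rows).set_index("gene_id")[["chrom", "start", "end"]]


def read_pair_list(path, sep: str = "\t") -> pd.DataFrame:
    """Gene-variant pair table with columns gene_id, variant_id (extra columns kept)."""
    df = pd.read_csv(path, sep=sep)
    need = {"gene_id", "variant_id"}
    if not need <= set(df.columns):
        raise ValueError(f"pair list must have columns {sorted(need)}")
    if df.duplicated(["gene_id", "variant_id"]).any():
        raise ValueError("pair list contains duplicate gene-variant pairs")
    return df


def write_results(df: pd.DataFrame, path) -> None:
    """Stable-column-order TSV output."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
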