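"""End-to-end orchestration: two-stage discovery, multiple-testing correction
and pseudobulk confirmation of stratified cell sets."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from scgxc.covariance import context_covariance, relatedness_context_covariance
from scgxc.inference import association_lrt, interaction_score_test
from scgxc.null_model import FixedDesign
from scgxc.preprocessing import (
    CellDonorMap,
    ContextMatrix,
    ExpressionVector,
    gaussianize,
)

log = logging.getLogger("scgxc")

__all__ = [
    "PairList",
    "CorrectedResults",
    "DataBundle",
    "two_stage_scan",
    "correct_multiple_testing",
    "storey_qvalues",
    "bh_qvalues",
    "pseudobulk_confirmation",
]


@dataclass
class PairList:
    """Unique gene-variant pairs nominated for testing."""

    pairs: pd.DataFrame  # columns: gene_id, variant_id (+ optional evidence)

    def __post_init__(self) -> None:
        if self.pairs.duplicated(["gene_id", "variant_id"]).any():
            raise ValueError("pair list contains duplicates")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CorrectedResults:
    """Raw, gene-level Bonferroni and across-gene FDR adjusted p-values."""

    per_pair: pd.DataFrame      # gene_id, variant_id, pvalue
    per_gene: pd.DataFrame      # gene_id, p_gene (Bonferroni), qvalue, significant
    fdr: float
    method: str
    pi0: float | None = None


@dataclass
class DataBundle:
    """All inputs of a scan, already aligned on cells and donors."""

    expression: pd.DataFrame            # genes x cells, raw or log counts
    dosages: pd.DataFrame               # variants x donors
    contexts: ContextMatrix             # standardized, cells in expression order
    cell_map: CellDonorMap
    gene_coords: pd.DataFrame | None = None    # index gene_id: chrom, start, end
    variant_coords: pd.DataFrame | None = None  # index variant_id: chrom, pos
    kinship: np.ndarray | None = None
    covariances: dict = field(default_factory=dict, repr=False)

    def model_terms(self):
        if "Sigma" not in self.covariances:
            self.covariances["Sigma"] = context_covariance(self.contexts)
            self.covariances["RSigma"] = relatedness_context_covariance(
                self.cell_map, self.contexts, kinship=self.kinship
            )
        return self.covariances["Sigma"], self.covariances["RSigma"]

    def genotype_cells(self, variant_id: str) -> np.ndarray:
        dosage = self.dosages.loc[variant_id].to_numpy(dtype=float)
        return dosage[self.cell_map.assignment]

    def phenotype(self, gene_id: str) -> np.ndarray:
        vec = ExpressionVector(
            self.expression.loc[gene_id].to_numpy(dtype=float), gene_id=str(gene_id)
        )
        return gaussianize(vec).values


def _cis_variants(bundle: DataBundle, gene_id: str, window: int, maf_min: float):
    coords = bundle.gene_coords.loc[gene_id]
    variants = bundle.variant_coords
    near = variants[
        (variants["chrom"] == coords["chrom"])
        & (variants["pos"] >= coords["start"] - window)
        & (variants["pos"] < coords["end"] + window)
    ].index
    kept = []
    for v in near:
        dosage = bundle.dosages.loc[v].to_numpy(dtype=float)
        freq = np.nanmean(dosage) / 2.0
        if min(freq, 1 - freq) > maf_min and not np.allclose(dosage, dosage[0]):
            kept.append(v)
    return kept


def two_stage_scan(
    bundle: DataBundle,
    cis_window: int = 100_000,
    maf_min: float = 0.05,
    discovery_fdr: float = 0.20,
    n_starts: int = 1,
) -> tuple[PairList, CorrectedResults]:
    """Association scan over cis variants, FDR-thresholded to nominate pairs for
    the interaction test.

    Variants within ``cis_window`` bp flanking the gene body and with
    MAF > ``maf_min`` are tested for a persistent effect; pairs passing the
    discovery FDR are returned for stage two.
    """
    if bundle.gene_coords is None or bundle.variant_coords is None:
        raise ValueError("two_stage_scan needs gene and variant coordinates")
    Sigma, RSigma = bundle.model_terms()
    n = bundle.cell_map.n_cells
    X0 = FixedDesign(np.ones((n, 1)), ["intercept"])
    rows = []
    for gene_id in bundle.expression.index:
        if gene_id not in bundle.gene_coords.index:
            log.info("gene %s has no coordinates; skipped", gene_id)
            continue
        variants = _cis_variants(bundle, gene_id, cis_window, maf_min)
        if not variants:
            log.info("gene %s: no cis variants in window; skipped", gene_id)
            continue
        y = bundle.phenotype(gene_id)
        null_fit = None
        for variant_id in variants:
            g = bundle.genotype_cells(variant_id)
            res = association_lrt(
                y, g, X0, Sigma, RSigma,
                mode="fast", null_fit=null_fit,
                gene_id=str(gene_id), variant_id=str(variant_id),
                n_starts=n_starts,
            )
            null_fit = res.fit  # variance components shared across cis variants
            rows.append(
                {
                    "gene_id": gene_id,
                    "variant_id": variant_id,
                    "beta_G": res.beta_G,
                    "pvalue": res.pvalue,
                }
            )
    results = pd.DataFrame(rows, columns=["gene_id", "variant_id", "beta_G", "pvalue"])
    corrected = correct_multiple_testing(results, fdr=discovery_fdr)
    sig_genes = set(corrected.per_gene.loc[corrected.per_gene["significant"], "gene_id"])
    nominated = results[results["gene_id"].isin(sig_genes)]
    if len(nominated) and discovery_fdr > 0:
        # forward each significant gene's best variant plus any variant passing
        # the gene-level threshold on its own
        keep = nominated.loc[nominated.groupby("gene_id")["pvalue"].idxmin()]
    else:
        keep = nominated.iloc[:0]
    pairs = PairList(keep[["gene_id", "variant_id"]].reset_index(drop=True))
    return pairs, corrected


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with spline-smoothed pi0 over a lambda grid."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_at = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = interpolate.UnivariateSpline(lambdas, pi0_at, k=3)
    pi0 = float(np.clip(spline(lambdas[-1]), 1.0 / m, 1.0))
    q = bh_qvalues(p) * pi0
    return np.minimum(q, 1.0), pi0


def correct_multiple_testing(
    results: pd.DataFrame, fdr: float = 0.05, method: str = "storey"
) -> CorrectedResults:
    """Gene-level Bonferroni over variants, then across-gene FDR control.

    Per gene: ``p_gene = min(1, min_j p_j * m_gene)``.  Across genes: Storey
    q-values (spline pi0; needs >= 100 genes, otherwise falls back to
    Benjamini-Hochberg with a warning) or BH directly.
    """
    if method not in ("storey", "bh"):
        raise ValueError("method must be 'storey' or 'bh'")
    if not len(results):
        empty = pd.DataFrame(columns=["gene_id", "p_gene", "qvalue", "significant"])
        return CorrectedResults(results, empty, fdr=fdr, method=method)
    grouped = results.groupby("gene_id")["pvalue"]
    p_gene = (grouped.min() * grouped.size()).clip(upper=1.0)
    genes = p_gene.index.to_numpy()
    pvec = p_gene.to_numpy()
    pi0 = None
    if method == "storey" and len(genes) < 100:
        warnings.warn(
            f"only {len(genes)} genes: Storey pi0 estimation unreliable, "
            "falling back to Benjamini-Hochberg",
            stacklevel=2,
        )
        method = "bh"
    if method == "storey":
        q, pi0 = storey_qvalues(pvec)
    else:
        q = bh_qvalues(pvec)
    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "p_gene": pvec,
            "qvalue": q,
            "significant": q <= fdr,
        }
    )
    return CorrectedResults(results, per_gene, fdr=fdr, method=method, pi0=pi0)


def pseudobulk_confirmation(
    counts: pd.DataFrame,
    cell_sets: dict[str, np.ndarray],
    g_donor: np.ndarray,
    cell_map: CellDonorMap,
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Conventional donor-level eQTL regression within stratified cell sets.

    For each named cell set (e.g. top/bottom effect quantiles) the mean
    expression per donor is regressed on donor dosage; returns slope, SE and
    p-value per set.  Donors without cells in a set are dropped from that
    regression (logged).
    """
    if gene_id is None:
        gene_id = counts.index[0]
    expr = counts.loc[gene_id].to_numpy(dtype=float)
    g_donor = np.asarray(g_donor, dtype=float)
    rows = []
    for name, cells in cell_sets.items():
        cells = np.asarray(cells, dtype=int)
        donors = cell_map.assignment[cells]
        means, dosages = [], []
        for d in range(cell_map.n_donors):
            mask = donors == d
            if not mask.any():
                log.info("cell set %s: donor %d has no cells; dropped", name, d)
                continue
            means.append(expr[cells[mask]].mean())
            dosages.append(g_donor[d])
        means = np.asarray(means)
        dosages = np.asarray(dosages)
        if np.allclose(dosages, dosages[0]):
            raise ValueError(f"cell set {name}: dosage constant across retained donors")
        fit = stats.linregress(dosages, means)
        rows.append(
            {
                "cell_set": name,
                "n_donors": means.size,
                "slope": fit.slope,
                "stderr": fit.stderr,
                "pvalue": fit.pvalue,
            }
        )
    return pd.DataFrame(rows)
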