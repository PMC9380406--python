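"""Transform raw inputs into the representations the mixed-model tests consume.

Expression vectors are rank-inverse-normal transformed, context factor
matrices are standardized column-wise, donor-level genotype dosages are
expanded to cells, and (optionally) raw counts are aggregated into
pseudocells given externally computed cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionVector",
    "GenotypeVector",
    "ContextMatrix",
    "CellDonorMap",
    "DegenerateInputError",
    "gaussianize",
    "standardize_contexts",
    "one_hot_contexts",
    "expand_genotype",
    "aggregate_pseudocells",
]


class DegenerateInputError(ValueError):
    """Raised when an input is constant / rank-deficient in a way the model cannot use."""


@dataclass
class ExpressionVector:
    """Per-gene expression across N cells.

    ``state`` tracks what has been done to the values: ``raw_counts``,
    ``log_normalized`` or ``gaussianized``.
    """

    values: np.ndarray
    state: str = "raw_counts"
    gene_id: str = "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("expression values must be a 1-D vector")
        if self.state not in ("raw_counts", "log_normalized", "gaussianized"):
            raise ValueError(f"unknown expression state {self.state!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class GenotypeVector:
    """Dosage genotype for one variant: donor-level values plus the cell-level expansion."""

    donor_dosages: np.ndarray
    expanded: np.ndarray | None = None
    variant_id: str = "variant"
    maf: float | None = None

    def __post_init__(self) -> None:
        self.donor_dosages = np.asarray(self.donor_dosages, dtype=float)
        valid = self.donor_dosages[~np.isnan(self.donor_dosages)]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.maf is None and valid.size:
            freq = float(valid.mean()) / 2.0
            self.maf = min(freq, 1.0 - freq)


@dataclass
class ContextMatrix:
    """N x k matrix of cellular-context factors; ``Sigma = values @ values.T`` once standardized."""

    values: np.ndarray
    standardized: bool = False
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.labels:
            self.labels = [f"context_{j}" for j in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("labels do not match number of context columns")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_contexts(self) -> int:
        return self.values.shape[1]


@dataclass
class CellDonorMap:
    """Assignment of each cell to exactly one donor."""

    assignment: np.ndarray  # donor index per cell

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a 1-D vector of donor indices")
        if self.assignment.size and self.assignment.min() < 0:
            raise ValueError("donor indices must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_donors(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    @property
    def indicator(self) -> np.ndarray:
        """N x d 0/1 matrix with exactly one 1 per row."""
        Z = np.zeros((self.n_cells, self.n_donors))
        Z[np.arange(self.n_cells), self.assignment] = 1.0
        return Z

    def subset(self, mask: np.ndarray) -> "CellDonorMap":
        """Restrict to the cells where ``mask`` is True, relabeling donors compactly."""
        kept = self.assignment[mask]
        _, relabeled = np.unique(kept, return_inverse=True)
        return CellDonorMap(relabeled)


def gaussianize(y: ExpressionVector) -> ExpressionVector:
    """Rank-based inverse-normal transform of an expression vector.

    Each value is mapped to ``Phi^{-1}((rank - 0.5) / N)`` with ties assigned
    their average rank, then re-centered and re-scaled so the output has
    empirical mean 0 and variance 1 exactly.
    """
    if y.state == "gaussianized":
        raise ValueError("vector is already gaussianized")
    v = y.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 cells to gaussianize")
    if np.ptp(v) == 0.0:
        raise DegenerateInputError(
            f"expression for {y.gene_id} is constant; cannot rank-transform"
        )
    ranks = stats.rankdata(v, method="average")
    transformed = stats.norm.ppf((ranks - 0.5) / v.shape[0])
    transformed = transformed - transformed.mean()
    transformed = transformed / transformed.std()
    return replace(y, values=transformed, state="gaussianized")


def standardize_contexts(C: ContextMatrix) -> ContextMatrix:
    """Center and scale every context column to mean 0 and (population) SD 1."""
    V = C.values
    sd = V.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(C.labels[j] for j in bad)
        raise DegenerateInputError(f"constant context column(s): {names}")
    return ContextMatrix((V - V.mean(axis=0)) / sd, standardized=True, labels=list(C.labels))


def one_hot_contexts(labels, standardize: bool = True) -> ContextMatrix:
    """Encode discrete per-cell categories as 0/1 context columns.

    By default the columns are subsequently standardized, matching the
    treatment of continuous contexts; pass ``standardize=False`` to keep the
    raw indicator matrix (whose ``C @ C.T`` is block-diagonal of ones).
    """
    labels = pd.Series(list(labels))
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise DegenerateInputError(
            "one-hot contexts need at least 2 distinct labels; a single level is "
            "confounded with the intercept"
        )
    V = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        V[:, j] = (labels == lev).to_numpy(dtype=float)
    C = ContextMatrix(V, standardized=False, labels=[str(lev) for lev in levels])
    return standardize_contexts(C) if standardize else C


def expand_genotype(
    g_donor: GenotypeVector,
    cell_map: CellDonorMap,
    missing: str = "error",
) -> tuple[GenotypeVector, np.ndarray]:
    """Expand donor dosages to cells via the cell->donor assignment.

    Returns the expanded genotype and a boolean keep-mask over cells.  The
    mask is all-True unless donors have missing (NaN) dosages and
    ``missing="drop"``, in which case their cells are flagged for removal
    (the caller must subset y, C and the map with the same mask).
    ``missing="mean"`` imputes the mean dosage instead.
    """
    dosages = np.asarray(g_donor.donor_dosages, dtype=float)
    if cell_map.n_donors > dosages.shape[0]:
        raise ValueError(
            f"cell map references donor index {cell_map.n_donors - 1} but only "
            f"{dosages.shape[0]} dosages were provided"
        )
    missing_donors = np.isnan(dosages)
    keep = np.ones(cell_map.n_cells, dtype=bool)
    if missing_donors.any():
        if missing == "error":
            raise ValueError(
                f"variant {g_donor.variant_id}: {int(missing_donors.sum())} donor(s) "
                "have missing dosage (use missing='drop' or 'mean')"
            )
        if missing == "drop":
            keep = ~missing_donors[cell_map.assignment]
        elif missing == "mean":
            dosages = dosages.copy()
            dosages[missing_donors] = np.nanmean(dosages)
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    expanded = dosages[cell_map.assignment]
    expanded = expanded[keep]
    return (
        GenotypeVector(
            donor_dosages=g_donor.donor_dosages,
            expanded=expanded,
            variant_id=g_donor.variant_id,
            maf=g_donor.maf,
        ),
        keep,
    )


def aggregate_pseudocells(
    counts: pd.DataFrame,
    cluster_labels,
    cell_map: CellDonorMap,
) -> tuple[pd.DataFrame, CellDonorMap, pd.DataFrame]:
    """Sum raw counts within precomputed cell clusters ("pseudocells").

    ``counts`` is genes x cells.  Clusters must be nested within donors; a
    cluster spanning two donors breaks the repeat-structure expansion and is
    rejected.  Returns the genes x pseudocells count matrix, the
    pseudocell->donor map and a cluster size table.
    """
    labels = pd.Series(list(cluster_labels))
    if len(labels) != counts.shape[1]:
        raise ValueError("cluster labels do not match the number of cells")
    donors = pd.Series(cell_map.assignment)
    spans = labels.groupby(labels).apply(lambda idx: donors[idx.index].nunique())
    offenders = spans[spans > 1]
    if len(offenders):
        raise ValueError(
            f"cluster(s) spanning multiple donors: {list(offenders.index)[:5]}"
        )
    order = sorted(labels.unique())
    agg = np.zeros((counts.shape[0], len(order)))
    pc_donor = np.zeros(len(order), dtype=int)
    sizes = []
    mat = counts.to_numpy()
    for j, cl in enumerate(order):
        members = np.flatnonzero((labels == cl).to_numpy())
        agg[:, j] = mat[:, members].sum(axis=1)
        pc_donor[j] = cell_map.assignment[members[0]]
        sizes.append((cl, len(members)))
    pseudo = pd.DataFrame(agg, index=counts.index, columns=[str(c) for c in order])
    size_table = pd.DataFrame(sizes, columns=["cluster", "n_cells"])
    _, relabeled = np.unique(pc_donor, return_inverse=True)
    return pseudo, CellDonorMap(relabeled), size_table
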