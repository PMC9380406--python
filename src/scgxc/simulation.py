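"""Synthetic data generation and calibration/power experiment runners.

Counts are drawn from a Poisson with log-link mean combining a structured
background expression vector, a persistent genetic effect and per-context
interaction effects.  The background carries donor intercepts, shared
context effects and donor-specific context slopes, emulating the repeat
structure of real single-cell data that the relatedness x context covariance
term exists to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from scgxc.covariance import (
    LowRankCovariance,
    context_covariance,
    gxc_covariance,
    relatedness_context_covariance,
)
from scgxc.effects import estimate_effects
from scgxc.inference import (
    association_lrt,
    interaction_score_test,
    interaction_test_no_relatedness,
    multi_env_lrt,
    single_env_lrt,
)
from scgxc.null_model import FixedDesign, fit_variance_components
from scgxc.preprocessing import (
    CellDonorMap,
    ContextMatrix,
    ExpressionVector,
    gaussianize,
    standardize_contexts,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_contexts",
    "simulate_base_expression",
    "simulate_counts",
    "simulate_dataset",
    "simulate_gaussian",
    "analyse_pair",
    "run_calibration",
    "run_power",
    "qq_data",
]

_LAMBDA_MAX = 1e8


@dataclass
class SimulationConfig:
    """Parameters of the semi-synthetic count generator and experiment runners."""

    n_donors: int = 50
    cells_per_donor: int = 100
    n_pairs: int = 500
    k_simulated: int = 10          # contexts carrying GxC effects
    k_tested: int = 10             # contexts used by the tests
    sigma2_G: float = 0.025        # total genetic variance
    rho_gxc: float = 0.0           # fraction of genetic variance from GxC
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    base_log_mean: float = float(np.log(10.0))
    donor_sd: float = 0.3          # donor intercepts in the background
    context_sd: float = 0.2        # shared context effects in the background
    donor_context_sd: float = 0.15  # donor-specific context slopes
    standardize_genotype: bool = True
    literal_variance_split: bool = False  # per-context var sigma2_G*rho (no /k_active)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_gxc <= 1.0:
            raise ValueError("rho_gxc must be in [0, 1]")
        if self.sigma2_G < 0:
            raise ValueError("sigma2_G must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.n_donors * self.cells_per_donor

    @property
    def n_contexts(self) -> int:
        return max(self.k_simulated, self.k_tested)


@dataclass
class SimulatedDataset:
    """One simulated gene-variant pair with its generative truth record."""

    counts: np.ndarray
    donor_dosages: np.ndarray
    g_cells: np.ndarray            # (standardized) genotype expanded to cells
    contexts: ContextMatrix
    cell_map: CellDonorMap
    truth: dict = field(default_factory=dict)

    def recompute_lambda(self) -> np.ndarray:
        """Rebuild the Poisson rate exactly from the truth record."""
        t = self.truth
        eta = t["y_base"] + self.g_cells * t["beta_G"]
        C = self.contexts.values
        for j, b in zip(t["active_contexts"], t["beta_gxc"]):
            eta = eta + self.g_cells * C[:, j] * b
        return np.exp(eta)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator, n_variants: int = 1
) -> np.ndarray:
    """Donor dosages: MAF ~ Uniform(maf_range), dosage ~ Binomial(2, MAF).

    Monomorphic draws (all donors identical) are rejected and resampled so
    the tests never see an unestimable genotype.
    """
    out = np.empty((n_variants, config.n_donors))
    for v in range(n_variants):
        while True:
            maf = rng.uniform(*config.maf_range)
            dosage = rng.binomial(2, maf, size=config.n_donors).astype(float)
            if not np.allclose(dosage, dosage[0]):
                out[v] = dosage
                break
    return out[0] if n_variants == 1 else out


def simulate_contexts(
    rng: np.random.Generator, n_cells: int, k: int
) -> ContextMatrix:
    """Independent standard-normal context factors, standardized column-wise."""
    return standardize_contexts(ContextMatrix(rng.standard_normal((n_cells, k))))


def simulate_base_expression(
    config: SimulationConfig,
    rng: np.random.Generator,
    C: ContextMatrix,
    cell_map: CellDonorMap,
) -> np.ndarray:
    """Structured background log-expression: donor intercepts + context effects
    + donor-specific context slopes."""
    d = cell_map.n_donors
    k = C.n_contexts
    a = rng.normal(0.0, config.donor_sd, size=d)
    w = rng.normal(0.0, config.context_sd, size=k)
    v = rng.normal(0.0, config.donor_context_sd, size=(d, k))
    V = C.values
    idx = cell_map.assignment
    return (
        config.base_log_mean
        + a[idx]
        + V @ w
        + np.sum(V * v[idx], axis=1)
    )


def simulate_counts(
    config: SimulationConfig,
    y_base: np.ndarray,
    g_cells: np.ndarray,
    C: ContextMatrix,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Poisson counts with log-link mean combining background and genetic terms.

    Per-context interaction effects are drawn with variance
    ``sigma2_G * rho / k_active`` (equal split across active contexts, so the
    total interaction variance honors rho); set
    ``config.literal_variance_split`` for variance ``sigma2_G * rho`` per
    context instead.  The persistent effect has variance
    ``sigma2_G * (1 - rho)``; at rho = 1 it is exactly 0.
    """
    rho = config.rho_gxc
    k_active = min(config.k_simulated, C.n_contexts)
    active = list(range(k_active))
    var_per_ctx = config.sigma2_G * rho
    if not config.literal_variance_split and k_active > 0:
        var_per_ctx /= k_active
    beta_gxc = (
        rng.normal(0.0, np.sqrt(var_per_ctx), size=k_active)
        if var_per_ctx > 0
        else np.zeros(k_active)
    )
    var_g = config.sigma2_G * (1.0 - rho)
    beta_G = float(rng.normal(0.0, np.sqrt(var_g))) if var_g > 0 else 0.0
    eta = y_base + g_cells * beta_G
    V = C.values
    for j, b in zip(active, beta_gxc):
        eta = eta + g_cells * V[:, j] * b
    lam = np.exp(eta)
    if lam.max() > _LAMBDA_MAX:
        raise OverflowError(
            f"Poisson rate exceeds {_LAMBDA_MAX:.0e}; reduce effect sizes or the base mean"
        )
    counts = rng.poisson(lam).astype(float)
    truth = {
        "beta_G": beta_G,
        "beta_gxc": beta_gxc,
        "active_contexts": active,
        "y_base": y_base,
        "lambda": lam,
    }
    return counts, truth


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    with_genetics: bool = True,
) -> SimulatedDataset:
    """Generate one complete gene-variant pair (map, contexts, genotype, counts)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cell_map = CellDonorMap(np.repeat(np.arange(config.n_donors), config.cells_per_donor))
    C = simulate_contexts(rng, config.n_cells, config.n_contexts)
    dosage = simulate_genotypes(config, rng)
    if config.standardize_genotype:
        g_donor = (dosage - dosage.mean()) / dosage.std()
    else:
        g_donor = dosage
    g_cells = g_donor[cell_map.assignment]
    y_base = simulate_base_expression(config, rng, C, cell_map)
    if with_genetics and config.sigma2_G > 0:
        counts, truth = simulate_counts(config, y_base, g_cells, C, rng)
    else:
        lam = np.exp(y_base)
        counts = rng.poisson(lam).astype(float)
        truth = {
            "beta_G": 0.0,
            "beta_gxc": np.zeros(0),
            "active_contexts": [],
            "y_base": y_base,
            "lambda": lam,
        }
    return SimulatedDataset(
        counts=counts,
        donor_dosages=dosage,
        g_cells=g_cells,
        contexts=C,
        cell_map=cell_map,
        truth=truth,
    )


def simulate_gaussian(
    rng: np.random.Generator,
    X: np.ndarray,
    beta: np.ndarray,
    RSigma: LowRankCovariance,
    Sigma: LowRankCovariance,
    variances: tuple[float, float, float],
) -> np.ndarray:
    """Draw y from the Gaussian mixed model itself (for parameter-recovery checks)."""
    v_rc, v_c, v_n = variances
    n = X.shape[0]
    y = X @ beta
    if v_rc > 0:
        y = y + np.sqrt(v_rc) * (RSigma.factor @ rng.standard_normal(RSigma.rank))
    if v_c > 0:
        y = y + np.sqrt(v_c) * (Sigma.factor @ rng.standard_normal(Sigma.rank))
    return y + np.sqrt(v_n) * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# experiment runners


def analyse_pair(
    ds: SimulatedDataset,
    tests: tuple[str, ...] = ("interaction",),
    k_tested: int | None = None,
    n_starts: int = 1,
) -> dict[str, float]:
    """Run the named tests on one simulated dataset; returns test -> p-value.

    Recognized test names: ``interaction``, ``association``, ``single_env``,
    ``multi_env``, ``no_relatedness``.  The interaction, single-env and
    multi-env tests share one null fit.
    """
    y = gaussianize(ExpressionVector(ds.counts)).values
    k = k_tested if k_tested is not None else ds.contexts.n_contexts
    C = ContextMatrix(ds.contexts.values[:, :k], standardized=True)
    Sigma = context_covariance(C)
    RSigma = relatedness_context_covariance(ds.cell_map, C)
    g = ds.g_cells
    X1 = FixedDesign(
        np.column_stack([np.ones_like(g), g]), ["intercept", "genotype"]
    )
    out: dict[str, float] = {}
    shared_fit = None
    if {"interaction", "single_env", "multi_env"} & set(tests):
        shared_fit = fit_variance_components(
            y, X1, [RSigma, Sigma], method="reml", n_starts=n_starts
        )
    for name in tests:
        if name == "interaction":
            out[name] = interaction_score_test(
                y, g, X1, Sigma, RSigma, fit=shared_fit
            ).pvalue
        elif name == "association":
            X0 = FixedDesign(np.ones((g.shape[0], 1)), ["intercept"])
            out[name] = association_lrt(
                y, g, X0, Sigma, RSigma, mode="fast", n_starts=n_starts
            ).pvalue
        elif name == "single_env":
            out[name] = single_env_lrt(y, g, X1, C, Sigma, RSigma, fit=shared_fit)
        elif name == "multi_env":
            out[name] = multi_env_lrt(y, g, X1, C, Sigma, RSigma, fit=shared_fit)
        elif name == "no_relatedness":
            out[name] = interaction_test_no_relatedness(
                y, g, X1, Sigma, n_starts=n_starts
            ).pvalue
        else:
            raise ValueError(f"unknown test {name!r}")
    return out


def run_calibration(
    config: SimulationConfig,
    tests: tuple[str, ...] = ("interaction",),
    regime: str = "no_genetic",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_pairs`` null datasets and collect p-values per test.

    ``regime="no_genetic"`` simulates without any genetic effect;
    ``regime="persistent"`` simulates a persistent effect only
    (rho_gxc = 0, sigma2_G as configured).  Returns the p-value table and a
    summary with the KS statistic against Uniform(0, 1) and empirical type-I
    error at alpha = 0.05 and 0.01.
    """
    if regime not in ("no_genetic", "persistent"):
        raise ValueError("regime must be 'no_genetic' or 'persistent'")
    rng = np.random.default_rng(config.seed)
    rows = []
    for _ in range(config.n_pairs):
        if regime == "no_genetic":
            ds = simulate_dataset(config, rng, with_genetics=False)
        else:
            cfg = SimulationConfig(**{**config.__dict__, "rho_gxc": 0.0})
            ds = simulate_dataset(cfg, rng, with_genetics=True)
        rows.append(analyse_pair(ds, tests, k_tested=config.k_tested))
    pvals = pd.DataFrame(rows)
    summaries = []
    for name in pvals.columns:
        p = pvals[name].to_numpy()
        ks = stats.kstest(p, "uniform")
        summaries.append(
            {
                "test": name,
                "n": len(p),
                "ks_stat": ks.statistic,
                "ks_pvalue": ks.pvalue,
                "type1_at_0.05": float((p < 0.05).mean()),
                "type1_at_0.01": float((p < 0.01).mean()),
            }
        )
    return pvals, pd.DataFrame(summaries)


def qq_data(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p-values for QQ plotting."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected_neglog10": -np.log10(expected), "observed_neglog10": -np.log10(p)}
    )


def run_power(
    config: SimulationConfig,
    tests: tuple[str, ...],
    grid: list[dict] | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Empirical power over a parameter grid.

    Each grid entry is a dict of SimulationConfig overrides (e.g.
    ``{"rho_gxc": 0.5}`` or ``{"k_simulated": 5, "k_tested": 20}``); when no
    grid is given, the rho grid of the reference power experiment is used.
    Returns one row per (grid point, test) with power and its binomial SE.
    """
    if grid is None:
        grid = [{"rho_gxc": r} for r in (0.0, 0.25, 0.5, 0.75, 1.0)]
    rows = []
    for point in grid:
        cfg = SimulationConfig(**{**config.__dict__, **point})
        rng = np.random.default_rng(cfg.seed)
        pvals = []
        for _ in range(cfg.n_pairs):
            ds = simulate_dataset(cfg, rng, with_genetics=True)
            pvals.append(analyse_pair(ds, tests, k_tested=cfg.k_tested))
        pvals = pd.DataFrame(pvals)
        for name in pvals.columns:
            hits = (pvals[name].to_numpy() < alpha).mean()
            se = np.sqrt(hits * (1 - hits) / len(pvals)) if len(pvals) else np.nan
            rows.append({**point, "test": name, "power": float(hits), "se": float(se), "n": len(pvals)})
    return pd.DataFrame(rows)
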