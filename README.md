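# scgxc

Genotype-by-context (GxC) interaction eQTL testing for single-cell
expression, built on a linear mixed model with low-rank covariance algebra.

Per-cell expression of a gene is modeled as

```
y = X b + u + c + e
```

with a persistent genetic effect (genotype column of `X`), an additive
cellular-context effect `c ~ N(0, v_C * Sigma)` where `Sigma = C C'` is built
from standardized per-cell context factors (e.g. latent factors or principal
components), a donor-repeat term `u ~ N(0, v_RC * R (*) Sigma)` (Hadamard
product of the cell-expanded donor relatedness with the context covariance —
the term that keeps the test calibrated when many cells come from each
donor), and iid noise. On top of this background the package provides:

- **Interaction score test** (`scgxc.inference.interaction_score_test`):
  a variance-component score test of the cell-specific genetic effect with
  covariance `diag(g) Sigma diag(g)`; the null distribution is a weighted
  chi-square mixture whose weights come from a k x k eigenproblem, with exact
  tail probabilities (Ruben series) and a flagged Liu fallback.
- **Association test** (`scgxc.inference.association_lrt`): 1-df LRT of the
  persistent effect, with a fast GLS mode for discovery scans.
- **Comparators**: per-context fixed-effect LRT (Bonferroni-combined), joint
  multi-context LRT, and a no-relatedness variant of the score test — all
  for benchmarking.
- **Per-cell effects** (`scgxc.effects.estimate_effects`): posterior (BLUP)
  estimates of per-cell allelic effects, opposite-effect flagging, and
  top/bottom quantile cell stratification.
- **Simulation** (`scgxc.simulation`): Poisson count generator with log-link
  mean combining a structured background, persistent and per-context
  interaction effects; calibration and power experiment runners.
- **Workflow** (`scgxc.workflow`): two-stage discovery (association scan at
  lenient FDR, then interaction testing), gene-level Bonferroni plus
  across-gene Storey/BH FDR, and pseudobulk confirmation of stratified cell
  sets.

All covariance terms are kept in factored form (`scale * W W'` + diagonal
noise); solves and log-determinants use the Woodbury identity, so fitting and
testing cost O(N) in the number of cells at fixed rank (rank = donors x
contexts for the repeat term).

## CLI

```sh
scgxc simulate --out-prefix sim --n-donors 20 --cells-per-donor 50 --rho-gxc 0.5
scgxc interaction --expression sim.counts.tsv --contexts sim.contexts.tsv \
    --donor-map sim.donor_map.tsv --dosages sim.dosages.tsv \
    --pairs pairs.tsv --out results.tsv
scgxc association ... --mode fast
scgxc estimate-effects ... --out effects.tsv
scgxc scan --gene-bed genes.bed --variant-pos variants.tsv ...   # two-stage
scgxc benchmark --mode calibration --tests interaction,no_relatedness --out calib.tsv
scgxc correct --results results.tsv --method storey --fdr 0.05 --out qvalues.tsv
```

Inputs are plain TSV (expression genes x cells, dosages variants x donors
with `NA` allowed, contexts cells x factors, donor map `cell_id/donor_id`,
optional symmetric donor kinship); MatrixMarket expression and minimal VCF
genotypes are also supported. Cell identifiers must match exactly across
files. Exit codes: 0 success, 2 input error, 3 numerical failure.

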