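import numpy as np
import pandas as pd
import pytest

from scgxc.preprocessing import CellDonorMap, ContextMatrix, standardize_contexts
from scgxc.simulation import (
    SimulationConfig,
    simulate_base_expression,
    simulate_contexts,
    simulate_counts,
    simulate_genotypes,
)
from scgxc.workflow import (
    DataBundle,
    PairList,
    bh_qvalues,
    correct_multiple_testing,
    pseudobulk_confirmation,
    storey_qvalues,
    two_stage_scan,
)


class TestMultipleTesting:
    def test_gene_bonferroni(self):
        results = pd.DataFrame(
            {"gene_id": ["g1", "g1"], "variant_id": ["v1", "v2"], "pvalue": [0.01, 0.5]}
        )
        corrected = correct_multiple_testing(results, method="bh")
        assert abs(corrected.per_gene["p_gene"].iloc[0] - 0.02) < 1e-12

    def test_all_ones_no_discoveries(self):
        results = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(20)],
             "variant_id": ["v"] * 20, "pvalue": [1.0] * 20}
        )
        corrected = correct_multiple_testing(results, method="bh")
        assert not corrected.per_gene["significant"].any()

    def test_bh_matches_textbook_fixture(self):
        # hand-checked 5-gene BH: sorted p (.01,.02,.03,.04,.05), m=5
        p = np.array([0.03, 0.01, 0.05, 0.02, 0.04])
        q = bh_qvalues(p)
        expected = np.array([0.05, 0.05, 0.05, 0.05, 0.05])
        np.testing.assert_allclose(q, expected, rtol=1e-12)
        p2 = np.array([0.001, 0.2, 0.9])
        np.testing.assert_allclose(bh_qvalues(p2), [0.003, 0.3, 0.9], rtol=1e-12)

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(0)
        results = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(200)],
             "variant_id": ["v"] * 200,
             "pvalue": rng.uniform(size=200)}
        )
        corrected = correct_multiple_testing(results, method="storey")
        per_gene = corrected.per_gene.sort_values("p_gene")
        assert (np.diff(per_gene["qvalue"]) >= -1e-12).all()
        assert ((per_gene["qvalue"] > 0) & (per_gene["qvalue"] <= 1)).all()

    def test_storey_bh_agree_on_uniform(self):
        # uniform p over 1000 genes: discovery counts agree within 10%
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(size=900), rng.uniform(0, 1e-4, size=100)])
        results = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(1000)],
             "variant_id": ["v"] * 1000, "pvalue": p}
        )
        st = correct_multiple_testing(results, method="storey", fdr=0.05)
        bh = correct_multiple_testing(results, method="bh", fdr=0.05)
        n_st = st.per_gene["significant"].sum()
        n_bh = bh.per_gene["significant"].sum()
        assert n_st >= n_bh  # pi0 <= 1 makes Storey at least as liberal
        assert abs(n_st - n_bh) <= 0.1 * max(n_bh, 1) + 2

    def test_small_m_falls_back_to_bh(self):
        results = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)],
             "variant_id": ["v"] * 10,
             "pvalue": np.linspace(0.01, 0.9, 10)}
        )
        with pytest.warns(UserWarning, match="falling back"):
            corrected = correct_multiple_testing(results, method="storey")
        assert corrected.method == "bh"

    def test_storey_pi0_reasonable(self):
        rng = np.random.default_rng(2)
        q, pi0 = storey_qvalues(rng.uniform(size=5000))
        assert 0.8 < pi0 <= 1.0

    def test_empty_results(self):
        corrected = correct_multiple_testing(pd.DataFrame(columns=["gene_id", "pvalue"]))
        assert len(corrected.per_gene) == 0


class TestPairList:
    def test_duplicates_rejected(self):
        df = pd.DataFrame({"gene_id": ["g", "g"], "variant_id": ["v", "v"]})
        with pytest.raises(ValueError):
            PairList(df)


def _make_scan_bundle(seed=0, n_true=10, n_null=100):
    """Bundle of genes with one cis variant each; the first n_true carry a
    strong persistent effect."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        n_donors=20, cells_per_donor=25, k_simulated=3, k_tested=3,
        sigma2_G=0.3, rho_gxc=0.0, seed=seed,
    )
    cmap = CellDonorMap(np.repeat(np.arange(cfg.n_donors), cfg.cells_per_donor))
    C = simulate_contexts(rng, cfg.n_cells, 3)
    genes, dosages, gene_rows, var_rows = [], [], [], []
    expr = {}
    for i in range(n_true + n_null):
        gene = f"gene_{i}"
        variant = f"var_{i}"
        dosage = simulate_genotypes(cfg, rng)
        g_std = (dosage - dosage.mean()) / dosage.std()
        y_base = simulate_base_expression(cfg, rng, C, cmap)
        if i < n_true:
            counts, _ = simulate_counts(cfg, y_base, g_std[cmap.assignment], C, rng)
        else:
            counts = rng.poisson(np.exp(y_base)).astype(float)
        expr[gene] = counts
        dosages.append(pd.Series(dosage, name=variant))
        gene_rows.append({"gene_id": gene, "chrom": f"chr{i}", "start": 1000, "end": 2000})
        var_rows.append({"variant_id": variant, "chrom": f"chr{i}", "pos": 1500})
        genes.append(gene)
    cells = [f"cell_{j}" for j in range(cfg.n_cells)]
    return DataBundle(
        expression=pd.DataFrame(expr, index=cells).T,
        dosages=pd.DataFrame(dosages),
        contexts=C,
        cell_map=cmap,
        gene_coords=pd.DataFrame(gene_rows).set_index("gene_id"),
        variant_coords=pd.DataFrame(var_rows).set_index("variant_id"),
    ), genes[:n_true]


class TestTwoStageScan:
    @pytest.fixture(scope="class")
    def scan_bundle(self):
        return _make_scan_bundle(seed=3)

    def test_recovers_true_effects(self, scan_bundle):
        bundle, true_genes = scan_bundle
        pairs, corrected = two_stage_scan(bundle, discovery_fdr=0.20)
        recovered = set(pairs.pairs["gene_id"]) & set(true_genes)
        assert len(recovered) >= 8

    def test_zero_fdr_empty(self, scan_bundle):
        bundle, _ = scan_bundle
        pairs, _ = two_stage_scan(bundle, discovery_fdr=0.0)
        assert len(pairs) == 0

    def test_at_most_one_pair_per_gene(self, scan_bundle):
        bundle, _ = scan_bundle
        pairs, _ = two_stage_scan(bundle, discovery_fdr=0.20)
        assert not pairs.pairs["gene_id"].duplicated().any()

    def test_window_excludes_far_variants(self, scan_bundle):
        bundle, _ = scan_bundle
        bundle2 = DataBundle(
            expression=bundle.expression, dosages=bundle.dosages,
            contexts=bundle.contexts, cell_map=bundle.cell_map,
            gene_coords=bundle.gene_coords,
            variant_coords=bundle.variant_coords.assign(
                pos=bundle.variant_coords["pos"] + 10**7
            ),
        )
        pairs, _ = two_stage_scan(bundle2)
        assert len(pairs) == 0


class TestPseudobulk:
    def _setup(self, flip=False, seed=0):
        rng = np.random.default_rng(seed)
        n_donors, cells_per = 30, 20
        cmap = CellDonorMap(np.repeat(np.arange(n_donors), cells_per))
        dosage = rng.binomial(2, 0.4, n_donors).astype(float)
        n = cmap.n_cells
        half = n // 2
        effect = np.where(np.arange(n) < half, 1.0, -1.0 if flip else 1.0)
        expr = 5.0 + effect * dosage[cmap.assignment] + rng.normal(0, 0.2, n)
        counts = pd.DataFrame([expr], index=["gene"])
        return counts, dosage, cmap, half, n

    def test_identical_sets_identical_slopes(self):
        counts, dosage, cmap, half, n = self._setup()
        cells = np.arange(0, n, 2)
        out = pseudobulk_confirmation(
            counts, {"a": cells, "b": cells.copy()}, dosage, cmap
        )
        assert out.loc[0, "slope"] == out.loc[1, "slope"]

    def test_opposite_effect_slopes(self):
        counts, dosage, cmap, half, n = self._setup(flip=True)
        out = pseudobulk_confirmation(
            counts,
            {"top": np.arange(half), "bottom": np.arange(half, n)},
            dosage, cmap,
        )
        slopes = dict(zip(out["cell_set"], out["slope"]))
        assert slopes["top"] > 0.5 and slopes["bottom"] < -0.5

    def test_absent_donor_dropped(self, caplog):
        counts, dosage, cmap, half, n = self._setup()
        cells = np.arange(0, 20)  # only donor 0
        cells_rest = np.arange(20, n)
        out = pseudobulk_confirmation(
            counts, {"partial": cells_rest}, dosage, cmap
        )
        assert out.loc[0, "n_donors"] == cmap.n_donors - 1
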