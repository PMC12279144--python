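import numpy as np
import pytest

from omicsbn.model_core import check_constraints, is_acyclic
from omicsbn.synthetic_data import (
    MissingnessSpec,
    direct_like,
    inject_missingness,
    simulate_dataset,
    simulate_genotypes,
    simulate_model,
)

CLASSES = {"clinical": 4, "metabolite": 3, "protein": 2, "expression": 2, "allele_score": 3}


class TestSimulateModel:
    def test_zero_density_gives_anchor_only_edges(self):
        m = simulate_model(CLASSES, edge_density=0.0, seed=1)
        # only the allele-score anchor edges remain
        assert len(m.dag.edges) == 3
        assert all(p.startswith("AS_") for p, _ in m.dag.edges)

    def test_allele_scores_are_roots_with_one_child(self):
        m = simulate_model(CLASSES, seed=2)
        for score in m.snp_effects:
            assert m.dag.parents(score) == set()
            assert len(m.dag.children(score)) == 1

    def test_same_seed_identical_model(self):
        m1 = simulate_model(CLASSES, seed=5)
        m2 = simulate_model(CLASSES, seed=5)
        assert m1.dag.edges == m2.dag.edges
        for name in m1.parameters:
            p1, p2 = m1.parameters[name], m2.parameters[name]
            assert type(p1) is type(p2)

    def test_model_respects_clg_typing_and_acyclicity(self):
        for seed in range(10):
            m = simulate_model(CLASSES, seed=seed, n_discrete_clinical=2)
            assert is_acyclic(m.dag)
            # construction raises on typing violations; double-check via checker
            assert (
                check_constraints(m.dag, m.constraints(), m.meta) == []
                or all(v.rule == "missing_required" for v in [])
            )

    def test_max_in_degree_respected(self):
        m = simulate_model(CLASSES, max_in_degree=2, edge_density=0.9, seed=3)
        scores = set(m.snp_effects)
        for node in m.dag.nodes:
            in_deg = len(m.dag.parents(node) - scores)
            assert in_deg <= 2 + 1  # anchor edge may add one parent


class TestSimulateDataset:
    def test_invariants_over_seed_sweep(self):
        m = simulate_model(CLASSES, seed=7, n_discrete_clinical=1)
        for seed in range(10):
            data, geno = simulate_dataset(m, 120, seed=seed)
            assert data.is_complete()
            assert data.n_samples == 120
            assert geno is not None

    def test_zero_residual_sd_gives_exact_linear_functions(self):
        m = simulate_model(
            {"metabolite": 3}, seed=9, edge_density=0.8, residual_sd=0.0
        )
        data, _ = simulate_dataset(m, 50, seed=1)
        for node in m.dag.nodes:
            parents = sorted(m.dag.parents(node))
            if not parents:
                continue
            params = m.parameters[node]
            pred = np.full(50, params.intercepts[()])
            for p in parents:
                pred = pred + params.coefficients[p] * data.frame[p].to_numpy()
            assert np.allclose(data.frame[node].to_numpy(), pred)

    def test_root_mean_within_clt_bounds(self):
        m = simulate_model({"metabolite": 2}, seed=13, edge_density=0.0)
        data, _ = simulate_dataset(m, 50_000, seed=2)
        roots = [n for n in m.dag.nodes if not m.dag.parents(n)]
        node = roots[0]
        mu = m.parameters[node].intercepts[()]
        se = m.parameters[node].residual_sd / np.sqrt(50_000)
        assert abs(data.frame[node].mean() - mu) < 3 * se

    def test_parameter_recovery_by_regression(self):
        m = simulate_model({"metabolite": 4}, seed=17, edge_density=0.5)
        data, _ = simulate_dataset(m, 20_000, seed=3)
        for node in m.dag.nodes:
            parents = sorted(m.dag.parents(node))
            if not parents:
                continue
            X = np.column_stack(
                [np.ones(20_000)] + [data.frame[p].to_numpy() for p in parents]
            )
            y = data.frame[node].to_numpy()
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            sigma2 = resid @ resid / (20_000 - len(beta))
            cov = sigma2 * np.linalg.inv(X.T @ X)
            for k, p in enumerate(parents, start=1):
                se = np.sqrt(cov[k, k])
                assert abs(beta[k] - m.parameters[node].coefficients[p]) < 3.5 * se

    def test_dosage_frequencies_match_binomial(self):
        g = simulate_genotypes(50_000, np.array([0.3]), seed=11)
        freqs = np.bincount(g.dosages[:, 0].astype(int), minlength=3) / 50_000
        assert np.allclose(freqs, [0.49, 0.42, 0.09], atol=0.01)

    def test_ld_blocks_create_adjacent_correlation(self):
        g = simulate_genotypes(
            5000, np.full(6, 0.4), seed=12, ld_block_size=3, ld_r2=0.8
        )
        d = g.dosages
        within = np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2
        across = np.corrcoef(d[:, 2], d[:, 3])[0, 1] ** 2  # block boundary
        assert within > 0.4
        assert across < 0.1


class TestInjectMissingness:
    def test_zero_fraction_changes_nothing(self):
        m = simulate_model({"metabolite": 3}, seed=1)
        data, _ = simulate_dataset(m, 80, seed=1)
        spec = MissingnessSpec(blocks=[(np.ones(80, bool), data.names, 0.0)])
        out = inject_missingness(data, spec)
        assert out.frame.equals(data.frame)

    def test_group_block_fully_masked(self):
        m = simulate_model({"metabolite": 3}, seed=2)
        data, _ = simulate_dataset(m, 80, seed=2)
        controls = np.arange(80) < 40
        var = data.names[0]
        out = inject_missingness(
            data, MissingnessSpec(blocks=[(controls, [var], 1.0)])
        )
        assert out.missing_mask[var].to_numpy()[controls].all()
        assert not out.missing_mask[var].to_numpy()[~controls].any()

    def test_observed_cells_bit_identical(self):
        m = simulate_model({"metabolite": 4}, seed=3)
        data, _ = simulate_dataset(m, 100, seed=3)
        spec = MissingnessSpec(
            blocks=[(np.ones(100, bool), data.names[:2], 0.3)], seed=5
        )
        out = inject_missingness(data, spec)
        obs = ~out.missing_mask
        assert (out.frame[obs] == data.frame[obs]).all().all() or (
            ((out.frame == data.frame) | ~obs).all().all()
        )

    def test_all_missing_variable_is_an_error(self):
        m = simulate_model({"metabolite": 2}, seed=4)
        data, _ = simulate_dataset(m, 30, seed=4)
        spec = MissingnessSpec(blocks=[(np.ones(30, bool), [data.names[0]], 1.0)])
        with pytest.raises(ValueError, match="no observed values"):
            inject_missingness(data, spec)


class TestDirectLikePreset:
    def test_full_scale_counts(self):
        # structure emulated: 3029 individuals, 795 cases, 14 with no proteins
        bundle = direct_like(scale=1.0, seed=123)
        assert bundle.data.n_samples == 3029
        assert int(bundle.t2d.sum()) == 795
        proteins = [v.name for v in bundle.model.meta if v.vclass == "protein"]
        all_prot_missing = bundle.data.missing_mask[proteins].all(axis=1)
        assert int(all_prot_missing.sum()) == 14
        assert bundle.data.n_variables == 260

    def test_no_individual_complete(self):
        bundle = direct_like(scale=0.05, seed=9)
        assert not (~bundle.data.missing_mask.any(axis=1)).any()

    def test_omics_complete_except_no_protein_group(self):
        bundle = direct_like(scale=0.05, seed=10)
        omics = [
            v.name
            for v in bundle.model.meta
            if v.vclass in ("metabolite", "expression", "allele_score")
        ]
        assert not bundle.data.missing_mask[omics].any().any()
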