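"""Network stage vs independent brute-force oracles, plus module recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from modfactor import (
    ExpressionMatrix,
    ModuleAssignment,
    NetworkParams,
    PhenotypeTable,
    ValidationError,
    adjacency_matrix,
    detect_modules,
    gene_trait_stats,
    lognormalize,
    module_eigengenes,
    module_trait_stats,
    pick_soft_threshold,
    scale_free_fit_index,
    tom_matrix,
)


def _tom_df(T):
    n = T.shape[0]
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(T, index=ids, columns=ids)


# --------------------------------------------------------------------- soft threshold

class TestSoftThreshold:
    def test_mean_connectivity_decreases_with_power(self, small_expr):
        _, table = pick_soft_threshold(small_expr, NetworkParams(fit_target=0.5))
        mean_k = table["mean_k"].to_numpy()
        assert (np.diff(mean_k) < 0).all()

    def test_lowest_power_reaching_target_is_selected(self, recovery_network):
        table = recovery_network["fit_table"]
        target = NetworkParams().fit_target
        reaching = table[table["fit_index"] >= target]
        assert len(reaching) > 0
        assert recovery_network["power"] == int(reaching["power"].iloc[0])

    def test_selection_matches_brute_force_rescan(self, recovery_network):
        """Recompute connectivity, binned fit, and the lowest-power rule from
        scratch with explicit loops on the same data."""
        logn = recovery_network["logn"]
        X = logn.values.to_numpy()
        C = np.abs(np.corrcoef(X))
        np.fill_diagonal(C, 0.0)
        target = NetworkParams().fit_target
        chosen = None
        best, best_fit = None, -np.inf
        for beta in range(1, 21):
            k = (C**beta).sum(axis=1)
            fit = scale_free_fit_index(k)
            if fit > best_fit:
                best, best_fit = beta, fit
            if fit >= target and chosen is None:
                chosen = beta
        assert recovery_network["power"] == (chosen if chosen is not None else best)

    def test_fit_index_positive_for_decaying_distribution(self):
        gen = np.random.default_rng(3)
        k = gen.pareto(2.0, size=400) + 0.1  # heavy-tailed, decaying density
        assert scale_free_fit_index(k) > 0.5


# --------------------------------------------------------------------- adjacency

class TestAdjacency:
    def test_perfect_anticorrelation_gives_unit_adjacency(self):
        x = np.linspace(0, 1, 8)
        df = pd.DataFrame([x, -x + 2], index=["g0", "g1"], columns=[f"s{j}" for j in range(8)])
        expr = ExpressionMatrix(df, scale="lognorm")
        adj = adjacency_matrix(expr, power=6)
        assert adj.loc["g0", "g1"] == pytest.approx(1.0, abs=1e-12)
        assert adj.loc["g0", "g0"] == 1.0

    def test_matches_loop_oracle(self, rng):
        vals = rng.normal(size=(5, 8))
        ids = [f"g{i}" for i in range(5)]
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=ids, columns=[f"s{j}" for j in range(8)]), scale="lognorm"
        )
        adj = adjacency_matrix(expr, power=6)
        for i in range(5):
            for j in range(5):
                if i == j:
                    expected = 1.0
                else:
                    r = np.corrcoef(vals[i], vals[j])[0, 1]
                    expected = abs(r) ** 6
                assert adj.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_is_reported(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"], columns=["a", "b", "c"]
        )
        with pytest.raises(ValidationError, match="flat"):
            adjacency_matrix(ExpressionMatrix(df, scale="lognorm"), power=6)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 12))
    def test_symmetry_range_and_diagonal(self, seed, power):
        gen = np.random.default_rng(seed)
        vals = gen.normal(size=(8, 10))
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(8)], columns=[f"s{j}" for j in range(10)]),
            scale="lognorm",
        )
        A = adjacency_matrix(expr, power=power).to_numpy()
        assert np.array_equal(A, A.T)
        assert A.min() >= 0.0 and A.max() <= 1.0
        assert (np.diag(A) == 1.0).all()


# --------------------------------------------------------------------- TOM

class TestTOM:
    def test_two_connected_one_isolated_hand_case(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.0
        T = tom_matrix(_tom_df(A)).to_numpy()
        assert T[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert T[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_complete_graph_has_unit_overlap(self):
        n = 4
        A = np.ones((n, n))
        T = tom_matrix(_tom_df(A)).to_numpy()
        assert np.allclose(T, 1.0, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        n = 10
        raw = rng.uniform(0, 1, size=(n, n))
        A = (raw + raw.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_matrix(_tom_df(A)).to_numpy()
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert T[i, j] == 1.0
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(A[i, u] for u in range(n) if u != i)
                k_j = sum(A[j, u] for u in range(n) if u != j)
                expected = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expected, abs=1e-12)

    def test_rejects_asymmetric_input(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            tom_matrix(A)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_range_and_diagonal(self, seed):
        gen = np.random.default_rng(seed)
        raw = gen.uniform(0, 1, size=(9, 9))
        A = (raw + raw.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_matrix(_tom_df(A)).to_numpy()
        assert np.allclose(T, T.T, atol=1e-12)
        assert T.min() >= 0.0 and T.max() <= 1.0
        assert (np.diag(T) == 1.0).all()


# --------------------------------------------------------------------- modules

class TestDetectModules:
    def test_perfect_blocks_are_recovered_exactly(self):
        sizes = [40, 35]
        n = sum(sizes)
        T = np.zeros((n, n))
        T[:40, :40] = 1.0
        T[40:, 40:] = 1.0
        np.fill_diagonal(T, 1.0)
        modules = detect_modules(_tom_df(T))
        counts = modules.gene_module.value_counts()
        assert "unassigned" not in counts
        assert sorted(counts.tolist(), reverse=True) == sizes
        assert counts["module_1"] == 40  # size-ranked labels

    def test_no_coexpression_leaves_all_unassigned(self):
        gen = np.random.default_rng(0)
        raw = gen.uniform(0, 0.01, size=(100, 100))
        T = (raw + raw.T) / 2
        np.fill_diagonal(T, 1.0)
        modules = detect_modules(_tom_df(T))
        assert (modules.gene_module == "unassigned").all()

    def test_fewer_genes_than_min_size_all_unassigned(self):
        T = np.ones((5, 5))
        modules = detect_modules(_tom_df(T), NetworkParams(min_module_size=30))
        assert (modules.gene_module == "unassigned").all()

    def test_planted_modules_recovered(self, recovery_network):
        modules = recovery_network["modules"]
        truth = recovery_network["truth"]
        assigned = modules.gene_module[modules.gene_module != "unassigned"]
        assert len(assigned) >= 100
        true_labels = [str(truth.gene_module[g]) for g in assigned.index]
        assert adjusted_rand_score(true_labels, assigned.tolist()) >= 0.8


# --------------------------------------------------------------------- eigengenes

class TestEigengenes:
    def _module_of(self, vals, label="m1"):
        genes = [f"g{i}" for i in range(vals.shape[0])]
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(vals.shape[1])]),
            scale="lognorm",
        )
        assign = ModuleAssignment(pd.Series([label] * len(genes), index=genes))
        return expr, assign

    def test_identical_genes_give_standardized_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        expr, assign = self._module_of(np.tile(profile, (5, 1)))
        eig = module_eigengenes(expr, assign)["m1"].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(eig, z, atol=1e-10)

    def test_matches_first_principal_component_oracle(self, rng):
        vals = rng.normal(size=(12, 15))
        expr, assign = self._module_of(vals)
        eig = module_eigengenes(expr, assign)["m1"].to_numpy()
        Z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        w, V = np.linalg.eigh(Z.T @ Z)  # sample-space covariance, independent route
        pc1 = V[:, -1]
        assert abs(np.corrcoef(eig, pc1)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert eig.std() == pytest.approx(1.0, abs=1e-10)

    def test_orientation_is_deterministic_under_global_flip(self, rng):
        vals = rng.normal(size=(8, 10))
        expr, assign = self._module_of(vals)
        e1 = module_eigengenes(expr, assign)["m1"].to_numpy()
        expr_f, _ = self._module_of(-vals)
        e2 = module_eigengenes(expr_f, assign)["m1"].to_numpy()
        # flipping all genes flips the anchor too: eigengene negates exactly,
        # and every |correlation| computed from it is unchanged
        assert np.allclose(e2, -e1, atol=1e-10)

    def test_zero_variance_module_errors(self):
        expr, assign = self._module_of(np.ones((4, 6)))
        with pytest.raises(ValidationError):
            module_eigengenes(expr, assign)


# --------------------------------------------------------------------- trait stats

class TestModuleTraitStats:
    def _pheno(self, labels):
        return PhenotypeTable(pd.Series(labels, index=[f"s{j}" for j in range(len(labels))]))

    def test_perfect_and_orthogonal_eigengenes(self):
        pheno = self._pheno(["R", "R", "NR", "NR"])
        t = pheno.trait_code.to_numpy()
        perfect = (t - t.mean()) / t.std()
        orth = np.array([1.0, -1.0, 1.0, -1.0])
        eig = pd.DataFrame({"hit": perfect, "orth": orth}, index=pheno.sample_ids)
        out = module_trait_stats(eig, pheno)
        assert out.loc["hit", "eigengene_cor"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["hit", "direction"] == "R_positive"
        assert out.loc["orth", "eigengene_cor"] == pytest.approx(0.0, abs=1e-12)

    def test_pvalues_match_t_transform_oracle(self, rng):
        n = 20
        pheno = self._pheno(["R"] * 8 + ["NR"] * 12)
        eig = pd.DataFrame(rng.normal(size=(n, 3)), index=pheno.sample_ids, columns=list("abc"))
        out = module_trait_stats(eig, pheno)
        t_code = pheno.trait_code.to_numpy()
        for mod in "abc":
            r = np.corrcoef(eig[mod], t_code)[0, 1]
            t_stat = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * sps.t.sf(abs(t_stat), df=n - 2)
            assert out.loc[mod, "p"] == pytest.approx(p, abs=1e-12)

    def test_single_class_phenotype_errors(self):
        pheno = self._pheno(["R", "R", "R"])
        eig = pd.DataFrame({"a": [0.1, 0.2, 0.3]}, index=pheno.sample_ids)
        with pytest.raises(ValidationError):
            module_trait_stats(eig, pheno)


class TestGeneTraitStats:
    def test_perfectly_aligned_gene_has_unit_gs(self):
        df = pd.DataFrame([[2.0, 2.0, 1.0, 1.0]], index=["g0"], columns=list("abcd"))
        expr = ExpressionMatrix(df, scale="lognorm")
        pheno = PhenotypeTable(pd.Series(["R", "R", "NR", "NR"], index=list("abcd")))
        out = gene_trait_stats(expr, pheno)
        assert out.loc["g0", "gs"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["g0", "p"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bh_tail_min_oracle(self, small_expr):
        labels = ["R"] * 6 + ["NR"] * 6
        pheno = PhenotypeTable(pd.Series(labels, index=small_expr.sample_ids))
        out = gene_trait_stats(small_expr, pheno)
        assert (out["fdr"] >= out["p"] - 1e-15).all()
        # independent BH: min over tails of p * m / rank
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = np.inf
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            expected[i] = min(running, 1.0)
        assert np.allclose(out["fdr"].to_numpy(), expected, atol=1e-12)

    def test_gs_sign_tracks_module_direction(self, signal_cohort):
        from modfactor import filter_genes

        expr, pheno, truth = signal_cohort
        logn = lognormalize(filter_genes(expr))
        out = gene_trait_stats(logn, pheno)
        deltas = truth.module_delta
        r_genes = [g for g, m in truth.gene_module.items() if m != "background" and deltas[m] > 0]
        nr_genes = [g for g, m in truth.gene_module.items() if m != "background" and deltas[m] < 0]
        assert out.loc[r_genes, "gs"].median() > 0
        assert out.loc[nr_genes, "gs"].median() < 0

    def test_null_fdr_is_controlled(self):
        from modfactor import SyntheticConfig, generate_cohort

        frac_p, frac_fdr = [], []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_samples=50, r_fraction=0.5, modules=[], n_background=200, seed=seed
            )
            expr, pheno, _ = generate_cohort(cfg)
            out = gene_trait_stats(lognormalize(expr), pheno)
            frac_p.append((out["p"] < 0.4).mean())
            frac_fdr.append((out["fdr"] < 0.4).mean())
        assert np.mean(frac_fdr) < np.mean(frac_p) / 4
        assert np.mean(frac_fdr) < 0.05
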