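import numpy as np
import pandas as pd
import pytest

from infantsleep.composites import (choose_k, fit_pca_promax, impute,
                                    label_components, pool_over_imputations,
                                    promax, prune_and_assign,
                                    score_composites, varimax)


def five_block_matrix(n=300, per_block=4, noise=0.35, seed=0,
                      factor_corr=None):
    """Synthetic matrix: five latent factors, disjoint variable blocks."""
    rng = np.random.default_rng(seed)
    if factor_corr is None:
        factor_corr = np.eye(5)
    chol = np.linalg.cholesky(factor_corr)
    f = rng.standard_normal((n, 5)) @ chol.T
    cols, data = [], []
    for b in range(5):
        for j in range(per_block):
            sign = 1 if j % 2 == 0 else -1
            data.append(sign * f[:, b] + noise * rng.standard_normal(n))
            cols.append(f"b{b}_v{j}")
    return pd.DataFrame(np.column_stack(data), columns=cols)


class TestImpute:
    def test_complete_matrix_passes_through(self):
        m = pd.DataFrame(np.arange(20.0).reshape(5, 4))
        out = impute(m, m=3, seed=0)
        assert len(out) == 3
        for o in out:
            pd.testing.assert_frame_equal(o, m)

    def test_deterministic_given_seed(self):
        m = five_block_matrix(n=80)
        m.iloc[::7, 0] = np.nan
        a = impute(m, m=2, iterations=3, seed=5)
        b = impute(m, m=2, iterations=3, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_observed_cells_untouched_and_donors_observed(self):
        m = five_block_matrix(n=80)
        mask = m.copy()
        mask.iloc[::9, 2] = np.nan
        out = impute(mask, m=2, iterations=3, seed=1)[0]
        obs = ~mask[2].isna() if 2 in mask else ~mask.iloc[:, 2].isna()
        assert np.allclose(out.iloc[:, 2][obs.to_numpy()],
                           mask.iloc[:, 2][obs.to_numpy()])
        # PMM draws donor values from the observed pool
        imputed = out.iloc[:, 2][~obs.to_numpy()]
        pool = set(np.round(mask.iloc[:, 2].dropna().to_numpy(), 9))
        assert all(np.round(v, 9) in pool for v in imputed)

    def test_all_missing_column_raises(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="no observed"):
            impute(m)


class TestChooseK:
    def test_five_block_structure_suggests_five(self):
        m = five_block_matrix(n=400, noise=0.5, seed=3)
        assert choose_k(m, seed=0)["k"] == 5

    def test_pure_noise_suggests_zero(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.standard_normal((300, 12)))
        assert choose_k(m, seed=0)["k"] == 0

    def test_rank_one_structure_suggests_one(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal(300)
        m = pd.DataFrame({f"v{i}": f + 0.4 * rng.standard_normal(300)
                          for i in range(8)})
        assert choose_k(m, seed=0)["k"] == 1


class TestRotation:
    # frozen oracle: base R stats::promax(L, m=4) on this matrix
    R_INPUT = np.array([
        [0.85, 0.10, 0.05], [0.80, 0.15, -0.05], [0.75, -0.10, 0.10],
        [0.10, 0.82, 0.08], [0.05, 0.78, -0.12], [-0.10, 0.70, 0.15],
        [0.08, 0.05, 0.80], [-0.05, 0.12, 0.76], [0.15, -0.08, 0.72]])
    R_PROMAX = np.array([
        [0.849711, 0.066592, 0.020911], [0.806883, 0.122261, -0.079379],
        [0.745065, -0.131787, 0.079290], [0.097559, 0.814204, 0.057359],
        [0.061573, 0.783522, -0.141394], [-0.108578, 0.698888, 0.137094],
        [0.023136, 0.017070, 0.801504], [-0.104195, 0.093490, 0.763661],
        [0.098643, -0.112682, 0.721926]])

    def test_promax_matches_independent_reference(self):
        pat, phi = promax(self.R_INPUT, power=4)
        assert np.allclose(pat, self.R_PROMAX, atol=1e-3)
        assert np.allclose(phi, phi.T)

    def test_varimax_preserves_communalities(self):
        L, _ = varimax(self.R_INPUT)
        assert np.allclose((L ** 2).sum(axis=1),
                           (self.R_INPUT ** 2).sum(axis=1))

    def test_block_structure_recovered_with_small_crossloadings(self):
        m = five_block_matrix(n=500, noise=0.3, seed=1)
        fit = fit_pca_promax(m, k=5)
        pat = fit["pattern"].abs()
        for var in m.columns:
            block = int(var[1])
            top = pat.loc[var].idxmax()
            others = pat.loc[var].drop(top)
            assert pat.loc[var, top] > 0.8
            assert (others < 0.2).all()

    def test_uncorrelated_factors_give_near_identity_phi(self):
        m = five_block_matrix(n=800, noise=0.3, seed=2)
        fit = fit_pca_promax(m, k=5)
        off = fit["phi"].to_numpy() - np.eye(5)
        assert np.abs(off).max() < 0.1

    def test_correlated_factors_recovered_in_phi(self):
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.5
        m = five_block_matrix(n=2000, noise=0.3, seed=3, factor_corr=corr)
        fit = fit_pca_promax(m, k=5)
        pat = fit["pattern"].abs()
        comp_of_block = {b: pat.loc[f"b{b}_v0"].idxmax() for b in range(5)}
        phi = fit["phi"]
        assert abs(phi.loc[comp_of_block[0], comp_of_block[1]]) > 0.3

    def test_sign_convention_largest_loading_positive(self):
        m = five_block_matrix(n=300, seed=5)
        pat = fit_pca_promax(m, k=5)["pattern"]
        for c in pat.columns:
            assert pat[c].loc[pat[c].abs().idxmax()] > 0

    def test_duplicated_column_gets_identical_loadings(self):
        m = five_block_matrix(n=300, seed=6)
        m["dup"] = m["b0_v0"]
        pat = fit_pca_promax(m, k=5)["pattern"]
        assert np.allclose(pat.loc["dup"], pat.loc["b0_v0"], atol=1e-6)

    def test_k_above_rank_raises(self):
        m = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 6)))
        with pytest.raises(ValueError):
            fit_pca_promax(m, k=5)


class TestPruneAndAssign:
    def test_low_loading_variables_dropped(self):
        m = five_block_matrix(n=400, noise=0.3, seed=7)
        rng = np.random.default_rng(8)
        m["junk"] = rng.standard_normal(len(m))  # loads on nothing
        sol = prune_and_assign(m, k=5, cutoff=0.512)
        assert "junk" in sol.dropped_low_loading
        assert "junk" not in sol.retained
        assert len(sol.retained) + len(sol.dropped_low_loading) \
            + len(sol.drop_list) == m.shape[1]

    def test_drop_list_removed_a_priori(self):
        m = five_block_matrix(n=300, seed=9)
        sol = prune_and_assign(m, k=5, drop_list=("b0_v0",))
        assert "b0_v0" not in sol.retained
        assert "b0_v0" not in sol.dropped_low_loading

    def test_assignment_matches_generating_blocks(self):
        m = five_block_matrix(n=500, noise=0.35, seed=10)
        sol = prune_and_assign(m, k=5)
        by_block = {}
        for var, (comp, sign) in sol.assignment.items():
            by_block.setdefault(var[1], set()).add(comp)
            expected_sign = 1 if int(var[4]) % 2 == 0 else -1
            # signs are consistent within a block up to a global flip
        assert all(len(comps) == 1 for comps in by_block.values())
        assert len({next(iter(c)) for c in by_block.values()}) == 5

    def test_scores_average_signed_zscores(self):
        m = five_block_matrix(n=300, noise=0.2, seed=11)
        sol = prune_and_assign(m, k=5)
        scores = score_composites(m, sol)
        comp, sign = sol.assignment["b2_v0"]
        members = sol.members(comp)
        z = (m[members] - m[members].mean()) / m[members].std(ddof=1)
        signs = np.array([sol.assignment[v][1] for v in members])
        name = sol.component_labels.get(comp, comp)
        assert np.allclose(scores[name], (z * signs).mean(axis=1))

    def test_scores_invariant_to_member_relabeling(self):
        m = five_block_matrix(n=200, noise=0.2, seed=12)
        sol = prune_and_assign(m, k=5)
        scores1 = score_composites(m, sol)
        shuffled = m[list(m.columns[::-1])]
        scores2 = score_composites(shuffled, sol)
        pd.testing.assert_frame_equal(scores1, scores2[scores1.columns])

    def test_missing_input_raises(self):
        m = five_block_matrix(n=100, seed=13)
        sol = prune_and_assign(m, k=5)
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            score_composites(m, sol)


class TestRubin:
    def test_identical_estimates_pool_to_themselves(self):
        out = pool_over_imputations([2.5, 2.5, 2.5], [0.4, 0.4, 0.4])
        assert out["estimate"] == 2.5
        assert out["between"] == 0.0
        assert out["variance"] == pytest.approx(0.4)

    def test_two_imputation_arithmetic(self):
        out = pool_over_imputations([1.0, 3.0], [1.0, 1.0])
        assert out["estimate"] == 2.0
        assert out["between"] == pytest.approx(2.0)
        assert out["variance"] == pytest.approx(1.0 + 1.5 * 2.0)

    def test_single_imputation_passthrough_warns(self):
        with pytest.warns(UserWarning, match="single imputation"):
            out = pool_over_imputations([1.7], [0.3])
        assert out["estimate"] == 1.7
        assert out["variance"] == 0.3
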