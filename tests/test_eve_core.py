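import numpy as np
import pytest
from scipy import stats

from holoeve.eve import (
    OUGeneParams,
    SampleLayout,
    build_covariance,
    divergence_test,
    fit_gene,
    fit_shared_beta,
    loglik_gene,
)
from holoeve.phylogeny import Phylogeny


def _dense_covariance(tree, params, layout):
    """Independent assembly of the OU covariance, entry by entry."""
    v = params.sigma2 / (2.0 * params.alpha)
    n = layout.n
    cov = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                cov[i, j] = v * (1.0 + params.beta)
            elif layout.species[i] == layout.species[j]:
                cov[i, j] = v
            else:
                d = tree.distance(layout.species[i], layout.species[j])
                cov[i, j] = v * np.exp(-params.alpha * d)
    return cov


class TestCovariance:
    def test_one_species_two_individuals(self, two_tip_tree):
        lay = SampleLayout(species=("X", "X"))
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        cov = build_covariance(two_tip_tree, p, lay)
        assert np.allclose(cov, [[2.0, 1.0], [1.0, 2.0]])

    def test_cross_species_entry_at_distance_two(self, two_tip_tree):
        lay = SampleLayout(species=("X", "Y"))
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        cov = build_covariance(two_tip_tree, p, lay)
        assert cov[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_huge_alpha_decouples_species(self, tree):
        lay = SampleLayout(species=("A", "B", "C"))
        p = OUGeneParams(theta=0.0, sigma2=2e6, alpha=1e6, beta=0.5)
        cov = build_covariance(tree, p, lay)
        off = cov[~np.eye(3, dtype=bool)]
        assert np.all(off < 1e-300)

    def test_species_not_on_tree_rejected(self, tree):
        lay = SampleLayout(species=("A", "Z"))
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        with pytest.raises(Exception, match="Z"):
            build_covariance(tree, p, lay)


class TestLoglik:
    def test_single_individual_standard_normal(self, two_tip_tree):
        # v_evo = 1, beta = 0 -> unit variance; density at the mean
        lay = SampleLayout(species=("X",))
        p = OUGeneParams(theta=3.0, sigma2=1.0, alpha=0.5, beta=0.0)
        ll = loglik_gene(np.array([3.0]), p, two_tip_tree, lay)
        assert ll == pytest.approx(np.log(1.0 / np.sqrt(2 * np.pi)), abs=1e-9)

    def test_mean_vector_maximises_density(self, tree, layout3x3, unit_params):
        y0 = np.full(layout3x3.n, unit_params.theta)
        ll0 = loglik_gene(y0, unit_params, tree, layout3x3)
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = y0 + rng.normal(0, 0.5, layout3x3.n)
            assert loglik_gene(y, unit_params, tree, layout3x3) < ll0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn_oracle(self, tree, seed):
        """On <= 6 individuals the likelihood equals an independently
        assembled dense multivariate-normal density to 1e-8 relative."""
        rng = np.random.default_rng(seed)
        n_per = rng.integers(1, 3, size=3)
        species = tuple(
            s for s, k in zip(("A", "B", "C"), n_per) for _ in range(k)
        )
        lay = SampleLayout(species=species)
        p = OUGeneParams(
            theta=rng.normal(0, 3),
            sigma2=rng.uniform(0.2, 3.0),
            alpha=rng.uniform(0.1, 2.0),
            beta=rng.uniform(0.05, 4.0),
        )
        y = rng.normal(p.theta, 1.0, lay.n)
        expected = stats.multivariate_normal(
            mean=np.full(lay.n, p.theta), cov=_dense_covariance(tree, p, lay)
        ).logpdf(y)
        got = loglik_gene(y, p, tree, lay)
        assert got == pytest.approx(expected, rel=1e-8)

    def test_nonfinite_input_rejected(self, tree, layout3x3, unit_params):
        y = np.zeros(9)
        y[4] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            loglik_gene(y, unit_params, tree, layout3x3)

    def test_length_mismatch_rejected(self, tree, layout3x3, unit_params):
        with pytest.raises(ValueError, match="length"):
            loglik_gene(np.zeros(5), unit_params, tree, layout3x3)


class TestFitGene:
    def test_zero_within_variance_pushes_beta_to_floor(self, tree, layout3x3):
        y = np.array([1.0] * 3 + [5.0] * 3 + [9.0] * 3)
        fit = fit_gene(y, tree, layout3x3)
        assert fit.params.beta < 1e-3

    def test_free_beta_never_below_fixed(self, tree, layout3x3, rng):
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        L = np.linalg.cholesky(build_covariance(tree, p, layout3x3))
        for _ in range(20):
            y = L @ rng.standard_normal(9)
            ll_free = fit_gene(y, tree, layout3x3).loglik
            ll_fixed = fit_gene(y, tree, layout3x3, fixed_beta=1.0).loglik
            assert ll_free >= ll_fixed - 1e-6

    def test_unreplicated_layout_rejected(self, tree):
        lay = SampleLayout(species=("A", "B", "C"))
        with pytest.raises(ValueError, match="unidentifiable|replicates"):
            fit_gene(np.array([1.0, 2.0, 3.0]), tree, lay)

    def test_single_species_rejected(self, tree):
        lay = SampleLayout(species=("A",) * 4)
        with pytest.raises(ValueError, match="2 species"):
            fit_gene(np.arange(4.0), tree, lay)

    def test_constant_gene_flagged_not_raised(self, tree, layout3x3):
        fit = fit_gene(np.full(9, 2.0), tree, layout3x3)
        assert not fit.converged


class TestSharedBeta:
    def test_two_identical_genes_equal_single_gene_estimate(
        self, tree, layout3x3, rng
    ):
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        L = np.linalg.cholesky(build_covariance(tree, p, layout3x3))
        y = L @ rng.standard_normal(9)
        single = fit_gene(y, tree, layout3x3).params.beta
        shared, _ = fit_shared_beta(np.vstack([y, y]), tree, layout3x3)
        assert shared == pytest.approx(single, abs=1e-4 * max(1.0, single))

    def test_local_optimality_of_joint_estimate(self, tree, layout3x3, rng):
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        L = np.linalg.cholesky(build_covariance(tree, p, layout3x3))
        Y = (L @ rng.standard_normal((9, 40))).T
        shared, params = fit_shared_beta(Y, tree, layout3x3)

        def joint_ll(beta):
            return sum(
                fit_gene(y, tree, layout3x3, fixed_beta=beta).loglik
                for y in Y
            )

        at_hat = joint_ll(shared)
        assert at_hat >= joint_ll(shared + 0.1) - 1e-6
        assert at_hat >= joint_ll(max(shared - 0.1, 1e-4)) - 1e-6

    def test_all_degenerate_rejected(self, tree, layout3x3):
        with pytest.raises(ValueError, match="degenerate"):
            fit_shared_beta(np.ones((5, 9)), tree, layout3x3)


class TestDivergenceTest:
    def test_constant_matrix_all_degenerate_with_warning(self, tree, layout3x3):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = divergence_test(np.ones((4, 9)), tree, layout3x3)
        assert res["degenerate"].all()
        assert (res["call"] == "none").all()

    def test_lrt_nonnegative_and_p_in_unit_interval(self, tree, layout3x3, rng):
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        L = np.linalg.cholesky(build_covariance(tree, p, layout3x3))
        Y = (L @ rng.standard_normal((9, 50))).T
        res = divergence_test(Y, tree, layout3x3)
        assert (res["lrt"] >= 0).all()
        assert res["pvalue"].between(0, 1).all()

    def test_call_direction_rule(self, tree, layout3x3, rng):
        """Significant genes are 'divergence' iff their beta falls below
        the shared estimate, 'diversity' iff above."""
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        L = np.linalg.cholesky(build_covariance(tree, p, layout3x3))
        Y = (L @ rng.standard_normal((9, 60))).T
        # plant a strong lineage shift (divergence direction)
        Y[0, :3] += 20.0
        res = divergence_test(Y, tree, layout3x3)
        sig = res[res["pvalue"] < 0.05]
        for _, row in sig.iterrows():
            if row["call"] == "divergence":
                assert row["beta_i"] < row["beta_shared"]
            else:
                assert row["beta_i"] > row["beta_shared"]
        assert res.iloc[0]["call"] == "divergence"

    def test_scale_equivariance(self, tree, layout3x3, rng):
        """Adding a constant to a gene shifts theta only; LRT invariant."""
        p = OUGeneParams(theta=0.0, sigma2=1.0, alpha=0.5, beta=1.0)
        L = np.linalg.cholesky(build_covariance(tree, p, layout3x3))
        Y = (L @ rng.standard_normal((9, 25))).T
        res1 = divergence_test(Y, tree, layout3x3, beta_shared=1.0)
        res2 = divergence_test(Y + 7.5, tree, layout3x3, beta_shared=1.0)
        np.testing.assert_allclose(res1["lrt"], res2["lrt"], atol=1e-6)
        np.testing.assert_allclose(
            res2["theta"], res1["theta"] + 7.5, atol=1e-5
        )
        np.testing.assert_allclose(res1["beta_i"], res2["beta_i"],
                                   rtol=1e-4, atol=1e-6)

    def test_strong_selection_limit_matches_anova_ranking(self, rng):
        """With negligible cross-species covariance the LRT (at the true
        shared variance ratio) ranks genes like the between/within variance
        ratio of a one-way ANOVA."""
        tree = Phylogeny.from_newick("((A:50,B:50):50,C:100);")
        lay = SampleLayout(species=("A",) * 3 + ("B",) * 3 + ("C",) * 3)
        G = 60
        # alpha -> infinity limit: independent species means (v=1) + noise
        means = rng.normal(0, 1, size=(G, 3))
        Y = np.repeat(means, 3, axis=1) + rng.normal(0, 1, size=(G, 9))
        shifts = np.linspace(0, 8, G)
        Y[:, :3] += shifts[:, None]
        res = divergence_test(Y, tree, lay, beta_shared=1.0)
        f_ratio = np.array([
            stats.f_oneway(y[:3], y[3:6], y[6:]).statistic for y in Y
        ])
        # signed statistic: divergence direction (beta below shared)
        # positive, diversity direction negative
        signed = np.sign(res["beta_shared"] - res["beta_i"]) * res["lrt"]
        rho = stats.spearmanr(signed, f_ratio).statistic
        assert rho > 0.9
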