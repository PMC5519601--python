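"""AI-REML engine: direct-likelihood oracle equivalence, invariances,
delta-method inference and variance partitioning."""

import numpy as np
import pytest
from scipy import optimize, stats

import envgreml as eg
from envgreml.exceptions import BoundaryError, DomainError


def direct_restricted_loglik(theta, A, y, X):
    """Independent evaluation of the REML kernel for a single block with
    V = vg * A + ve * I (explicit inverse, no shared code with the engine)."""
    vg, ve = theta
    n = len(y)
    V = vg * A + ve * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    s2, logdet_x = np.linalg.slogdet(XtViX)
    if s2 <= 0:
        return -np.inf
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))


@pytest.fixture(scope="module")
def single_block():
    G = eg.simulate_genotypes(50, 100, (0.1, 0.5), seed=21)
    A = eg.compute_grm(G)
    cfg = eg.gxe_config([50], 0.5, 1.0, 100, seed=22)
    cohort = eg.simulate_gxe_cohort(G, cfg)
    y = cohort["phenotype"].to_numpy()
    return A, y


class TestRemlOracle:
    def test_matches_direct_likelihood_maximization(self, single_block):
        """AI-REML optimum equals a grid + Nelder-Mead maximization of the
        explicit restricted likelihood on a 2-parameter single-group model."""
        A, y = single_block
        blocks = eg.ModelBlocks(y=[y], idx=[np.arange(50)])
        vc = eg.reml_fit(blocks, A, tol=1e-10)

        X = np.ones((50, 1))
        grid = np.linspace(0.01, 2.5 * y.var(), 25)
        best = max(
            ((vg, ve) for vg in grid for ve in grid),
            key=lambda th: direct_restricted_loglik(th, A.values, y, X),
        )
        res = optimize.minimize(
            lambda th: -direct_restricted_loglik(th, A.values, y, X),
            x0=np.array(best),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        assert abs(vc.logl - (-res.fun)) < 1e-6
        assert abs(vc.sigma_g[0][0, 0] - res.x[0]) < 1e-3
        assert abs(vc.sigma_e[0, 0] - res.x[1]) < 1e-3

    def test_likelihood_trail_monotone(self, single_block):
        A, y = single_block
        blocks = eg.ModelBlocks(y=[y], idx=[np.arange(50)])
        vc = eg.reml_fit(blocks, A)
        trail = np.array(vc.logl_trail)
        assert (np.diff(trail) >= -1e-8).all()


class TestDegenerateAndBoundary:
    def test_identity_grm_flagged_non_identifiable(self):
        """With A = I the genetic and residual variances are completely
        confounded; the engine must flag this instead of reporting SEs."""
        rng = np.random.default_rng(23)
        n = 60
        y = rng.normal(size=n)
        A = eg.GRM([f"s{i}" for i in range(n)], np.eye(n), np.full((n, n), 1.0))
        blocks = eg.ModelBlocks(y=[y], idx=[np.arange(n)])
        vc = eg.reml_fit(blocks, A, on_fail="flag")
        assert not vc.identifiable
        assert vc.param_cov() is None
        est, se, p = vc.h2(0)
        assert np.isnan(se)

    def test_null_heritability_pins_variance_at_floor(self, pool):
        G, A = pool
        rng = np.random.default_rng(24)
        y = rng.normal(size=300)  # pure noise: vg -> floor
        blocks = eg.ModelBlocks(y=[y, rng.normal(size=300)],
                                idx=[np.arange(300), np.arange(300, 600)])
        vc = eg.reml_fit(blocks, A, on_fail="flag")
        kg = [vc.param_index("g", 0, i, i) for i in (0, 1)]
        if vc.boundary[kg].any():
            with pytest.raises(BoundaryError):
                eg.genetic_correlation(vc, 0, 1)
        else:
            # tiny but positive estimates: r_G must still be finite
            res = eg.genetic_correlation(vc, 0, 1)
            assert np.isfinite(res.r_g)


class TestInvariances:
    def test_scale_and_shift_invariance(self, pool, cohort2):
        G, A = pool
        blocks = eg.ModelBlocks.from_cohort(cohort2, A)
        vc1 = eg.reml_fit(blocks, A, tol=1e-9)
        scaled = cohort2.copy()
        c = 3.7
        scaled["phenotype"] = c * scaled["phenotype"] + 11.0
        vc2 = eg.reml_fit(eg.ModelBlocks.from_cohort(scaled, A), A, tol=1e-9)
        assert np.allclose(vc2.sigma_g[0], c**2 * vc1.sigma_g[0], rtol=1e-4)
        assert np.allclose(np.diag(vc2.sigma_e), c**2 * np.diag(vc1.sigma_e), rtol=1e-4)
        r1 = eg.genetic_correlation(vc1, 0, 1).r_g
        r2 = eg.genetic_correlation(vc2, 0, 1).r_g
        assert abs(r1 - r2) < 1e-6

    def test_multitrait_mode_with_disjoint_blocks_equals_gxe(self, pool, cohort2):
        G, A = pool
        blocks = eg.ModelBlocks.from_cohort(cohort2, A)
        vc_g = eg.reml_fit(blocks, A, mode="gxe", tol=1e-9)
        vc_m = eg.reml_fit(blocks, A, mode="multi_trait", tol=1e-9)
        # disjoint samples: no residual-covariance parameter exists, fits agree
        assert len(vc_m.params) == len(vc_g.params)
        assert np.allclose(vc_m.params, vc_g.params, atol=1e-8)


class TestMultiTrait:
    def test_residual_covariance_recovered_on_shared_samples(self):
        """Two traits on the same individuals with genetic r_G = 0.8 and
        residual correlation 0.5: the multi-trait engine must model the
        residual covariance (ignoring it would inflate the genetic one)."""
        rng = np.random.default_rng(25)
        n, m = 500, 800
        G = eg.simulate_genotypes(n, m, seed=26)
        A = eg.compute_grm(G)
        W = G.standardized()
        L = np.linalg.cholesky(np.array([[1.0, 0.8], [0.8, 1.0]]))
        B = rng.standard_normal((m, 2)) @ L.T * np.sqrt(0.4 / m)
        g = W @ B
        Le = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        e = rng.standard_normal((n, 2)) @ Le.T * np.sqrt(0.6)
        y = g + e
        blocks = eg.ModelBlocks(
            y=[y[:, 0], y[:, 1]], idx=[np.arange(n), np.arange(n)],
            labels=["trait1", "trait2"],
        )
        vc = eg.reml_fit(blocks, A, mode="multi_trait")
        assert ("e", None, 0, 1) in vc.param_names
        re = vc.sigma_e[0, 1] / np.sqrt(vc.sigma_e[0, 0] * vc.sigma_e[1, 1])
        assert abs(re - 0.5) < 0.2
        rg = eg.genetic_correlation(vc, 0, 1).r_g
        assert abs(rg - 0.8) < 0.35


class TestGeneticCorrelation:
    def test_zero_covariance_gives_zero_correlation_p_one(self, fitted2):
        vc = fitted2
        # construct the zero-covariance case directly on the fitted object
        vc2 = eg.VarianceComponents(
            sigma_g=[np.diag(np.diag(vc.sigma_g[0]))],
            sigma_e=vc.sigma_e, logl=vc.logl, info=np.eye(len(vc.params)),
            params=vc.params.copy(), param_names=vc.param_names,
            n_iter=vc.n_iter, converged=True, boundary=vc.boundary,
            block_labels=vc.block_labels, block_sizes=vc.block_sizes,
            mode=vc.mode, floors=vc.floors,
        )
        kc = vc2.param_index("g", 0, 0, 1)
        vc2.params[kc] = 0.0
        res = eg.genetic_correlation(vc2, 0, 1)
        assert res.r_g == 0.0
        assert res.p_vs_0 == pytest.approx(1.0)

    def test_random_split_of_one_population_has_rg_one(self, pool):
        """Splitting a homogeneous population into two pseudo-groups is the
        purest no-G-by-E case: r_G within 2 SE of 1."""
        G, A = pool
        cfg = eg.gxe_config([600], 0.5, 1.0, G.n_variants, seed=27)
        cohort = eg.simulate_gxe_cohort(G, cfg)
        rng = np.random.default_rng(28)
        half = rng.permutation(600) < 300
        cohort = cohort.copy()
        cohort["group"] = np.where(half, "P1", "P2")
        vc = eg.reml_fit(eg.ModelBlocks.from_cohort(cohort, A), A)
        res = eg.genetic_correlation(vc, 0, 1)
        assert abs(res.r_g - 1.0) < 2 * res.se

    def test_delta_se_agrees_with_parametric_bootstrap(self):
        """Delta-method SE of r_G vs the SD of parametric-bootstrap
        re-estimates on one fixed dataset: ratio within [0.7, 1.3]."""
        n1 = 400
        G = eg.simulate_genotypes(2 * n1, 1200, seed=29)
        A = eg.compute_grm(G)
        cfg = eg.gxe_config([n1, n1], 0.4, 0.5, 1200, seed=30)
        cohort = eg.simulate_gxe_cohort(G, cfg)
        blocks = eg.ModelBlocks.from_cohort(cohort, A)
        vc = eg.reml_fit(blocks, A)
        res = eg.genetic_correlation(vc, 0, 1)

        # simulate phenotypes from the fitted model, refit, collect r_G
        rng = np.random.default_rng(31)
        Av = A.values
        N = 2 * n1
        sg, se_ = vc.sigma_g[0], np.diag(vc.sigma_e)
        V = np.zeros((N, N))
        V[:n1, :n1] = sg[0, 0] * Av[:n1, :n1] + se_[0] * np.eye(n1)
        V[n1:, n1:] = sg[1, 1] * Av[n1:, n1:] + se_[1] * np.eye(n1)
        V[:n1, n1:] = sg[0, 1] * Av[:n1, n1:]
        V[n1:, :n1] = V[:n1, n1:].T
        Lv = np.linalg.cholesky(V + 1e-10 * np.eye(N))
        boots = []
        for _ in range(60):
            yb = Lv @ rng.standard_normal(N)
            bb = eg.ModelBlocks(y=[yb[:n1], yb[n1:]], idx=list(blocks.idx))
            try:
                vb = eg.reml_fit(bb, A, theta0=vc.params, on_fail="flag")
            except eg.EnvGremlError:
                continue
            ki, kj, kc = (vb.param_index("g", 0, a, b) for a, b in ((0, 0), (1, 1), (0, 1)))
            v1, v2, c = vb.params[[ki, kj, kc]]
            if v1 > vb.floors[ki] * 2 and v2 > vb.floors[kj] * 2:
                boots.append(c / np.sqrt(v1 * v2))
        assert len(boots) > 45
        ratio = res.se / np.std(boots)
        assert 0.7 < ratio < 1.3


class TestWald:
    def test_estimate_at_null_gives_p_one(self):
        assert eg.wald_test(0.5, 0.1, 0.5) == pytest.approx(1.0)

    def test_normal_quantile_identity(self):
        assert eg.wald_test(1.959964 * 0.2, 0.2, 0.0) == pytest.approx(0.05, abs=1e-6)

    def test_published_contrast_arithmetic(self):
        """A genetic correlation of 0.597 (SE 0.123) tested against 1 gives
        p about 1.0e-3, matching the reported significance of that
        cross-environment contrast."""
        p = eg.wald_test(0.597, 0.123, 1.0)
        assert p == pytest.approx(2 * stats.norm.sf((1 - 0.597) / 0.123), abs=1e-12)
        assert abs(p - 1.0e-3) < 1e-4

    def test_invalid_se_rejected(self):
        with pytest.raises(DomainError):
            eg.wald_test(1.0, 0.0, 0.0)


class TestPartitionRatio:
    @staticmethod
    def _two_component_fit(frac_snps, frac_var, n=600, m=900, seed=31):
        rng = np.random.default_rng(seed)
        G = eg.simulate_genotypes(n, m, seed=seed)
        m1 = int(frac_snps * m)
        W = G.standardized()
        h2 = 0.5
        b1 = rng.standard_normal(m1) * np.sqrt(h2 * frac_var / m1)
        b2 = rng.standard_normal(m - m1) * np.sqrt(h2 * (1 - frac_var) / (m - m1))
        g = W[:, :m1] @ b1 + W[:, m1:] @ b2
        y = g + rng.normal(0, np.sqrt(1 - h2), n)
        A1 = eg.compute_grm(G.subset(variant_idx=np.arange(m1)))
        A2 = eg.compute_grm(G.subset(variant_idx=np.arange(m1, m)))
        blocks = eg.ModelBlocks(y=[y], idx=[np.arange(n)])
        vc = eg.reml_fit(blocks, [A1, A2], on_fail="flag")
        return eg.partition_ratio(vc, component=0, i=0, snp_fraction=frac_snps)

    def test_single_component_ratio_is_one(self, fitted2):
        res = eg.partition_ratio(fitted2, component=0, i=0)
        assert res.ratio == 1.0

    def test_enriched_category_recovered(self):
        """A category with 10% of SNPs carrying 35% of genetic variance:
        the estimated share exceeds the SNP share and covers the truth."""
        results = [self._two_component_fit(0.10, 0.35, seed=100 + r) for r in range(6)]
        ratios = np.array([r.ratio for r in results])
        ses = np.array([r.se for r in results])
        pooled_se = np.sqrt(np.nanmean(ses**2) / len(results))
        assert abs(ratios.mean() - 0.35) < 3 * max(pooled_se, ratios.std() / np.sqrt(6))
        rejections = sum(r.p_vs_fraction < 0.05 for r in results if r.p_vs_fraction is not None)
        assert rejections >= 3

    def test_null_enrichment_matches_snp_fraction(self):
        results = [self._two_component_fit(0.5, 0.5, seed=200 + r) for r in range(4)]
        ratios = np.array([r.ratio for r in results])
        assert abs(ratios.mean() - 0.5) < 3 * max(
            np.nanmean([r.se for r in results]) / 2, ratios.std() / 2
        )
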