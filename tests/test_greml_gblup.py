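import numpy as np
import pytest

from haplopred import (
    SimConfig,
    TraitArchitecture,
    build_design,
    build_grms,
    build_model_matrices,
    gblup_predict,
    greml_fit,
    per_locus_heritability,
    simulate_genotypes,
    simulate_phenotypes,
)
from haplopred.greml_gblup import FitResult


def reml_loglik_direct(y, X, g, sigma_g, sigma_e):
    """Independent restricted log-likelihood (direct formula, no shortcuts)."""
    n = y.size
    v = sigma_g * g + sigma_e * np.eye(n)
    vinv = np.linalg.inv(v)
    m = X.T @ vinv @ X
    beta = np.linalg.solve(m, X.T @ vinv @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(v)[1] + np.linalg.slogdet(m)[1] + float(r @ vinv @ r)
    )


@pytest.fixture(scope="module")
def additive_panel():
    panel = simulate_genotypes(
        SimConfig(
            n_individuals=300,
            chromosomes=[("1", 4_000_000)],
            snp_density=100,
            ld_decay=0.5,
            seed=51,
        )
    )
    mm = build_model_matrices(panel, components=("snp_additive",))
    return panel, mm, build_grms(mm).a_g


class TestGremlFit:
    def test_matches_brute_force_likelihood_grid(self):
        rng = np.random.default_rng(61)
        panel = simulate_genotypes(
            SimConfig(n_individuals=30, chromosomes=[("1", 1_000_000)], snp_density=80, seed=62)
        )
        mm = build_model_matrices(panel, components=("snp_additive",))
        g = build_grms(mm).a_g
        u = np.linalg.cholesky(g + 1e-8 * np.eye(30)) @ rng.standard_normal(30)
        y = u * 0.8 + rng.standard_normal(30)
        X = np.ones((30, 1))
        fit = greml_fit(y, X, {"snp_additive": g})

        grid = np.arange(0.02, 3.0, 0.02)
        lls = np.array([[reml_loglik_direct(y, X, g, a, b) for b in grid] for a in grid])
        i, j = np.unravel_index(lls.argmax(), lls.shape)
        assert fit.variance_components["snp_additive"] == pytest.approx(grid[i], abs=0.02)
        assert fit.variance_components["residual"] == pytest.approx(grid[j], abs=0.02)
        assert fit.log_likelihood >= lls.max() - 1e-6

    def test_null_phenotype_recovers_near_zero_heritability(self):
        # boundary noise of h2_hat under a pure-noise trait concentrates
        # below 0.05 once n is large enough for SE(h2_hat) ~ 0.02
        panel = simulate_genotypes(
            SimConfig(
                n_individuals=800,
                chromosomes=[("1", 5_000_000)],
                snp_density=100,
                ld_decay=0.9,
                seed=51,
            )
        )
        g = build_grms(build_model_matrices(panel, components=("snp_additive",))).a_g
        X = np.ones((800, 1))
        below = 0
        reps = 20
        for rep in range(reps):
            y = np.random.default_rng(70 + rep).standard_normal(800)
            fit = greml_fit(y, X, {"snp_additive": g})
            below += fit.heritabilities["snp_additive"] < 0.05
        assert below >= int(np.ceil(0.95 * reps))

    def test_heritabilities_sum_to_one_with_residual(self, additive_panel):
        panel, _, g = additive_panel
        pheno, _ = simulate_phenotypes(panel, None, TraitArchitecture(additive=0.4), seed=3)
        X, _ = build_design(pheno, ["sex"], ["age"])
        fit = greml_fit(pheno["y"].to_numpy(), X, {"snp_additive": g})
        assert sum(fit.heritabilities.values()) == pytest.approx(1.0, abs=1e-10)
        assert all(v >= 0 for v in fit.variance_components.values())

    def test_adding_component_never_decreases_likelihood(self, additive_panel):
        panel, _, g = additive_panel
        mm = build_model_matrices(panel, components=("snp_additive", "snp_dominance"))
        grms = build_grms(mm)
        pheno, _ = simulate_phenotypes(panel, None, TraitArchitecture(additive=0.4), seed=4)
        X, _ = build_design(pheno, ["sex"], ["age"])
        y = pheno["y"].to_numpy()
        fit_a = greml_fit(y, X, {"snp_additive": grms.a_g})
        fit_ad = greml_fit(y, X, {"snp_additive": grms.a_g, "snp_dominance": grms.d_g})
        assert fit_ad.log_likelihood >= fit_a.log_likelihood - 1e-6

    def test_singular_design_rejected(self, additive_panel):
        _, _, g = additive_panel
        y = np.random.default_rng(5).standard_normal(300)
        X = np.ones((300, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            greml_fit(y, X, {"snp_additive": g})

    def test_nonconvergence_flagged_not_raised(self, additive_panel):
        panel, _, g = additive_panel
        pheno, _ = simulate_phenotypes(panel, None, TraitArchitecture(additive=0.4), seed=6)
        X, _ = build_design(pheno, ["sex"], ["age"])
        with pytest.warns(UserWarning, match="did not converge"):
            fit = greml_fit(pheno["y"].to_numpy(), X, {"snp_additive": g}, max_iter=2)
        assert fit.converged is False


class TestGblupPredict:
    def test_zero_genetic_variance_gives_zero_predictions(self, additive_panel):
        _, _, g = additive_panel
        y = np.random.default_rng(7).standard_normal(300)
        X = np.ones((300, 1))
        fit = FitResult(
            variance_components={"snp_additive": 0.0, "residual": 1.0},
            heritabilities={"snp_additive": 0.0, "residual": 1.0},
            beta=np.zeros(1),
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
            component_names=["snp_additive"],
        )
        pred = gblup_predict(fit, {"snp_additive": g}, y, X, np.ones(300, dtype=bool))
        assert np.all(pred["total"] == 0)

    def test_grm_gblup_equals_marker_ridge_oracle(self):
        rng = np.random.default_rng(81)
        panel = simulate_genotypes(
            SimConfig(n_individuals=50, chromosomes=[("1", 2_000_000)], snp_density=100, seed=82)
        )
        mm = build_model_matrices(panel, components=("snp_additive",))
        w = mm.w_alpha
        k = mm.k_alpha
        g = build_grms(mm).a_g
        y = rng.standard_normal(50) + w[:, 10] * 0.5
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        sigma_g, sigma_e = 0.4, 0.8
        fit = FitResult(
            variance_components={"snp_additive": sigma_g, "residual": sigma_e},
            heritabilities={},
            beta=np.zeros(2),
            log_likelihood=0.0,
            converged=True,
            n_iter=0,
            component_names=["snp_additive"],
        )
        pred = gblup_predict(fit, {"snp_additive": g}, y, X, np.ones(50, dtype=bool))

        # independent oracle: marker-effect ridge normal equations (m-space)
        lam = sigma_e * k / sigma_g
        v = sigma_g * g + sigma_e * np.eye(50)
        vinv = np.linalg.inv(v)
        beta = np.linalg.solve(X.T @ vinv @ X, X.T @ vinv @ y)
        r = y - X @ beta
        alpha = np.linalg.solve(w.T @ w + lam * np.eye(w.shape[1]), w.T @ r)
        assert np.allclose(pred["beta"], beta, atol=1e-8)
        assert np.allclose(pred["snp_additive"], w @ alpha, atol=1e-8)

    def test_duplicating_snps_changes_nothing(self, additive_panel):
        panel, mm, g = additive_panel
        pheno, _ = simulate_phenotypes(panel, None, TraitArchitecture(additive=0.4), seed=8)
        X, _ = build_design(pheno, ["sex"], ["age"])
        y = pheno["y"].to_numpy()
        w2 = np.hstack([mm.w_alpha, mm.w_alpha])
        g2 = (w2 @ w2.T) / (np.trace(w2 @ w2.T) / 300)
        mask = np.ones(300, dtype=bool)
        mask[:40] = False
        fit1 = greml_fit(y[mask], X[mask], {"snp_additive": g[np.ix_(mask, mask)]})
        fit2 = greml_fit(y[mask], X[mask], {"snp_additive": g2[np.ix_(mask, mask)]})
        for key in fit1.heritabilities:
            assert fit1.heritabilities[key] == pytest.approx(fit2.heritabilities[key], abs=1e-8)
        p1 = gblup_predict(fit1, {"snp_additive": g}, y, X, mask)
        p2 = gblup_predict(fit2, {"snp_additive": g2}, y, X, mask)
        assert np.abs(p1["total"] - p2["total"]).max() < 1e-8

    def test_permutation_equivariance(self, additive_panel):
        panel, _, g = additive_panel
        pheno, _ = simulate_phenotypes(panel, None, TraitArchitecture(additive=0.4), seed=9)
        X, _ = build_design(pheno, ["sex"], ["age"])
        y = pheno["y"].to_numpy()
        mask = np.ones(300, dtype=bool)
        mask[250:] = False
        fit = greml_fit(y[mask], X[mask], {"snp_additive": g[np.ix_(mask, mask)]})
        pred = gblup_predict(fit, {"snp_additive": g}, y, X, mask)

        perm = np.random.default_rng(10).permutation(300)
        gp = g[np.ix_(perm, perm)]
        pred_p = gblup_predict(fit, {"snp_additive": gp}, y[perm], X[perm], mask[perm])
        assert np.allclose(pred_p["total"], pred["total"][perm], atol=1e-10)


class TestPerLocusHeritability:
    def test_single_causal_snp_attains_max(self):
        hits = 0
        reps = 8
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            panel = simulate_genotypes(
                SimConfig(
                    n_individuals=500,
                    chromosomes=[("1", 3_000_000)],
                    snp_density=100,
                    ld_decay=0.3,
                    seed=200 + rep,
                )
            )
            mm = build_model_matrices(panel, components=("snp_additive",))
            g = build_grms(mm).a_g
            causal = 150
            w = mm.w_alpha[:, causal]
            y = w / w.std(ddof=1) * np.sqrt(0.3) + rng.standard_normal(500) * np.sqrt(0.7)
            X = np.ones((500, 1))
            fit = greml_fit(y, X, {"snp_additive": g})
            prof = per_locus_heritability(fit, mm, {"snp_additive": g}, y, X, panel.snp_map)
            top = int(prof["snp_additive"]["heritability"].idxmax())
            hits += abs(top - causal) <= 2  # tight-LD neighbors count
        assert hits >= reps - 1

    def test_per_snp_sum_bounded_by_component_heritability(self, additive_panel):
        panel, mm, g = additive_panel
        pheno, _ = simulate_phenotypes(panel, None, TraitArchitecture(additive=0.4), seed=11)
        X, _ = build_design(pheno, ["sex"], ["age"])
        y = pheno["y"].to_numpy()
        fit = greml_fit(y, X, {"snp_additive": g})
        prof = per_locus_heritability(fit, mm, {"snp_additive": g}, y, X, panel.snp_map)
        total = prof["snp_additive"]["heritability"].sum()
        assert total <= fit.heritabilities["snp_additive"] * 1.1

    def test_null_signal_gives_tiny_per_locus_values(self, additive_panel):
        panel, mm, g = additive_panel
        y = np.random.default_rng(12).standard_normal(300)
        X = np.ones((300, 1))
        fit = greml_fit(y, X, {"snp_additive": g})
        prof = per_locus_heritability(fit, mm, {"snp_additive": g}, y, X, panel.snp_map)
        assert prof["snp_additive"]["heritability"].max() < 1e-3
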