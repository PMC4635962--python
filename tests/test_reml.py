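"""AI-REML engine: closed-form and grid-search oracles, invariances, BLUPs."""

import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve

from crossvar import (
    ArchitectureSpec,
    ModelSpec,
    blup_effects,
    fit_aireml,
    simulate_phenotypes,
    variance_fractions,
)
from crossvar.kinship import additive_grm, hadamard_power


def reml_loglik_oracle(y, X, V):
    """Restricted log-likelihood, straight from the textbook formula."""
    cf = cho_factor(V, lower=True)
    ldV = 2 * np.sum(np.log(np.diag(cf[0])))
    ViX = cho_solve(cf, X)
    XtViX = X.T @ ViX
    Viy = cho_solve(cf, y)
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    Py = Viy - ViX @ beta
    return -0.5 * (ldV + np.linalg.slogdet(XtViX)[1] + y @ Py)


def test_balanced_oneway_matches_anova_estimators(rng):
    """Strain + error model on balanced duplicates equals the classical
    one-way random-effects ANOVA estimators (MSB-MSW)/r and MSW."""
    n, r = 120, 2
    strain_eff = rng.normal(0, np.sqrt(0.6), n)
    strain = np.repeat(np.arange(n), r)
    y = strain_eff[strain] + rng.normal(0, np.sqrt(0.4), n * r)

    fit = fit_aireml(
        ModelSpec(y=y, strain=strain, n_strains=n, K={}, include_strain_term=True),
        tol=1e-12,
    )
    ybar = y.reshape(n, r).mean(axis=1)
    msb = r * np.sum((ybar - ybar.mean()) ** 2) / (n - 1)
    msw = np.sum((y.reshape(n, r) - ybar[:, None]) ** 2) / (n * (r - 1))
    assert fit.sigma2["strain"] == pytest.approx((msb - msw) / r, abs=1e-6)
    assert fit.sigma2["error"] == pytest.approx(msw, abs=1e-6)


def test_aireml_beats_grid_search_oracle(small_panel):
    """The AI-REML optimum dominates a 21^3 grid over the variance simplex
    on a 150-strain two-GRM instance."""
    G = small_panel.subset_segregants(np.arange(150))
    A = additive_grm(G)
    AA = hadamard_power(A, 2)
    spec = ArchitectureSpec(6, 3, 0.35, H2_total=0.5, n_replicates=1, seed=5)
    pheno, _ = simulate_phenotypes(G, spec)
    y = pheno.value
    strain = pheno.strain
    ms = ModelSpec(
        y=y, strain=strain, n_strains=150, K={"a": A, "i": AA}, include_strain_term=False
    )
    fit = fit_aireml(ms, tol=1e-10)

    X = np.ones((150, 1))
    vy = y.var()
    grid = np.linspace(1e-4 * vy, 1.5 * vy, 21)
    best = -np.inf
    I = np.eye(150)
    for sa in grid:
        for si in grid:
            Vai = sa * A + si * AA
            for se in grid:
                best = max(best, reml_loglik_oracle(y, X, Vai + se * I))
    assert fit.loglik >= best - 1e-6
    # and the engine's loglik agrees with the oracle formula at its optimum
    Vhat = fit.sigma2["a"] * A + fit.sigma2["i"] * AA + fit.sigma2["error"] * I
    assert fit.loglik == pytest.approx(reml_loglik_oracle(y, X, Vhat), abs=1e-6)


def test_loglik_trace_monotone(small_panel, small_trait, small_kinship):
    pheno, _ = small_trait
    fit = fit_aireml(
        ModelSpec(
            y=pheno.value,
            strain=pheno.strain,
            n_strains=small_panel.n_segregants,
            K={"additive": small_kinship.A, "interaction": small_kinship.AA},
        )
    )
    assert fit.converged
    diffs = np.diff(fit.loglik_trace)
    assert (diffs >= -1e-8).all()


def test_shift_and_scale_invariance(small_panel, small_trait, small_kinship):
    pheno, _ = small_trait
    K = {"additive": small_kinship.A}
    n = small_panel.n_segregants

    def fit_sig(y):
        return fit_aireml(ModelSpec(y=y, strain=pheno.strain, n_strains=n, K=K), tol=1e-9)

    base = fit_sig(pheno.value)
    shifted = fit_sig(pheno.value + 100.0)
    scaled = fit_sig(pheno.value * 3.0)
    for c in base.sigma2:
        assert shifted.sigma2[c] == pytest.approx(base.sigma2[c], rel=1e-3, abs=1e-8)
        assert scaled.sigma2[c] == pytest.approx(9.0 * base.sigma2[c], rel=1e-3, abs=1e-8)
    assert shifted.beta[0] == pytest.approx(base.beta[0] + 100.0, abs=1e-6)


def test_constant_phenotype_is_degenerate_but_finite(small_panel, small_kinship):
    n = small_panel.n_segregants
    strain = np.repeat(np.arange(n), 2)
    y = np.full(2 * n, 3.14)
    fit = fit_aireml(
        ModelSpec(y=y, strain=strain, n_strains=n, K={"additive": small_kinship.A})
    )
    assert all(v <= 1e-10 for k, v in fit.sigma2.items())
    assert fit.beta[0] == pytest.approx(3.14)


def test_blup_zero_component_and_shrinkage_limit(small_panel, small_kinship, rng):
    n = small_panel.n_segregants
    A = small_kinship.A
    # near-deterministic trait: heritability ~ 1, tiny error
    g = np.linalg.cholesky(A + 1e-8 * np.eye(n)) @ rng.normal(size=n)
    strain = np.repeat(np.arange(n), 3)
    y = g[strain] + rng.normal(0, 1e-4, 3 * n)
    ms = ModelSpec(y=y, strain=strain, n_strains=n, K={"additive": A}, include_strain_term=False)
    fit = fit_aireml(ms, tol=1e-10)
    a_hat = blup_effects(fit, ms, "additive")
    ybar = y.reshape(n, 3).mean(axis=1)
    assert np.max(np.abs(a_hat - (ybar - fit.beta[0]))) < 1e-3

    fit0 = fit_aireml(
        ModelSpec(
            y=rng.normal(size=2 * n),
            strain=np.repeat(np.arange(n), 2),
            n_strains=n,
            K={"additive": A},
        )
    )
    if fit0.sigma2["additive"] <= 1e-9:
        ms0 = ModelSpec(
            y=np.zeros(2 * n), strain=np.repeat(np.arange(n), 2), n_strains=n, K={"additive": A}
        )
        assert np.allclose(
            blup_effects(fit0, ms0, "additive") / max(fit0.sigma2["additive"], 1), 0, atol=1e-6
        )


def test_blup_residuals_orthogonal_to_design(small_panel, small_trait, small_kinship):
    pheno, _ = small_trait
    n = small_panel.n_segregants
    ms = ModelSpec(
        y=pheno.value,
        strain=pheno.strain,
        n_strains=n,
        K={"additive": small_kinship.A, "interaction": small_kinship.AA},
    )
    fit = fit_aireml(ms)
    tot = sum(blup_effects(fit, ms, c) for c in ("additive", "interaction", "strain"))
    resid = pheno.value - ms.X @ fit.beta - tot[pheno.strain]
    assert np.max(np.abs(ms.X.T @ resid)) < 1e-6


def test_unbalanced_replicates_full_path(small_panel, small_trait, small_kinship):
    """Dropping observations (unbalanced design) still fits, via the full
    m-dimensional form, and lands near the balanced estimates."""
    pheno, _ = small_trait
    n = small_panel.n_segregants
    keep = np.ones(pheno.n_obs, dtype=bool)
    keep[::17] = False  # make ~6% of strains singletons
    K = {"additive": small_kinship.A, "interaction": small_kinship.AA}
    fit_b = fit_aireml(ModelSpec(y=pheno.value, strain=pheno.strain, n_strains=n, K=K))
    fit_u = fit_aireml(
        ModelSpec(y=pheno.value[keep], strain=pheno.strain[keep], n_strains=n, K=K)
    )
    assert fit_u.converged
    assert fit_u.fractions["additive"] == pytest.approx(fit_b.fractions["additive"], abs=0.06)


def test_variance_fractions_table(small_panel, small_trait, small_kinship):
    pheno, _ = small_trait
    fit = fit_aireml(
        ModelSpec(
            y=pheno.value,
            strain=pheno.strain,
            n_strains=small_panel.n_segregants,
            K={"additive": small_kinship.A},
        )
    )
    tab = variance_fractions(fit)
    assert tab["fraction"].sum() == pytest.approx(1.0)
    assert (tab["fraction"] >= 0).all()
    assert set(tab["component"]) == {"additive", "strain", "error"}


def test_parameter_recovery_known_fractions():
    """Recover (0.45, 0.10, 0.08, 0.37) on average over seeds at n=1000."""
    from crossvar import default_marker_map, simulate_genotypes
    from crossvar.kinship import build_kinship_set

    mm = default_marker_map(600, 16)
    G = simulate_genotypes(mm, 1000, seed=77)
    kin = build_kinship_set(G, loco=False)
    est = []
    for seed in range(8):
        spec = ArchitectureSpec(
            30, 15, 0.45, H2_total=0.55, strain_var=0.08, n_replicates=2, seed=1000 + seed
        )
        pheno, _ = simulate_phenotypes(G, spec)
        fit = fit_aireml(
            ModelSpec(
                y=pheno.value,
                strain=pheno.strain,
                n_strains=1000,
                K={"additive": kin.A, "interaction": kin.AA},
            )
        )
        est.append([fit.fractions[c] for c in ("additive", "interaction", "strain", "error")])
    mean = np.mean(est, axis=0)
    assert np.allclose(mean, [0.45, 0.10, 0.08, 0.37], atol=0.03)
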