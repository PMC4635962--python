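"""Variance captured by detected loci; ANOVA effect sizes; background controls."""

import numpy as np
import pytest

from crossvar import (
    ArchitectureSpec,
    anova_effect_sizes,
    background_control,
    captured_additive,
    interaction_partition,
    simulate_phenotypes,
)


def test_captured_additive_true_causal_set(medium_panel):
    spec = ArchitectureSpec(10, 0, 0.5, H2_total=0.5, strain_var=0.05, seed=9)
    pheno, truth = simulate_phenotypes(medium_panel, spec)
    n = medium_panel.n_segregants
    res = captured_additive(pheno.value, pheno.strain, n, medium_panel, truth.additive_loci)
    assert res["additive_qtl"] == pytest.approx(res["additive_genome"], abs=0.05)
    assert res["additive_qtl"] == pytest.approx(0.5, abs=0.05)


def test_captured_additive_all_markers_coincide(medium_panel):
    spec = ArchitectureSpec(10, 0, 0.4, H2_total=0.4, strain_var=0.05, seed=10)
    pheno, _ = simulate_phenotypes(medium_panel, spec)
    n = medium_panel.n_segregants
    res = captured_additive(
        pheno.value, pheno.strain, n, medium_panel, np.arange(medium_panel.n_markers)
    )
    assert res["additive_qtl"] == pytest.approx(res["additive_genome"], abs=1e-6)


def test_random_peaks_capture_little(medium_panel):
    spec = ArchitectureSpec(10, 0, 0.5, H2_total=0.5, strain_var=0.05, seed=11)
    pheno, truth = simulate_phenotypes(medium_panel, spec)
    n = medium_panel.n_segregants
    rng = np.random.default_rng(12)
    decoys = rng.choice(
        np.setdiff1d(np.arange(medium_panel.n_markers), truth.additive_loci), 10, replace=False
    )
    res_true = captured_additive(pheno.value, pheno.strain, n, medium_panel, truth.additive_loci)
    res_decoy = captured_additive(pheno.value, pheno.strain, n, medium_panel, decoys)
    assert res_decoy["additive_qtl"] < 0.5 * res_true["additive_qtl"]


def test_background_control_below_true_capture(medium_panel):
    spec = ArchitectureSpec(10, 0, 0.5, H2_total=0.5, seed=13)
    pheno, truth = simulate_phenotypes(medium_panel, spec)
    n = medium_panel.n_segregants
    y_avg = pheno.value.reshape(n, 2).mean(axis=1)
    med = background_control(y_avg, medium_panel, N=10, n_draws=10, seed=14)
    res_true = captured_additive(pheno.value, pheno.strain, n, medium_panel, truth.additive_loci)
    assert med < 0.3 * res_true["additive_qtl"]
    med2 = background_control(y_avg, medium_panel, N=10, n_draws=10, seed=14)
    assert med == med2  # same seed, same draws
    with pytest.raises(ValueError):
        background_control(y_avg, medium_panel, N=0)


def test_interaction_partition_contrast(medium_panel, medium_kinship):
    """Interactions among additive QTL load on the QTL x QTL GRM; interactions
    among non-additive loci do not."""
    n = medium_panel.n_segregants
    # all pairs among additive QTL
    spec_in = ArchitectureSpec(10, 10, 0.40, H2_total=0.60, strain_var=0.0, seed=15)
    pheno, truth = simulate_phenotypes(medium_panel, spec_in)
    row = interaction_partition(
        pheno.value,
        pheno.strain,
        n,
        medium_panel,
        medium_kinship,
        truth.additive_loci,
        truth.interacting_pairs,
    )
    assert row["qtl_x_qtl"] >= 0.8 * row["genome_x_genome"]
    assert row["sig_pairs_over_genome"] > 0.5

    # interactions only among non-additive loci: simulate 2 additive QTL with
    # tiny additive share and pairs placed away from them
    spec_out = ArchitectureSpec(2, 20, 0.01, H2_total=0.41, strain_var=0.0, seed=16)
    pheno2, truth2 = simulate_phenotypes(medium_panel, spec_out)
    non_add_pairs = truth2.interacting_pairs[~np.isin(
        truth2.interacting_pairs, truth2.additive_loci
    ).any(axis=1)]
    assert len(non_add_pairs) >= 15
    decoy_qtl = np.array([5, 300, 700])  # not the interacting loci
    row2 = interaction_partition(
        pheno2.value, pheno2.strain, n, medium_panel, medium_kinship, decoy_qtl
    )
    assert row2["genome_x_genome"] > 0.2
    assert row2["qtl_x_qtl"] < 0.1


def test_anova_single_marker_five_percent():
    rng = np.random.default_rng(17)
    n = 4000
    g = rng.choice([-1.0, 1.0], size=n)
    y = np.sqrt(0.05) * g + rng.normal(0, np.sqrt(0.95), n)
    tab = anova_effect_sizes(y, g[:, None])
    assert tab["fraction"].iloc[0] == pytest.approx(0.05, abs=0.01)


def test_anova_aliased_column_gets_zero():
    rng = np.random.default_rng(18)
    g = rng.choice([-1.0, 1.0], size=500)
    y = g + rng.normal(0, 1, 500)
    with pytest.warns(UserWarning):
        tab = anova_effect_sizes(y, np.column_stack([g, g]))
    assert tab["fraction"].iloc[1] == 0.0
    assert bool(tab["aliased"].iloc[1])


def test_anova_null_total_r2_near_k_over_n():
    rng = np.random.default_rng(19)
    n, k = 2000, 10
    X = rng.choice([-1.0, 1.0], size=(n, k))
    y = rng.normal(size=n)
    tab = anova_effect_sizes(y, X)
    assert tab["fraction"].sum() == pytest.approx(k / n, abs=3 * k / n)


def test_anova_fractions_sum_to_model_r2(medium_panel):
    spec = ArchitectureSpec(5, 2, 0.4, H2_total=0.5, seed=20)
    pheno, truth = simulate_phenotypes(medium_panel, spec)
    n = medium_panel.n_segregants
    y_avg = pheno.value.reshape(n, 2).mean(axis=1)
    X = medium_panel.dosage()[:, truth.additive_loci]
    P = (
        medium_panel.dosage()[:, truth.interacting_pairs[:, 0]]
        * medium_panel.dosage()[:, truth.interacting_pairs[:, 1]]
    )
    tab = anova_effect_sizes(y_avg, X, P)
    # independent R^2 via ordinary least squares
    D = np.column_stack([np.ones(n), X, P])
    beta, *_ = np.linalg.lstsq(D, y_avg, rcond=None)
    resid = y_avg - D @ beta
    ss_tot = np.sum((y_avg - y_avg.mean()) ** 2)
    r2 = 1 - resid @ resid / ss_tot
    assert tab["fraction"].sum() == pytest.approx(r2, abs=1e-8)


def test_anova_matches_statsmodels_type1(medium_panel):
    """Sequential SS agrees with statsmodels' type-I ANOVA on the same model."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(21)
    n = 300
    x1 = rng.choice([-1.0, 1.0], n)
    x2 = rng.choice([-1.0, 1.0], n)
    y = 0.5 * x1 + 0.3 * x2 + rng.normal(0, 1, n)
    tab = anova_effect_sizes(y, np.column_stack([x1, x2]))
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    sm_tab = sm.stats.anova_lm(ols("y ~ x1 + x2", df).fit(), typ=1)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert tab["fraction"].iloc[0] == pytest.approx(sm_tab["sum_sq"]["x1"] / ss_tot, rel=1e-6)
    assert tab["fraction"].iloc[1] == pytest.approx(sm_tab["sum_sq"]["x2"] / ss_tot, rel=1e-6)
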