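"""GRM construction: additive, Hadamard powers, LOCO, marker subsets."""

import numpy as np
import pytest

from crossvar import (
    GenotypeMatrix,
    MarkerMap,
    additive_grm,
    cross_subset_grm,
    hadamard_power,
    loco_grms,
    pair_product_grm,
)
from crossvar.kinship import build_kinship_set


def _tiny(vals):
    vals = np.asarray(vals, dtype=np.int8)
    M = vals.shape[1]
    return GenotypeMatrix(vals, MarkerMap(np.ones(M, dtype=int), np.arange(1, M + 1) * 100))


def test_additive_grm_identical_and_opposite():
    G = _tiny([[1, -1, 1, 1], [1, -1, 1, 1], [-1, 1, -1, -1]])
    A = additive_grm(G)
    assert np.allclose(np.diag(A), 1.0)
    assert A[0, 1] == pytest.approx(1.0)
    assert A[0, 2] == pytest.approx(-1.0)


def test_additive_grm_independent_rows_near_zero(rng):
    vals = rng.choice([-1, 1], size=(4, 10000)).astype(np.int8)
    G = GenotypeMatrix(vals, MarkerMap(np.ones(10000, dtype=int), np.arange(10000) + 1))
    A = additive_grm(G)
    off = A[~np.eye(4, dtype=bool)]
    assert np.abs(off).max() < 0.05  # ~5 binomial s.d. at M=10,000


def test_hadamard_power_values_and_psd(small_panel):
    A = additive_grm(small_panel)
    AA = hadamard_power(A, 2)
    assert np.allclose(AA, A**2)
    assert AA[0, 1] == pytest.approx(A[0, 1] ** 2)
    AAA = hadamard_power(A, 3)
    assert AAA[0, 1] == pytest.approx(A[0, 1] ** 3)
    assert np.linalg.eigvalsh(AA).min() >= -1e-8
    with pytest.raises(ValueError):
        hadamard_power(A, 4)


def test_grm_weighted_average_identity(small_panel):
    """A over the marker union is the size-weighted average over subsets."""
    M = small_panel.n_markers
    idx1, idx2 = np.arange(0, 120), np.arange(120, M)
    A = additive_grm(small_panel)
    A1 = additive_grm(small_panel, idx1)
    A2 = additive_grm(small_panel, idx2)
    weighted = (len(idx1) * A1 + len(idx2) * A2) / M
    assert np.allclose(A, weighted)


def test_loco_grms_exact_subtraction(small_panel):
    locos = loco_grms(small_panel)
    mm = small_panel.map
    for c in mm.chromosomes[:3]:
        keep = np.flatnonzero(mm.chromosome != c)
        assert np.allclose(locos[int(c)], additive_grm(small_panel, keep))


def test_hadamard_square_is_pairs_of_markers_shared(rng):
    """(A o A)_jk equals the all-pairs-of-markers product average at M<=50."""
    vals = rng.choice([-1, 1], size=(6, 20)).astype(np.int8)
    G = GenotypeMatrix(vals, MarkerMap(np.ones(20, dtype=int), np.arange(20) + 1))
    A = additive_grm(G)
    AA = hadamard_power(A, 2)
    X = G.dosage()
    M = 20
    for j, k in [(0, 1), (2, 5), (3, 3)]:
        brute = sum(
            (X[j, l] * X[k, l]) * (X[j, l2] * X[k, l2]) for l in range(M) for l2 in range(M)
        ) / M**2
        assert AA[j, k] == pytest.approx(brute)


def test_cross_subset_grm_reductions(small_panel):
    A = additive_grm(small_panel)
    allm = np.arange(small_panel.n_markers)
    assert np.allclose(cross_subset_grm(small_panel, allm, "qtl_by_genome"), A * A)
    one = cross_subset_grm(small_panel, [7], "qtl_by_qtl")
    assert np.allclose(one, 1.0)  # (+/-1)^2
    with pytest.raises(ValueError):
        cross_subset_grm(small_panel, [], "qtl_by_qtl")
    with pytest.raises(ValueError):
        cross_subset_grm(small_panel, [10**6], "qtl_by_qtl")


def test_cross_subset_matches_bruteforce_pairs(rng):
    vals = rng.choice([-1, 1], size=(50, 12)).astype(np.int8)
    G = GenotypeMatrix(vals, MarkerMap(np.ones(12, dtype=int), np.arange(12) + 1))
    subset = np.array([1, 3, 5, 8, 11])
    K = cross_subset_grm(G, subset, "qtl_by_qtl")
    X = G.dosage()[:, subset]
    S = len(subset)
    # direct definition: (A_sub o A_sub)_jk = (1/S^2) sum_{l,l2} x_jl x_kl x_jl2 x_kl2
    for j in range(0, 50, 17):
        for k in range(0, 50, 13):
            val = sum(
                X[j, l] * X[k, l] * X[j, l2] * X[k, l2] for l in range(S) for l2 in range(S)
            ) / S**2
            assert K[j, k] == pytest.approx(val)


def test_pair_product_grm_properties(small_panel, rng):
    pairs = [(0, 60), (10, 200), (5, 290)]
    K = pair_product_grm(small_panel, pairs)
    assert np.allclose(np.diag(K), 1.0)
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-8
    one = pair_product_grm(small_panel, [(3, 40)])
    assert np.linalg.matrix_rank(one) == 1
    assert np.isin(one, [-1.0, 1.0]).all()
    with pytest.warns(UserWarning):
        K2 = pair_product_grm(small_panel, [(0, 60), (60, 0), (10, 200), (5, 290)])
    assert np.allclose(K, K2)
    with pytest.raises(ValueError):
        pair_product_grm(small_panel, [(4, 4)])


def test_pair_product_all_pairs_vs_hadamard_square(rng):
    """On tiny M, the all-pairs product GRM equals A o A up to the
    same-marker 'pair' diagonal term that the Hadamard square includes."""
    vals = rng.choice([-1, 1], size=(20, 8)).astype(np.int8)
    G = GenotypeMatrix(vals, MarkerMap(np.ones(8, dtype=int), np.arange(8) + 1))
    M = 8
    pairs = [(j, k) for j in range(M) for k in range(j + 1, M)]
    QQ = pair_product_grm(G, pairs)  # (1/q) sum over j<k of products
    AA = hadamard_power(additive_grm(G), 2)
    A = additive_grm(G)
    # AA = (1/M^2)[ 2 * sum_{j<k} prod + M * A_jk^0-term ]: same-marker pairs
    # contribute (1/M^2) * M * 1 on ... off-diagonal the same-marker terms give
    # (1/M) * 1 only on entries where x_jl x_kl squared = 1 -> constant 1/M
    q = len(pairs)
    reconstructed = (2 * q * QQ / M**2) + np.ones((20, 20)) / M
    assert np.allclose(AA, reconstructed)


def test_build_kinship_set(small_panel):
    ks = build_kinship_set(small_panel, cube=True)
    assert set(ks.A_loco) == set(int(c) for c in small_panel.map.chromosomes)
    assert np.allclose(ks.AA, ks.A**2)
    assert np.allclose(ks.AAA, ks.A**3)
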