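"""Genomic relationship matrices (GRMs) for +/-1-coded biparental crosses.

The additive GRM is the raw cross-product A = (1/M) G G^T on the +/-1 codes:
with balanced allele frequencies (p ~ 0.5 in a cross) this differs from an
allele-frequency-centred GRM only by an affine map absorbed by the model
intercept and variance scale, while making "fraction of genome shared" equal
to (A + 1)/2 and keeping Hadamard identities exact: the entrywise square
A o A equals the fraction-of-marker-pairs-shared matrix that models pairwise
epistatic covariance, and the entrywise cube models three-way interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from crossvar.simulate import GenotypeMatrix

__all__ = [
    "KinshipSet",
    "additive_grm",
    "hadamard_power",
    "loco_grms",
    "cross_subset_grm",
    "pair_product_grm",
    "build_kinship_set",
]


def additive_grm(G: GenotypeMatrix, marker_subset=None) -> np.ndarray:
    """Additive GRM A_jk = (1/|S|) sum_{l in S} g_jl g_kl.

    Entries lie in [-1, 1]; the diagonal is exactly 1 under the +/-1 coding.
    ``marker_subset`` restricts the sum to a marker index set S (default: all
    markers).
    """
    if marker_subset is not None:
        marker_subset = np.asarray(marker_subset)
        if marker_subset.size == 0:
            raise ValueError("marker subset must be non-empty")
        X = G.dosage()[:, marker_subset]
    else:
        X = G.dosage()
    A = (X @ X.T) / X.shape[1]
    return (A + A.T) / 2.0


def hadamard_power(A: np.ndarray, k: int) -> np.ndarray:
    """Entrywise k-th power of a GRM (k = 2 pairwise, k = 3 three-way).

    By the Schur product theorem the entrywise power of a PSD matrix is PSD;
    symmetry is preserved trivially.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    return A**k


def loco_grms(G: GenotypeMatrix) -> dict[int, np.ndarray]:
    """Leave-one-chromosome-out additive GRMs, one per chromosome.

    Uses the exact identity that the all-marker GRM is the marker-count
    weighted average of per-chromosome GRMs: each LOCO GRM is obtained by
    subtracting the focal chromosome's cross-product from the genome total.
    """
    X = G.dosage()
    M = G.n_markers
    total = X @ X.T
    out: dict[int, np.ndarray] = {}
    for c in G.map.chromosomes:
        cols = G.map.chrom_slice(c)
        if cols.size == M:
            raise ValueError("cannot leave out the only chromosome")
        Xc = X[:, cols]
        A = (total - Xc @ Xc.T) / (M - cols.size)
        out[int(c)] = (A + A.T) / 2.0
    return out


def cross_subset_grm(G: GenotypeMatrix, subset, mode: str) -> np.ndarray:
    """Interaction GRMs built from a marker subset (typically QTL peaks).

    mode="qtl_by_qtl" gives A_QTL o A_QTL (pairwise interactions within the
    subset); mode="qtl_by_genome" gives A_QTL o A (interactions between the
    subset and the whole genome). No normalisation beyond the constituent
    GRMs is applied.
    """
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("marker subset must be non-empty")
    if subset.min() < 0 or subset.max() >= G.n_markers:
        raise ValueError("subset indices out of range")
    A_sub = additive_grm(G, subset)
    if mode == "qtl_by_qtl":
        return A_sub * A_sub
    if mode == "qtl_by_genome":
        return A_sub * additive_grm(G)
    raise ValueError(f"unknown mode {mode!r}")


def pair_product_grm(G: GenotypeMatrix, pairs) -> np.ndarray:
    """GRM over explicit marker pairs: columns are products g_j * g_k.

    Builds the n x q matrix P of per-pair genotype products and returns
    (1/q) P P^T; its diagonal is 1 because the products are +/-1 variables.
    Duplicate pairs are dropped with a warning. Self-pairs (j == k) are not
    allowed.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size == 0:
        raise ValueError("pairs must be non-empty")
    if np.any(pairs[:, 0] == pairs[:, 1]):
        raise ValueError("self-pairs are not allowed")
    canon = np.sort(pairs, axis=1)
    uniq, first = np.unique(canon, axis=0, return_index=True)
    if uniq.shape[0] < pairs.shape[0]:
        warnings.warn("duplicate marker pairs dropped", stacklevel=2)
    canon = canon[np.sort(first)]
    X = G.dosage()
    P = X[:, canon[:, 0]] * X[:, canon[:, 1]]
    K = (P @ P.T) / canon.shape[0]
    return (K + K.T) / 2.0


@dataclass
class KinshipSet:
    """The relatedness matrices used by the variance models.

    A is the additive GRM, AA its Hadamard square (pairwise epistasis), AAA
    the optional Hadamard cube (three-way), A_loco the per-chromosome
    leave-one-chromosome-out additive GRMs, and ``subsets`` holds named
    marker-subset GRMs (A_QTL, A_QTL o A_QTL, A_QTL o A, QQ, random-subset
    controls).
    """

    A: np.ndarray
    AA: np.ndarray
    AAA: np.ndarray | None = None
    A_loco: dict[int, np.ndarray] = field(default_factory=dict)
    subsets: dict[str, np.ndarray] = field(default_factory=dict)


def build_kinship_set(
    G: GenotypeMatrix, loco: bool = True, cube: bool = False
) -> KinshipSet:
    """Compute A, A o A (optionally the cube) and LOCO GRMs in one pass."""
    A = additive_grm(G)
    return KinshipSet(
        A=A,
        AA=hadamard_power(A, 2),
        AAA=hadamard_power(A, 3) if cube else None,
        A_loco=loco_grms(G) if loco else {},
    )
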