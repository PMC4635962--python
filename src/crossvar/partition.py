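"""Variance captured by detected loci and by marker-subset interaction GRMs.

Quantifies how much of the genome-wide additive and pairwise-interaction
variance is accounted for by the loci a scan actually found: the additive
model is refit with a GRM built only from QTL peak markers (A_QTL) and
compared with the all-marker fit; interaction variance is partitioned by
swapping the genome-wide Hadamard GRM A o A for A_QTL o A_QTL (pairs within
detected QTL), A_QTL o A (detected QTL x genome) or QQ (explicit significant
pairs). Background-linkage controls repeat the fits over random marker draws,
and per-term ANOVA effect sizes come from sequential sums of squares over a
fixed-effect multiple regression on peak markers and pair products.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from crossvar.kinship import (
    KinshipSet,
    additive_grm,
    cross_subset_grm,
    pair_product_grm,
)
from crossvar.reml import ModelSpec, fit_aireml
from crossvar.simulate import GenotypeMatrix

__all__ = [
    "captured_additive",
    "interaction_partition",
    "background_control",
    "anova_effect_sizes",
]


def captured_additive(
    y: np.ndarray,
    strain: np.ndarray,
    n_strains: int,
    G: GenotypeMatrix,
    qtl_peaks,
) -> dict:
    """Additive variance fraction captured by QTL peak markers vs all markers.

    Fits y = Xb + Za + Zp + e twice: once with the additive GRM restricted to
    the peak markers (A_QTL) and once with the all-marker GRM (A). Returns
    both additive fractions with standard errors.
    """
    qtl_peaks = np.asarray(qtl_peaks, dtype=np.int64)
    if qtl_peaks.size == 0:
        raise ValueError("qtl_peaks must be non-empty")
    out = {}
    for label, subset in (("qtl", qtl_peaks), ("genome", None)):
        K = {"additive": additive_grm(G, subset)}
        fit = fit_aireml(ModelSpec(y=y, strain=strain, n_strains=n_strains, K=K))
        out[f"additive_{label}"] = fit.fractions["additive"]
        out[f"additive_{label}_se"] = fit.fractions_se["additive"]
        out[f"converged_{label}"] = fit.converged
    return out


def interaction_partition(
    y: np.ndarray,
    strain: np.ndarray,
    n_strains: int,
    G: GenotypeMatrix,
    kin: KinshipSet,
    qtl_peaks,
    sig_pairs=None,
) -> dict:
    """Interaction variance fractions under marker-subset GRM variants.

    Fits y = Xb + Za + Zi + Zp + e with the interaction GRM set to, in turn:
    the genome-wide Hadamard square (genome x genome), A_QTL o A
    (QTL x genome), A_QTL o A_QTL (QTL x QTL) and, when significant pairs are
    supplied, the pair-product GRM QQ. The ratio of the QQ (or QTL x QTL)
    fraction to the genome x genome fraction measures how much of the
    interaction variance the detected loci explain.
    """
    qtl_peaks = np.asarray(qtl_peaks, dtype=np.int64)
    variants: dict[str, np.ndarray] = {"genome_x_genome": kin.AA}
    if qtl_peaks.size:
        variants["qtl_x_genome"] = cross_subset_grm(G, qtl_peaks, "qtl_by_genome")
        variants["qtl_x_qtl"] = cross_subset_grm(G, qtl_peaks, "qtl_by_qtl")
    if sig_pairs is not None and len(sig_pairs):
        variants["sig_pairs"] = pair_product_grm(G, sig_pairs)
    row: dict = {}
    for label, Ki in variants.items():
        K = {"additive": kin.A, "interaction": Ki}
        fit = fit_aireml(ModelSpec(y=y, strain=strain, n_strains=n_strains, K=K))
        row[label] = fit.fractions["interaction"]
        row[f"{label}_se"] = fit.fractions_se["interaction"]
    gg = row.get("genome_x_genome", 0.0)
    if gg > 0:
        if "qtl_x_qtl" in row:
            row["qtl_x_qtl_over_genome"] = row["qtl_x_qtl"] / gg
        if "sig_pairs" in row:
            row["sig_pairs_over_genome"] = row["sig_pairs"] / gg
    return row


def _sample_separated_pairs(rng, M, n_pairs, min_separation):
    pairs = []
    guard = 0
    while len(pairs) < n_pairs:
        j, k = rng.choice(M, size=2, replace=False)
        if abs(int(j) - int(k)) >= min_separation:
            pairs.append((min(j, k), max(j, k)))
        guard += 1
        if guard > 1000 * n_pairs:
            raise ValueError("cannot sample enough separated pairs")
    return np.array(pairs, dtype=np.int64)


def background_control(
    y_avg: np.ndarray,
    G: GenotypeMatrix,
    N: int,
    n_draws: int = 50,
    seed: int | None = None,
    family: str = "additive",
    min_separation: int = 50,
) -> float:
    """Median variance fraction captured by random marker (or pair) subsets.

    Estimates the background-linkage baseline: ``n_draws`` times, draw N
    random markers (family="additive") or N random pairs with the usual
    separation rule (family="pairs"), build the corresponding GRM, fit the
    reduced strain-mean model (no repeatability term) and record the captured
    fraction; the median over draws is returned.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > G.n_markers:
        raise ValueError("N exceeds the number of markers")
    rng = np.random.default_rng(seed)
    n = y_avg.size
    strain = np.arange(n)
    fracs = []
    A_all = additive_grm(G) if family == "pairs" else None
    for _ in range(n_draws):
        if family == "additive":
            subset = rng.choice(G.n_markers, size=N, replace=False)
            K = {"subset": additive_grm(G, subset)}
            target = "subset"
        elif family == "pairs":
            pairs = _sample_separated_pairs(rng, G.n_markers, N, min_separation)
            K = {"additive": A_all, "subset": pair_product_grm(G, pairs)}
            target = "subset"
        else:
            raise ValueError(f"unknown family {family!r}")
        fit = fit_aireml(
            ModelSpec(
                y=y_avg,
                strain=strain,
                n_strains=n,
                K=K,
                include_strain_term=False,
            )
        )
        fracs.append(fit.fractions[target])
    return float(np.median(fracs))


def anova_effect_sizes(
    y_avg: np.ndarray,
    peak_columns: np.ndarray | None,
    pair_product_columns: np.ndarray | None = None,
    term_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-term variance fractions by sequential (entry-order) sums of squares.

    Terms enter in the order given: additive peak-marker columns first, then
    pair-product columns. Each term's fraction is its sequential sum of
    squares divided by the total sum of squares of the (strain-averaged)
    phenotype. Columns aliased with earlier terms get a zero sum of squares
    and a warning.
    """
    cols = []
    names = []
    if peak_columns is not None and np.size(peak_columns):
        pc = np.atleast_2d(np.asarray(peak_columns, dtype=float))
        if pc.shape[0] != y_avg.size:
            pc = pc.T
        cols.append(pc)
        names += [f"qtl_{i}" for i in range(pc.shape[1])]
    if pair_product_columns is not None and np.size(pair_product_columns):
        qc = np.atleast_2d(np.asarray(pair_product_columns, dtype=float))
        if qc.shape[0] != y_avg.size:
            qc = qc.T
        cols.append(qc)
        names += [f"pair_{i}" for i in range(qc.shape[1])]
    if not cols:
        raise ValueError("no model terms supplied")
    D = np.hstack(cols)
    if term_names is not None:
        if len(term_names) != D.shape[1]:
            raise ValueError("term_names length mismatch")
        names = list(term_names)

    y = np.asarray(y_avg, dtype=float)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    n = y.size
    # incremental Gram-Schmidt against the columns accepted so far
    Q: list[np.ndarray] = [np.full(n, 1.0 / np.sqrt(n))]
    rows = []
    for name, col in zip(names, D.T):
        v = col.astype(float).copy()
        for q in Q:
            v -= (q @ v) * q
        norm = np.linalg.norm(v)
        if norm < 1e-8 * max(np.linalg.norm(col), 1.0):
            warnings.warn(f"term {name} is aliased with earlier terms; dropped", stacklevel=2)
            rows.append((name, 0.0, 0.0, True))
            continue
        q = v / norm
        ss = float((q @ yc) ** 2)
        Q.append(q)
        rows.append((name, ss, ss / ss_total if ss_total > 0 else 0.0, False))
    return pd.DataFrame(rows, columns=["term", "ss", "fraction", "aliased"])
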