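"""Additive QTL mapping by forward search on LOCO BLUP residuals.

For each chromosome, the polygenic model is refit with the additive GRM
computed from all other chromosomes (leave one chromosome out, LOCO) plus the
genome-wide pairwise-interaction GRM and the strain-repeatability term. BLUP
residuals — phenotypes minus the predicted polygenic and interaction
contributions (and minus any fixed peak-marker effects already conditioned
on) — are averaged per strain and scanned marker by marker with

    LOD = -n ln(1 - r^2) / (2 ln 10),

where r is the Pearson correlation between the marker genotypes and the
residuals. Family-wise error is controlled per chromosome and per round by
permuting residuals against strain assignments and recording the chromosome-
wide maximum LOD. Significant peaks are added to the fixed effects and the
procedure repeats until no marker passes the recomputed threshold; support
intervals are 1.5-LOD drops around each peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossvar.kinship import KinshipSet
from crossvar.reml import ModelSpec, blup_effects, fit_aireml
from crossvar.simulate import GenotypeMatrix

__all__ = [
    "AdditiveQtl",
    "ScanContext",
    "loco_residuals",
    "lod_scan",
    "permutation_fwer_threshold",
    "forward_search",
    "lod_support_interval",
]

_LN10_2 = 2.0 * math.log(10.0)


@dataclass
class AdditiveQtl:
    """One genome-wide significant additive QTL."""

    trait: str
    chromosome: int
    peak_marker: int
    peak_bp: int
    lod: float
    threshold: float
    ci_left: int
    ci_right: int
    ci_left_bp: int
    ci_right_bp: int
    round_added: int
    variance_explained: float | None = None


@dataclass
class ScanContext:
    """Per-strain averaged BLUP residuals ready for a chromosome scan."""

    residuals: np.ndarray
    chromosome: int
    fixed_markers: list[int] = field(default_factory=list)
    source: str = ""
    converged: bool = True


def _derive_seed(base_seed, *parts) -> int:
    """Deterministic per-(trait, chromosome, round) seed below 2**31."""
    import zlib

    key = repr((int(base_seed) if base_seed is not None else 0,) + parts).encode()
    return zlib.crc32(key) % (2**31)


def loco_residuals(
    y: np.ndarray,
    strain: np.ndarray,
    n_strains: int,
    kin: KinshipSet,
    chrom: int,
    G: GenotypeMatrix | None = None,
    fixed_markers: list[int] | None = None,
) -> ScanContext:
    """BLUP residuals for scanning one chromosome.

    Fits components (A_loco, A o A, strain, error) with fixed effects
    [intercept, genotype columns of ``fixed_markers``], subtracts the
    additive-LOCO and interaction BLUPs plus the fixed marker effects, and
    averages per strain. The interaction GRM stays genome-wide: only the
    additive polygenic term is made LOCO.
    """
    if chrom not in kin.A_loco:
        raise KeyError(f"chromosome {chrom} not present in the LOCO kinship set")
    fixed_markers = list(fixed_markers or [])
    m = np.asarray(y).size
    X = np.ones((m, 1))
    if fixed_markers:
        if G is None:
            raise ValueError("fixed_markers require the genotype matrix")
        Xm = G.dosage()[:, fixed_markers][np.asarray(strain)]
        X = np.hstack([X, Xm])
    K = {"additive_loco": kin.A_loco[chrom], "interaction": kin.AA}
    spec = ModelSpec(y=y, strain=strain, n_strains=n_strains, K=K, X=X)
    fit = fit_aireml(spec)
    a_loco = blup_effects(fit, spec, "additive_loco")
    i_hat = blup_effects(fit, spec, "interaction")
    resid = np.asarray(y, dtype=float) - (a_loco + i_hat)[np.asarray(strain)]
    if fixed_markers:
        resid -= (X[:, 1:] @ fit.beta[1:]).ravel()
    counts = np.bincount(np.asarray(strain), minlength=n_strains).astype(float)
    avg = np.bincount(np.asarray(strain), weights=resid, minlength=n_strains) / np.maximum(
        counts, 1.0
    )
    return ScanContext(
        residuals=avg,
        chromosome=int(chrom),
        fixed_markers=fixed_markers,
        source="loco additive+interaction BLUP residuals",
        converged=fit.converged,
    )


def _corr_with_columns(Gcols: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlations between each genotype column and each column of Y."""
    Gs = Gcols - Gcols.mean(axis=0)
    gn = np.linalg.norm(Gs, axis=0)
    gn[gn == 0] = np.inf  # constant marker -> correlation 0
    Ys = Y - Y.mean(axis=0)
    yn = np.linalg.norm(Ys, axis=0)
    yn[yn == 0] = np.inf
    return (Gs.T @ Ys) / np.outer(gn, yn)


def lod_from_r2(r2: np.ndarray, n: int) -> np.ndarray:
    """LOD = -n ln(1 - r^2) / (2 ln 10), with r^2 capped just below 1."""
    r2 = np.minimum(r2, 1.0 - 1e-12)
    return -n * np.log1p(-r2) / _LN10_2


def lod_scan(context: ScanContext, G_chrom: np.ndarray) -> np.ndarray:
    """Single-marker LOD scores on one chromosome's genotype columns."""
    y_r = context.residuals
    n = y_r.size
    if n < 3:
        raise ValueError("need at least 3 strains")
    if np.std(y_r) == 0:
        warnings.warn("constant residuals: returning all-zero LODs", stacklevel=2)
        return np.zeros(G_chrom.shape[1])
    r = _corr_with_columns(np.asarray(G_chrom, dtype=float), y_r[:, None])[:, 0]
    return lod_from_r2(r**2, n)


def permutation_fwer_threshold(
    context: ScanContext,
    G_chrom: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Empirical FWER threshold from chromosome-wide permutation maxima.

    Residuals are permuted against strain assignments; the chromosome-wide
    maximum LOD is recorded per permutation and the threshold is the
    ceil((1 - alpha) * n_perm)-th smallest maximum.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    y_r = context.residuals
    n = y_r.size
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = y_r[rng.permutation(n)]
    R = _corr_with_columns(np.asarray(G_chrom, dtype=float), perms)
    maxima = lod_from_r2(R**2, n).max(axis=0)
    k = int(np.ceil((1.0 - alpha) * n_perm))
    return float(np.sort(maxima)[k - 1])


def lod_support_interval(lods: np.ndarray, peak: int, drop: float = 1.5) -> tuple[int, int]:
    """Widest contiguous run around the peak with LOD >= peak LOD - drop."""
    cut = lods[peak] - drop
    left = peak
    while left > 0 and lods[left - 1] >= cut:
        left -= 1
    right = peak
    while right < lods.size - 1 and lods[right + 1] >= cut:
        right += 1
    return left, right


def forward_search(
    y: np.ndarray,
    strain: np.ndarray,
    n_strains: int,
    kin: KinshipSet,
    G: GenotypeMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    trait: str = "trait",
    max_rounds: int = 30,
) -> list[AdditiveQtl]:
    """Forward stepwise additive QTL search over all chromosomes.

    Per chromosome: compute LOCO BLUP residuals conditioning on the peaks
    found so far, scan, recompute the permutation threshold on the current
    residuals, and add the chromosome maximum if it passes; repeat until no
    marker is significant. Ties in LOD break to the lowest marker index.
    """
    qtl: list[AdditiveQtl] = []
    Gd = G.dosage()
    for chrom in G.map.chromosomes:
        cols = G.map.chrom_slice(chrom)
        Gc = Gd[:, cols]
        fixed: list[int] = [q.peak_marker for q in qtl]
        for rnd in range(1, max_rounds + 1):
            ctx = loco_residuals(y, strain, n_strains, kin, int(chrom), G, fixed)
            lods = lod_scan(ctx, Gc)
            thr = permutation_fwer_threshold(
                ctx,
                Gc,
                n_perm=n_perm,
                alpha=alpha,
                seed=_derive_seed(seed, trait, int(chrom), rnd),
            )
            peak_local = int(np.argmax(lods))  # argmax takes the first (lowest index) tie
            if lods[peak_local] <= thr:
                break
            lo, hi = lod_support_interval(lods, peak_local)
            q = AdditiveQtl(
                trait=trait,
                chromosome=int(chrom),
                peak_marker=int(cols[peak_local]),
                peak_bp=int(G.map.position_bp[cols[peak_local]]),
                lod=float(lods[peak_local]),
                threshold=thr,
                ci_left=int(cols[lo]),
                ci_right=int(cols[hi]),
                ci_left_bp=int(G.map.position_bp[cols[lo]]),
                ci_right_bp=int(G.map.position_bp[cols[hi]]),
                round_added=rnd,
            )
            qtl.append(q)
            fixed.append(q.peak_marker)
        else:
            warnings.warn(
                f"chromosome {chrom}: round cap {max_rounds} reached", stacklevel=2
            )
    return qtl


def qtl_table(qtl: list[AdditiveQtl]) -> pd.DataFrame:
    """Detected-QTL table in the on-disk TSV layout."""
    return pd.DataFrame(
        [
            {
                "trait": q.trait,
                "chrom": q.chromosome,
                "peak_marker": q.peak_marker,
                "peak_bp": q.peak_bp,
                "LOD": q.lod,
                "threshold": q.threshold,
                "CI_left_bp": q.ci_left_bp,
                "CI_right_bp": q.ci_right_bp,
                "round": q.round_added,
                "variance_explained": q.variance_explained,
            }
            for q in qtl
        ]
    )
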