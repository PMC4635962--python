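"""QTL-QTL interaction mapping: two-dimensional and marginal scans on
additive-model BLUP residuals, with permutation-based FDR control.

The scan statistic for a marker pair (j, k) is the single-marker LOD applied
to the product of the two +/-1 genotype columns:

    LOD_jk = -n ln(1 - r_jk^2) / (2 ln 10),   r_jk = cor(g_j * g_k, y_r),

restricted to pairs separated by at least ``min_separation`` genome-order
indices (which also removes pairs in strong linkage). Residuals y_r come from
the additive polygenic model (components A, strain, error) with only the
additive BLUP subtracted, so the interaction signal being sought is not
absorbed. FDR at a LOD threshold t is the average number of permutation-scan
peaks >= t divided by the observed number of peaks >= t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crossvar.kinship import KinshipSet
from crossvar.reml import ModelSpec, blup_effects, fit_aireml
from crossvar.scan_additive import _derive_seed, lod_from_r2
from crossvar.simulate import GenotypeMatrix

__all__ = [
    "InteractionPeak",
    "interaction_residuals",
    "full_scan",
    "marginal_scan",
    "fdr_select",
    "classify_peaks",
]

_DEFAULT_MARKER_CAP = 12000
_REPORT_FLOOR = 3.0  # minimum LOD for a pair to enter the peak list


@dataclass
class InteractionPeak:
    """One two-locus interaction peak (genome-order indices, j < k)."""

    trait: str
    marker_j: int
    marker_k: int
    lod: float
    classification: str | None = None  # both / one / neither additive
    variance_explained: float | None = None


def interaction_residuals(
    y: np.ndarray, strain: np.ndarray, n_strains: int, kin: KinshipSet
) -> np.ndarray:
    """Per-strain averaged BLUP residuals from the additive polygenic model.

    Fits components (A, strain, error) with an intercept, subtracts only the
    additive BLUP from the phenotypes (the strain-repeatability BLUP would
    absorb part of the interaction signal), averages per strain and centres.
    """
    spec = ModelSpec(
        y=y, strain=strain, n_strains=n_strains, K={"additive": kin.A}
    )
    fit = fit_aireml(spec)
    a_hat = blup_effects(fit, spec, "additive")
    resid = np.asarray(y, dtype=float) - a_hat[np.asarray(strain)]
    counts = np.bincount(np.asarray(strain), minlength=n_strains).astype(float)
    avg = np.bincount(np.asarray(strain), weights=resid, minlength=n_strains) / np.maximum(
        counts, 1.0
    )
    return avg - avg.mean()


def _pair_lods(Gd: np.ndarray, y_r: np.ndarray, min_separation: int, rows=None):
    """LOD matrix over marker pairs via two Gram products.

    For +/-1 genotypes the product column p_jk = g_j * g_k has mean
    mu_jk = (G^T G)_jk / n and variance 1 - mu_jk^2, so all pair correlations
    with y_r reduce to (G diag(y) G^T) and (G^T G). ``rows`` restricts the
    first index (marginal scan). Returns (lod, valid) with invalid pairs
    (separation or degenerate product) masked to 0 / False.
    """
    n, M = Gd.shape
    ys = y_r - y_r.mean()
    sd_y = ys.std()
    rows_idx = np.arange(M) if rows is None else np.asarray(rows)
    Gr = Gd[:, rows_idx]
    num = (Gr * ys[:, None]).T @ Gd / n  # E[p_jk * y] with y centred
    mu = Gr.T @ Gd / n
    var_p = np.clip(1.0 - mu**2, 0.0, None)
    denom = sd_y * np.sqrt(var_p)
    valid = denom > 1e-12
    r = np.zeros_like(num)
    np.divide(num, denom, out=r, where=valid)
    sep = np.abs(rows_idx[:, None] - np.arange(M)[None, :]) >= min_separation
    valid &= sep
    lod = np.where(valid, lod_from_r2(r**2, n), 0.0)
    return lod, valid


def _extract_peaks(lod, valid, rows_idx, min_separation, floor, trait):
    """Greedy 2D peak extraction: take the highest remaining pair, suppress
    all pairs within +/- min_separation in BOTH coordinates, repeat."""
    ii, jj = np.nonzero(valid & (lod >= floor))
    if ii.size == 0:
        return []
    jglob = rows_idx[ii]
    a = np.minimum(jglob, jj)
    b = np.maximum(jglob, jj)
    lods = lod[ii, jj]
    # deduplicate unordered pairs (full scan sees both orientations)
    key = a.astype(np.int64) * (2**31) + b
    _, first = np.unique(key, return_index=True)
    order = first[np.argsort(-lods[first], kind="stable")]
    peaks: list[InteractionPeak] = []
    taken_a, taken_b = [], []
    for t in order:
        if taken_a:
            close = (np.abs(a[t] - np.array(taken_a)) <= min_separation) & (
                np.abs(b[t] - np.array(taken_b)) <= min_separation
            )
            if close.any():
                continue
        peaks.append(InteractionPeak(trait, int(a[t]), int(b[t]), float(lods[t])))
        taken_a.append(a[t])
        taken_b.append(b[t])
    return peaks


def full_scan(
    G: GenotypeMatrix,
    residuals: np.ndarray,
    min_separation: int = 50,
    trait: str = "trait",
    report_floor: float = _REPORT_FLOOR,
    marker_cap: int = _DEFAULT_MARKER_CAP,
    tiled: bool = False,
) -> list[InteractionPeak]:
    """Exhaustive two-dimensional interaction scan.

    Tests every pair of markers whose genome-order indices differ by at least
    ``min_separation`` and returns greedy 2D peaks with LOD >= report_floor,
    sorted by decreasing LOD. For marker counts above ``marker_cap`` the scan
    refuses to allocate the full LOD matrix unless ``tiled`` is set, in which
    case it proceeds in row blocks.
    """
    M = G.n_markers
    if M < min_separation + 1:
        raise ValueError("genome smaller than the separation rule")
    if M > marker_cap and not tiled:
        raise MemoryError(
            f"{M} markers exceeds the pair-scan cap {marker_cap}; pass tiled=True"
        )
    Gd = G.dosage()
    if not tiled:
        lod, valid = _pair_lods(Gd, residuals, min_separation)
        return _extract_peaks(lod, valid, np.arange(M), min_separation, report_floor, trait)
    block = max(1, marker_cap**2 // max(M, 1))
    peaks: list[InteractionPeak] = []
    for start in range(0, M, block):
        rows = np.arange(start, min(start + block, M))
        lod, valid = _pair_lods(Gd, residuals, min_separation, rows=rows)
        peaks.extend(
            _extract_peaks(lod, valid, rows, min_separation, report_floor, trait)
        )
    # merge peaks straddling block boundaries
    peaks.sort(key=lambda p: -p.lod)
    merged: list[InteractionPeak] = []
    for p in peaks:
        if any(
            abs(p.marker_j - q.marker_j) <= min_separation
            and abs(p.marker_k - q.marker_k) <= min_separation
            for q in merged
        ):
            continue
        merged.append(p)
    return merged


def marginal_scan(
    G: GenotypeMatrix,
    residuals: np.ndarray,
    additive_peaks,
    min_separation: int = 50,
    trait: str = "trait",
    report_floor: float = _REPORT_FLOOR,
) -> list[InteractionPeak]:
    """Interaction scan restricted to pairs anchored at additive QTL peaks."""
    additive_peaks = np.asarray(additive_peaks, dtype=np.int64)
    if additive_peaks.size == 0:
        warnings.warn("empty additive peak list: no pairs to test", stacklevel=2)
        return []
    lod, valid = _pair_lods(G.dosage(), residuals, min_separation, rows=additive_peaks)
    return _extract_peaks(lod, valid, additive_peaks, min_separation, report_floor, trait)


def fdr_select(
    observed_peaks: list[InteractionPeak],
    G: GenotypeMatrix,
    residuals: np.ndarray,
    n_perm: int = 5,
    target_fdr: float = 0.10,
    seed: int | None = None,
    min_separation: int = 50,
    mode: str = "full",
    additive_peaks=None,
    report_floor: float = _REPORT_FLOOR,
    trait: str = "trait",
) -> tuple[float | None, list[InteractionPeak]]:
    """Select significant peaks at a permutation-estimated FDR.

    FDR(t) = (average number of peaks with LOD >= t over permutations of
    strain identities) / (number of observed peaks with LOD >= t). Candidate
    thresholds are the distinct observed peak LODs; the smallest t with
    FDR(t) <= target is chosen. Returns (threshold, significant peaks);
    threshold is None when no observed peak qualifies.
    """
    if not observed_peaks:
        warnings.warn("no observed peaks: FDR threshold undefined", stacklevel=2)
        return None, []
    rng = np.random.default_rng(_derive_seed(seed, trait, mode, "fdr"))
    n = residuals.size
    perm_lods: list[np.ndarray] = []
    for _ in range(n_perm):
        y_p = residuals[rng.permutation(n)]
        if mode == "full":
            pk = full_scan(
                G, y_p, min_separation=min_separation, trait=trait, report_floor=report_floor
            )
        elif mode == "marginal":
            pk = marginal_scan(
                G,
                y_p,
                additive_peaks,
                min_separation=min_separation,
                trait=trait,
                report_floor=report_floor,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        perm_lods.append(np.array([p.lod for p in pk]))
    obs = np.array(sorted({p.lod for p in observed_peaks}))
    threshold = None
    for t in obs:
        n_obs = sum(p.lod >= t for p in observed_peaks)
        n_perm_mean = float(np.mean([(pl >= t).sum() for pl in perm_lods]))
        if n_obs > 0 and n_perm_mean / n_obs <= target_fdr:
            threshold = float(t)
            break
    if threshold is None:
        return None, []
    sig = [p for p in observed_peaks if p.lod >= threshold]
    return threshold, sig


def classify_peaks(
    peaks: list[InteractionPeak], additive_peaks, min_separation: int = 50
) -> list[InteractionPeak]:
    """Annotate each pair by whether both / one / neither member coincides
    with a significant additive QTL peak (within +/- min_separation indices)."""
    additive_peaks = np.asarray(additive_peaks, dtype=np.int64)

    def near(idx):
        return additive_peaks.size > 0 and bool(
            (np.abs(additive_peaks - idx) <= min_separation).any()
        )

    for p in peaks:
        hits = int(near(p.marker_j)) + int(near(p.marker_k))
        p.classification = {2: "both", 1: "one", 0: "neither"}[hits]
    return peaks


def interaction_table(peaks: list[InteractionPeak], G: GenotypeMatrix) -> pd.DataFrame:
    """Interaction-peak table in the on-disk TSV layout."""
    mm = G.map
    return pd.DataFrame(
        [
            {
                "trait": p.trait,
                "marker_j": p.marker_j,
                "marker_k": p.marker_k,
                "chrom_j": int(mm.chromosome[p.marker_j]),
                "pos_j": int(mm.position_bp[p.marker_j]),
                "chrom_k": int(mm.chromosome[p.marker_k]),
                "pos_k": int(mm.position_bp[p.marker_k]),
                "LOD": p.lod,
                "classification": p.classification,
                "variance_explained": p.variance_explained,
            }
            for p in peaks
        ]
    )
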