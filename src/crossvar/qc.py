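"""Segregant- and marker-level genotype quality control.

Filters mirror standard QC for sequenced segregant panels: individuals with
implausibly few or many recombination breakpoints (failed gametes, diploid
contaminants or genotyping artifacts) are removed, near-duplicate segregants
(Pearson r > 0.9 genome-wide) are collapsed to one representative, and runs of
markers carrying identical genotype columns are collapsed to a single
representative marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from crossvar.simulate import GenotypeMatrix, MarkerMap

__all__ = ["QcReport", "count_breakpoints", "filter_segregants", "dedup_markers"]


@dataclass
class QcReport:
    """Outcome of segregant-level QC.

    ``dropped`` maps segregant index -> reason; reasons are exclusive, the
    first failing rule wins in the order breakpoint-low, breakpoint-high,
    duplicate.
    """

    kept_segregants: np.ndarray
    dropped: dict[int, str] = field(default_factory=dict)
    kept_markers: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "kept_segregants": self.kept_segregants.tolist(),
            "dropped": {str(k): v for k, v in self.dropped.items()},
            "kept_markers": None if self.kept_markers is None else self.kept_markers.tolist(),
        }


def count_breakpoints(genotype_row: np.ndarray, map: MarkerMap) -> int:
    """Number of recombination breakpoints in one segregant genome.

    A breakpoint is an adjacent same-chromosome marker pair with opposite
    genotype sign; chromosome boundaries are never counted.
    """
    row = np.asarray(genotype_row)
    if row.shape != (map.n_markers,):
        raise ValueError("genotype row length does not match the marker map")
    flips = row[1:] != row[:-1]
    same_chrom = map.chromosome[1:] == map.chromosome[:-1]
    return int(np.count_nonzero(flips & same_chrom))


def _all_breakpoints(G: GenotypeMatrix) -> np.ndarray:
    flips = G.values[:, 1:] != G.values[:, :-1]
    same_chrom = G.map.chromosome[1:] == G.map.chromosome[:-1]
    return (flips & same_chrom).sum(axis=1)


def filter_segregants(
    G: GenotypeMatrix,
    min_bp: int = 25,
    max_bp: int = 105,
    max_dup_corr: float = 0.9,
) -> QcReport:
    """Drop segregants outside the breakpoint envelope, then near-duplicates.

    Duplicate removal is greedy in input order: for any pair with genome-wide
    genotype Pearson correlation above ``max_dup_corr``, the later member is
    dropped.
    """
    if G.n_segregants < 2:
        raise ValueError("need at least 2 segregants for QC")
    bp = _all_breakpoints(G)
    dropped: dict[int, str] = {}
    for i in range(G.n_segregants):
        if bp[i] < min_bp:
            dropped[i] = "breakpoint-low"
        elif bp[i] > max_bp:
            dropped[i] = "breakpoint-high"

    survivors = [i for i in range(G.n_segregants) if i not in dropped]
    if survivors:
        X = G.values[survivors].astype(np.float64)
        X -= X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(X, axis=1)
        norms[norms == 0] = 1.0
        X /= norms[:, None]
        R = X @ X.T
        kept: list[int] = []
        kept_pos: list[int] = []
        for pos, i in enumerate(survivors):
            if kept_pos and np.any(R[pos, kept_pos] > max_dup_corr):
                dropped[i] = "duplicate"
            else:
                kept.append(i)
                kept_pos.append(pos)
    else:
        kept = []
    return QcReport(kept_segregants=np.array(kept, dtype=np.int64), dropped=dropped)


def dedup_markers(G: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse runs of markers with identical genotype columns.

    Among consecutive markers whose columns are identical across all
    segregants, only the first in genome order is retained; the marker map is
    re-indexed accordingly. Columns identical only up to a global sign flip
    are distinct and both retained.
    """
    same_as_prev = np.concatenate(
        ([False], (G.values[:, 1:] == G.values[:, :-1]).all(axis=0))
    )
    keep = np.flatnonzero(~same_as_prev)
    return G.subset_markers(keep)
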