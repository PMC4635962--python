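"""Synthetic two-parent cross: genotypes with crossover structure and
phenotypes with a controllable additive / epistatic / repeatability
architecture.

The generator emulates a haploid biparental cross (two parental alleles coded
-1 and +1, e.g. BY and RM in a yeast segregant panel): each offspring starts
every chromosome in one parental state and switches state at recombination
crossovers. Phenotypes are the sum of additive locus effects, pairwise
locus-product (epistatic) effects, a per-strain repeatability effect, and
replicate-level Gaussian error, with user-specified population variance
fractions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "ArchitectureSpec",
    "ArchitectureTruth",
    "default_marker_map",
    "simulate_genotypes",
    "simulate_phenotypes",
]

# Chromosome lengths (kb) of the S. cerevisiae nuclear genome, used to spread
# markers realistically across 16 chromosomes.
_YEAST_CHROM_KB = np.array(
    [230, 813, 316, 1532, 577, 270, 1091, 563, 440, 746, 667, 1078, 924, 784, 1091, 948],
    dtype=float,
)


@dataclass(frozen=True)
class MarkerMap:
    """Genome coordinates for a set of ordered markers.

    Attributes
    ----------
    chromosome : (M,) int array of chromosome ids (1-based).
    position_bp : (M,) int array of physical positions, strictly increasing
        within each chromosome.
    """

    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position_bp, dtype=np.int64)
        if chrom.shape != pos.shape or chrom.ndim != 1 or chrom.size == 0:
            raise ValueError("chromosome and position_bp must be equal-length 1D arrays")
        # genome order: sorted by (chromosome, position), positions strictly
        # increasing within a chromosome
        if np.any(np.diff(chrom) < 0):
            raise ValueError("markers must be sorted by chromosome")
        same = np.diff(chrom) == 0
        if np.any(np.diff(pos)[same] <= 0):
            raise ValueError("positions must be strictly increasing within a chromosome")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_bp", pos)

    @property
    def n_markers(self) -> int:
        return self.chromosome.size

    @property
    def index(self) -> np.ndarray:
        """0-based genome-order rank of each marker."""
        return np.arange(self.n_markers)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome ids, in order."""
        return np.unique(self.chromosome)

    def chrom_slice(self, chrom: int) -> np.ndarray:
        """Indices of the markers on one chromosome."""
        return np.flatnonzero(self.chromosome == chrom)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.chromosome[idx], self.position_bp[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": [f"m{i:05d}" for i in range(self.n_markers)],
                "chrom": self.chromosome,
                "pos_bp": self.position_bp,
            }
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Segregants x markers genotypes coded -1 / +1, with a marker map."""

    values: np.ndarray
    map: MarkerMap

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("genotype values must be 2D (segregants x markers)")
        if vals.shape[0] < 2:
            raise ValueError("need at least 2 segregants")
        if vals.shape[1] != self.map.n_markers:
            raise ValueError("genotype columns do not match the marker map")
        if not np.isin(vals, (-1, 1)).all():
            raise ValueError("genotypes must be coded -1 / +1 with no missing values")
        object.__setattr__(self, "values", vals.astype(np.int8, copy=False))

    @property
    def n_segregants(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def dosage(self) -> np.ndarray:
        """Genotypes as float64 (for linear algebra)."""
        return self.values.astype(np.float64)

    def subset_segregants(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values[np.asarray(idx)], self.map)

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.values[:, idx], self.map.subset(idx))


@dataclass(frozen=True)
class PhenotypeTable:
    """Replicate-level phenotype observations.

    Attributes
    ----------
    strain : (m,) int array of strain codes in 0..n-1 (the incidence map Z).
    replicate : (m,) int array of replicate numbers (1-based).
    value : (m,) float array of measurements.
    n_strains : total number of strains n (some may have no observations only
        in externally loaded data; the simulator always covers all strains).
    """

    strain: np.ndarray
    replicate: np.ndarray
    value: np.ndarray
    n_strains: int

    def __post_init__(self):
        s = np.asarray(self.strain, dtype=np.int64)
        r = np.asarray(self.replicate, dtype=np.int64)
        v = np.asarray(self.value, dtype=np.float64)
        if not (s.shape == r.shape == v.shape) or s.ndim != 1:
            raise ValueError("strain, replicate and value must be equal-length 1D arrays")
        if s.size and (s.min() < 0 or s.max() >= self.n_strains):
            raise ValueError("strain codes out of range")
        object.__setattr__(self, "strain", s)
        object.__setattr__(self, "replicate", r)
        object.__setattr__(self, "value", v)

    @property
    def n_obs(self) -> int:
        return self.value.size

    def replicate_counts(self) -> np.ndarray:
        return np.bincount(self.strain, minlength=self.n_strains)

    def strain_means(self) -> np.ndarray:
        counts = self.replicate_counts()
        sums = np.bincount(self.strain, weights=self.value, minlength=self.n_strains)
        return sums / np.maximum(counts, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": [f"seg{int(i):05d}" for i in self.strain],
                "replicate": self.replicate,
                "value": self.value,
            }
        )


def default_marker_map(n_markers: int = 2000, n_chromosomes: int = 16) -> MarkerMap:
    """Evenly spaced markers over chromosomes with realistic relative lengths.

    Markers are allocated to chromosomes proportionally to yeast chromosome
    lengths (recycled if ``n_chromosomes`` exceeds 16) with at least two
    markers per chromosome, and spaced evenly along each chromosome.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    lengths = np.resize(_YEAST_CHROM_KB, n_chromosomes) * 1000.0
    alloc = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    # trim/add from the largest chromosomes to hit n_markers exactly
    while alloc.sum() != n_markers:
        j = int(np.argmax(alloc)) if alloc.sum() > n_markers else int(np.argmin(alloc / lengths))
        alloc[j] += -1 if alloc.sum() > n_markers else 1
        if alloc[j] < 2:
            raise ValueError("n_markers too small for the requested chromosome count")
    chroms, positions = [], []
    for c, (L, k) in enumerate(zip(lengths, alloc), start=1):
        chroms.append(np.full(k, c))
        positions.append(np.round(np.linspace(1000, L, k)).astype(np.int64))
    return MarkerMap(np.concatenate(chroms), np.concatenate(positions))


def simulate_genotypes(
    map: MarkerMap,
    n_segregants: int,
    expected_crossovers: float = 65.0,
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Simulate segregant genotypes from a biparental haploid cross.

    Each segregant starts each chromosome in either parental state with
    probability 1/2; a Poisson number of crossovers (genome-wide mean
    ``expected_crossovers``, split over chromosomes proportionally to their
    marker span, no interference) is placed uniformly along the chromosome and
    the genotype flips sign at each crossover. The default mean of 65 sits in
    the middle of the 25-105 breakpoint envelope typical of sequenced yeast
    segregants.
    """
    if n_segregants <= 0:
        raise ValueError("n_segregants must be positive")
    if expected_crossovers < 0:
        raise ValueError("expected_crossovers must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    chrom_ids = map.chromosomes
    spans = np.array(
        [
            max(float(np.ptp(map.position_bp[map.chrom_slice(c)])), 1.0)
            for c in chrom_ids
        ]
    )
    means = expected_crossovers * spans / spans.sum()

    G = np.empty((n_segregants, map.n_markers), dtype=np.int8)
    for c, mu in zip(chrom_ids, means):
        cols = map.chrom_slice(c)
        pos = map.position_bp[cols].astype(float)
        lo, hi = pos[0], pos[-1]
        start = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_segregants)
        n_co = rng.poisson(mu, size=n_segregants)
        total = int(n_co.sum())
        xpos = rng.uniform(lo, hi, size=total)
        offsets = np.concatenate(([0], np.cumsum(n_co)))
        for i in range(n_segregants):
            xo = np.sort(xpos[offsets[i] : offsets[i + 1]])
            parity = np.searchsorted(xo, pos, side="right") & 1
            G[i, cols] = start[i] * np.where(parity, -1, 1).astype(np.int8)
    return GenotypeMatrix(G, map)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Target genetic architecture for phenotype simulation.

    ``h2_additive`` and ``h2_interaction = H2_total - h2_additive`` are target
    fractions of the population phenotypic variance; ``strain_var`` is the
    residual strain-repeatability fraction and the remainder
    ``1 - H2_total - strain_var`` is replicate-level error.
    """

    n_additive_qtl: int
    n_interactions: int
    h2_additive: float
    H2_total: float = 0.75
    n_replicates: int = 2
    strain_var: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_additive_qtl < 0 or self.n_interactions < 0:
            raise ValueError("QTL counts must be non-negative")
        if not (0.0 <= self.h2_additive <= self.H2_total < 1.0):
            raise ValueError("need 0 <= h2_additive <= H2_total < 1")
        if self.h2_additive > 0 and self.n_additive_qtl == 0:
            raise ValueError("h2_additive > 0 requires at least one additive QTL")
        if self.h2_interaction > 0 and self.n_interactions == 0:
            raise ValueError("h2_interaction > 0 requires at least one interacting pair")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.strain_var < 0 or self.H2_total + self.strain_var >= 1.0:
            raise ValueError("strain_var must be >= 0 with H2_total + strain_var < 1")

    @property
    def h2_interaction(self) -> float:
        return self.H2_total - self.h2_additive


@dataclass
class ArchitectureTruth:
    """Ground truth of one simulated architecture."""

    additive_loci: np.ndarray
    additive_effects: np.ndarray
    interacting_pairs: np.ndarray  # (q, 2) marker indices
    interaction_effects: np.ndarray
    g: np.ndarray  # per-strain total genetic value
    additive_values: np.ndarray  # scaled additive part of g
    interaction_values: np.ndarray  # scaled epistatic part of g
    strain_effects: np.ndarray
    error_sd: float
    realized_fractions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "additive_loci": self.additive_loci.tolist(),
            "additive_effects": self.additive_effects.tolist(),
            "interacting_pairs": self.interacting_pairs.tolist(),
            "interaction_effects": self.interaction_effects.tolist(),
            "error_sd": self.error_sd,
            "realized_fractions": self.realized_fractions,
        }
        return json.dumps(payload, indent=2)


def _choose_pairs(rng, additive, n_pairs, n_markers):
    """Interacting pairs, preferentially from combinations of additive loci.

    Overflow pairs (when more pairs are requested than C(n_additive, 2)) are
    placed between loci with no marginal additive effect.
    """
    combos = list(itertools.combinations(sorted(additive.tolist()), 2))
    if n_pairs <= len(combos):
        take = rng.choice(len(combos), size=n_pairs, replace=False)
        return np.array([combos[i] for i in sorted(take)], dtype=np.int64).reshape(n_pairs, 2)
    extra = n_pairs - len(combos)
    non_additive = np.setdiff1d(np.arange(n_markers), additive)
    if 2 * extra > non_additive.size:
        raise ValueError(
            f"cannot place {n_pairs} interacting pairs: only {len(combos)} additive "
            f"combinations and {non_additive.size} non-additive markers available"
        )
    picked = rng.choice(non_additive, size=2 * extra, replace=False).reshape(extra, 2)
    picked.sort(axis=1)
    pairs = np.array(combos + picked.tolist(), dtype=np.int64).reshape(n_pairs, 2)
    return pairs


def simulate_phenotypes(
    G: GenotypeMatrix, spec: ArchitectureSpec
) -> tuple[PhenotypeTable, ArchitectureTruth]:
    """Simulate replicate-level phenotypes on top of a genotype matrix.

    Additive loci are placed uniformly at random and given equal-magnitude,
    random-sign effects; their sum is rescaled to the target additive variance
    fraction. Interacting pairs act through the product of the two +/-1
    genotypes, again with equal-magnitude random signs, rescaled to the target
    interaction fraction. The genetic value g is the sum of the two scaled
    parts; strain effects and replicate error are added so population variance
    fractions match ``spec``. Error variance is (1 - H2)/H2 * var(g) when
    ``strain_var`` is 0, scaled analogously otherwise.
    """
    if spec.n_additive_qtl > G.n_markers:
        raise ValueError("more additive QTL requested than markers")
    rng = np.random.default_rng(spec.seed)
    n, M = G.n_segregants, G.n_markers
    X = G.dosage()

    loci = np.sort(rng.choice(M, size=spec.n_additive_qtl, replace=False)) if spec.n_additive_qtl else np.empty(0, dtype=np.int64)
    signs_a = rng.choice([-1.0, 1.0], size=loci.size)
    a_raw = X[:, loci] @ signs_a if loci.size else np.zeros(n)
    sd_a = a_raw.std()
    scale_a = np.sqrt(spec.h2_additive) / sd_a if sd_a > 0 and spec.h2_additive > 0 else 0.0
    a = a_raw * scale_a

    if spec.n_interactions:
        pairs = _choose_pairs(rng, loci, spec.n_interactions, M)
        signs_i = rng.choice([-1.0, 1.0], size=pairs.shape[0])
        prods = X[:, pairs[:, 0]] * X[:, pairs[:, 1]]
        i_raw = prods @ signs_i
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
        signs_i = np.empty(0)
        i_raw = np.zeros(n)
    sd_i = i_raw.std()
    scale_i = np.sqrt(spec.h2_interaction) / sd_i if sd_i > 0 and spec.h2_interaction > 0 else 0.0
    ivals = i_raw * scale_i

    g = a + ivals
    var_g = g.var()
    # implied total phenotypic variance: the genetic part occupies H2 of it
    unit = var_g / spec.H2_total if var_g > 0 else 1.0
    var_p = spec.strain_var * unit
    var_e = (1.0 - spec.H2_total - spec.strain_var) * unit
    p = rng.normal(0.0, np.sqrt(var_p), size=n) if var_p > 0 else np.zeros(n)

    r = spec.n_replicates
    strain_idx = np.repeat(np.arange(n), r)
    replicate = np.tile(np.arange(1, r + 1), n)
    e = rng.normal(0.0, np.sqrt(var_e), size=n * r)
    y = (g + p)[strain_idx] + e

    total = y.var()
    realized = {
        "additive": float(a.var() / total) if total > 0 else 0.0,
        "interaction": float(ivals.var() / total) if total > 0 else 0.0,
        "strain": float(p.var() / total) if total > 0 else 0.0,
        "error": float(var_e / total) if total > 0 else 0.0,
    }

    table = PhenotypeTable(strain_idx, replicate, y, n_strains=n)
    truth = ArchitectureTruth(
        additive_loci=loci,
        additive_effects=signs_a * scale_a,
        interacting_pairs=pairs,
        interaction_effects=signs_i * scale_i,
        g=g,
        additive_values=a,
        interaction_values=ivals,
        strain_effects=p,
        error_sd=float(np.sqrt(var_e)),
        realized_fractions=realized,
    )
    return table, truth
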