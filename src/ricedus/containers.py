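"""Core in-memory containers shared across the pipeline.

Genotypes are stored as variety x locus dosage codes on the unit scale:
0 (homozygous reference), 0.5 (heterozygous), 1 (homozygous alternate),
with ``numpy.nan`` marking a missing call.  Morphological traits are
ordinal grade codes 1-9, again with ``nan`` for missing observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The three admissible genotype codes after imputation.
GENOTYPE_CODES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class LocusRecord:
    """Identity of a biallelic SNP locus.

    The ``id`` defaults to the ``Chr<chrom>_<pos>`` convention used for
    naming rice SNPs when none is supplied in the source file.
    """

    chrom: str
    pos: int  # 1-based physical position (bp)
    ref_allele: str
    alt_allele: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt allele identical at {self.chrom}:{self.pos}"
            )
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}_{self.pos}")


@dataclass(frozen=True)
class VarietyLabel:
    """Accession identity: short code, cultivar name, optional origin."""

    id: str
    name: str = ""
    origin: str | None = None


@dataclass
class GenotypeMatrix:
    """Varieties x loci dosage matrix over {0, 0.5, 1, nan}."""

    values: np.ndarray
    variety_ids: list[str]
    loci: list[LocusRecord]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-dimensional")
        n, m = self.values.shape
        if n != len(self.variety_ids):
            raise ValueError(
                f"{len(self.variety_ids)} variety ids for {n} rows"
            )
        if m != len(self.loci):
            raise ValueError(f"{len(self.loci)} locus records for {m} columns")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, GENOTYPE_CODES).all():
            bad = finite[~np.isin(finite, GENOTYPE_CODES)]
            raise ValueError(f"genotype codes outside {{0,0.5,1}}: {bad[:5]}")

    @property
    def n_varieties(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


@dataclass
class TraitTable:
    """Varieties x traits ordinal grade codes (integers 1-9, nan missing)."""

    codes: np.ndarray
    trait_names: list[str]
    variety_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("trait codes must be 2-dimensional")
        n, t = self.codes.shape
        if n != len(self.variety_ids) or t != len(self.trait_names):
            raise ValueError("trait table dimensions inconsistent with labels")
        finite = self.codes[~np.isnan(self.codes)]
        if finite.size:
            if not np.array_equal(finite, np.round(finite)) or (
                (finite < 1) | (finite > 9)
            ).any():
                raise ValueError("grade codes must be integers in 1..9")

    @property
    def n_varieties(self) -> int:
        return self.codes.shape[0]

    @property
    def n_traits(self) -> int:
        return self.codes.shape[1]


@dataclass
class PhenotypeIndicatorMatrix:
    """Binary variety x (trait, level) indicator matrix.

    ``column_labels`` pairs each column with its (trait name, grade level).
    Within one trait's block a variety has row sum 1, or 0 when the trait
    was not observed for it.
    """

    values: np.ndarray
    column_labels: list[tuple[str, int]]
    variety_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("indicator values must be 2-dimensional")
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("column label count mismatch")
        if self.values.shape[0] != len(self.variety_ids):
            raise ValueError("variety id count mismatch")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("indicator entries must be 0 or 1")

    @property
    def trait_names(self) -> list[str]:
        seen: list[str] = []
        for trait, _ in self.column_labels:
            if trait not in seen:
                seen.append(trait)
        return seen

    def trait_block(self, trait: str) -> np.ndarray:
        """Column indices belonging to one trait's indicator block."""
        idx = [i for i, (t, _) in enumerate(self.column_labels) if t == trait]
        if not idx:
            raise KeyError(f"trait {trait!r} not present")
        return np.asarray(idx, dtype=int)

    def subset_traits(self, traits: list[str]) -> "PhenotypeIndicatorMatrix":
        """Restrict to whole trait blocks (blocks are never split)."""
        cols = np.concatenate([self.trait_block(t) for t in traits])
        return PhenotypeIndicatorMatrix(
            values=self.values[:, cols],
            column_labels=[self.column_labels[i] for i in cols],
            variety_ids=list(self.variety_ids),
        )


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative variety x variety distance matrix."""

    values: np.ndarray
    variety_ids: list[str]
    metric: str = ""
    source: str = ""  # "molecular" | "phenotypic" | ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.variety_ids):
            raise ValueError("variety id count mismatch")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix contains non-finite entries")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        # symmetrize exactly so downstream comparisons are bit-stable
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class MixedModelFit:
    """Ridge-regression BLUP fit of y = mu + X alpha + e."""

    mu: float
    alpha: np.ndarray
    var_u: float  # marker-effect variance sigma_alpha^2
    var_e: float  # residual variance sigma_e^2
    degenerate: bool = False
    column_means: np.ndarray | None = None

    @property
    def lam(self) -> float:
        """Shrinkage ratio sigma_e^2 / sigma_alpha^2."""
        if self.var_u == 0:
            return np.inf
        return self.var_e / self.var_u

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.column_means is not None:
            X = X - self.column_means
        return self.mu + X @ self.alpha


@dataclass
class PredictionResult:
    """Cross-validated prediction accuracy for one trait."""

    trait: str
    accuracies: np.ndarray  # nan marks replicates with constant test truth
    group: str = ""  # "A" | "B" | ""
    n_dropped: int = 0

    @property
    def mean_accuracy(self) -> float:
        valid = self.accuracies[~np.isnan(self.accuracies)]
        return float(valid.mean()) if valid.size else float("nan")


@dataclass
class DSet:
    """Distinct-variety set selected at a distance threshold."""

    source: str
    size: int
    members: frozenset[str]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.members) != self.size:
            raise ValueError("member count does not equal requested size")


@dataclass
class ReproductionMatrix:
    """Shared distinct-variety counts across threshold ladders."""

    phenotypic_sizes: list[int]
    molecular_sizes: list[int]
    shared: np.ndarray

    def __post_init__(self) -> None:
        self.shared = np.asarray(self.shared, dtype=int)
        if self.shared.shape != (
            len(self.phenotypic_sizes),
            len(self.molecular_sizes),
        ):
            raise ValueError("shared grid shape mismatch")


@dataclass
class DistanceCorrelationResult:
    """Mantel-style correlation between two distance matrices."""

    metric: str
    r: float
    p: float
    n_pairs: int


@dataclass
class SubsampleCurve:
    """Correlation as a function of SNP- or trait-subset size."""

    axis: str  # "snps" | "traits"
    sizes: list[int]
    r_values: np.ndarray  # len(sizes) x reps
    seed: int


@dataclass
class Dendrogram:
    """Rooted binary ultrametric tree from agglomerative clustering.

    ``merges`` lists (left, right, height) triples in merge order, where
    cluster ids 0..n-1 are leaves and n+k is the cluster made by merge k.
    Heights follow the ultrametric convention: two leaves at distance d
    merge at height d/2, so leaf-to-root path lengths equal the height.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a binary tree on n leaves has n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def cherries(self) -> set[frozenset[str]]:
        """Leaf pairs merged directly together (sister pairs)."""
        n = len(self.leaves)
        return {
            frozenset((self.leaves[a], self.leaves[b]))
            for a, b, _ in self.merges
            if a < n and b < n
        }


@dataclass
class SimulationConfig:
    """Parameters of the structured-population genotype/trait simulator."""

    n_varieties: int = 122
    n_loci: int = 5000
    n_subpops: int = 4
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 30
    h2: float | list[float] = 0.5
    n_causal: int = 100
    n_levels: int | list[int] = 9
    het_rate: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_varieties, self.n_loci, self.n_subpops, self.n_traits) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_causal > self.n_loci:
            raise ValueError("n_causal cannot exceed n_loci")
        levels = (
            self.n_levels if isinstance(self.n_levels, list) else [self.n_levels]
        )
        if any(not 2 <= lv <= 9 for lv in levels):
            raise ValueError("n_levels must be in 2..9")
        for rate in (self.het_rate, self.missing_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        h2s = self.h2 if isinstance(self.h2, list) else [self.h2]
        if any(not (0 <= h <= 1) for h in h2s):
            raise ValueError("h2 must be in [0, 1]")

    def trait_h2(self) -> np.ndarray:
        """Per-trait heritabilities, recycling a scalar h2."""
        if isinstance(self.h2, list):
            if len(self.h2) != self.n_traits:
                raise ValueError("h2 list length must equal n_traits")
            return np.asarray(self.h2, dtype=float)
        return np.full(self.n_traits, float(self.h2))

    def trait_levels(self) -> np.ndarray:
        """Per-trait grade-level counts, recycling a scalar n_levels."""
        if isinstance(self.n_levels, list):
            if len(self.n_levels) != self.n_traits:
                raise ValueError("n_levels list length must equal n_traits")
            return np.asarray(self.n_levels, dtype=int)
        return np.full(self.n_traits, int(self.n_levels))
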