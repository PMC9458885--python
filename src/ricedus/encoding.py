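"""Construction of the two 0-1 analysis matrices.

The molecular side is the dosage matrix itself (0 reference, 1 alternate,
0.5 heterozygous) after mode imputation and MAF/missingness filtering.
The phenotypic side expands each ordinal trait into one binary indicator
column per observed grade level: a variety scored at level i of a trait
carries a 1 in that (trait, level) column and 0 elsewhere in the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    GENOTYPE_CODES,
    GenotypeMatrix,
    PhenotypeIndicatorMatrix,
    TraitTable,
)


@dataclass(frozen=True)
class FilterSpec:
    """Locus-retention thresholds: keep maf > maf_min and missing < miss_max."""

    maf_min: float = 0.05
    miss_max: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 1 and 0 <= self.miss_max <= 1):
            raise ValueError("filter thresholds must be in [0, 1]")


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing calls with each locus's most frequent genotype code.

    Ties are broken toward the smallest code (0 < 0.5 < 1) so the result
    is deterministic.  A locus with no observed call cannot be imputed
    and raises; filter such loci first.
    """
    values = g.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return GenotypeMatrix(values, list(g.variety_ids), list(g.loci))
    all_missing = missing.all(axis=0)
    if all_missing.any():
        idx = int(np.flatnonzero(all_missing)[0])
        raise ValueError(
            f"locus {g.loci[idx].id} has no observed call; "
            "filter all-missing loci before imputation"
        )
    # counts[k, j] = occurrences of code k at locus j; argmax takes the
    # first (smallest) code on ties because GENOTYPE_CODES is sorted
    counts = np.stack(
        [(values == code).sum(axis=0) for code in GENOTYPE_CODES]
    )
    modes = np.asarray(GENOTYPE_CODES)[counts.argmax(axis=0)]
    values[missing] = np.broadcast_to(modes, values.shape)[missing]
    return GenotypeMatrix(values, list(g.variety_ids), list(g.loci))


def locus_stats(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus (alt_freq, maf, missing_rate) as a structured array.

    Allele frequency is computed on dosage over non-missing calls: a
    heterozygote contributes one alternate allele of two.
    """
    values = g.values
    missing = np.isnan(values)
    n_obs = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(values, axis=0) / n_obs
    alt_freq = np.where(n_obs > 0, alt_freq, np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    missing_rate = missing.sum(axis=0) / values.shape[0]
    out = np.zeros(
        g.n_loci,
        dtype=[("alt_freq", float), ("maf", float), ("missing_rate", float)],
    )
    out["alt_freq"] = alt_freq
    out["maf"] = maf
    out["missing_rate"] = missing_rate
    return out


def filter_loci(g: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Keep loci with maf > maf_min and missing_rate < miss_max (strict).

    Locus order is preserved.  An empty result is legal (a warning is the
    caller's concern); loci with no observed calls are always dropped
    since their frequency is undefined.
    """
    stats = locus_stats(g)
    with np.errstate(invalid="ignore"):
        keep = (stats["maf"] > spec.maf_min) & (
            stats["missing_rate"] < spec.miss_max
        )
    keep &= ~np.isnan(stats["maf"])
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        values=g.values[:, idx],
        variety_ids=list(g.variety_ids),
        loci=[g.loci[i] for i in idx],
    )


def encode_phenotypes(t: TraitTable) -> PhenotypeIndicatorMatrix:
    """Expand grade codes into the binary (trait, level) indicator matrix.

    Only observed levels produce columns; a variety missing a trait gets
    an all-zero row in that trait's block (no phenotype imputation).
    """
    blocks: list[np.ndarray] = []
    labels: list[tuple[str, int]] = []
    for j, trait in enumerate(t.trait_names):
        col = t.codes[:, j]
        levels = np.unique(col[~np.isnan(col)]).astype(int)
        for level in levels:
            blocks.append((col == level).astype(float))
            labels.append((trait, int(level)))
    values = (
        np.column_stack(blocks)
        if blocks
        else np.empty((t.n_varieties, 0))
    )
    return PhenotypeIndicatorMatrix(
        values=values,
        column_labels=labels,
        variety_ids=list(t.variety_ids),
    )


def indicator_column_headers(m: PhenotypeIndicatorMatrix) -> list[str]:
    """TSV column headers in the "trait#level" convention."""
    return [f"{trait}#{level}" for trait, level in m.column_labels]
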