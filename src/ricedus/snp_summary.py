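"""Descriptive statistics of the SNP panel.

Per-locus heterozygosity, the distribution of physical gaps between
consecutive SNPs, and per-chromosome marker density in kb/SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix, LocusRecord

#: Default interval bin edges in bp: < 1 kb, 1-3 kb, > 3 kb.
DEFAULT_BIN_EDGES = (1000, 3000)


@dataclass(frozen=True)
class ChromDensityRow:
    """One chromosome's SNP density summary."""

    chrom: str
    length_mb: float
    n_snp: int
    density_kb_per_snp: float


def heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of heterozygous (0.5) calls among non-missing."""
    values = g.values
    het = (values == 0.5).sum(axis=0)
    n_obs = (~np.isnan(values)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = het / n_obs
    return np.where(n_obs > 0, frac, np.nan)


def inter_snp_intervals(loci: list[LocusRecord]) -> np.ndarray:
    """Gaps (bp) between consecutive loci, never spanning chromosomes."""
    gaps = []
    for prev, cur in zip(loci, loci[1:]):
        if cur.chrom == prev.chrom:
            if cur.pos <= prev.pos:
                raise ValueError(
                    f"loci not sorted: {prev.chrom}:{prev.pos} then "
                    f"{cur.chrom}:{cur.pos}"
                )
            gaps.append(cur.pos - prev.pos)
        elif cur.chrom < prev.chrom:
            raise ValueError("loci not sorted by (chrom, pos)")
    return np.asarray(gaps, dtype=float)


def interval_histogram(
    loci: list[LocusRecord],
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
) -> np.ndarray:
    """Fractions of inter-SNP gaps per bin (left-closed boundaries).

    Default bins: [0, 1000), [1000, 3000), [3000, inf).  Fractions sum
    to 1; with no intervals at all (at most one locus per chromosome)
    an empty array is returned.
    """
    gaps = inter_snp_intervals(loci)
    if gaps.size == 0:
        return np.empty(0)
    edges = [0, *bin_edges, np.inf]
    counts = np.histogram(gaps, bins=edges)[0]
    return counts / gaps.size


def chrom_density(
    lengths_mb: dict[str, float],
    counts: dict[str, int],
) -> list[ChromDensityRow]:
    """Per-chromosome density: length_mb x 1000 / n_snp, 2 decimals."""
    missing = set(lengths_mb) ^ set(counts)
    if missing:
        raise KeyError(f"chromosomes missing from one map: {sorted(missing)}")
    rows = []
    for chrom in lengths_mb:
        n = counts[chrom]
        if n <= 0:
            raise ValueError(f"chromosome {chrom} has no SNPs")
        rows.append(
            ChromDensityRow(
                chrom=chrom,
                length_mb=lengths_mb[chrom],
                n_snp=n,
                density_kb_per_snp=round(lengths_mb[chrom] * 1000.0 / n, 2),
            )
        )
    return rows
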