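"""Distinctness decisions from distance thresholds (UPOV option 2 core).

A variety's separation score is its minimum distance to every other
variety — the DUS-relevant quantity, since a distinct variety must
differ from all others.  Ranking varieties by separation makes distance
thresholds and distinct-variety counts interconvertible: the "D" set of
size k is the k most separated varieties, and the realized threshold is
the separation of the last variety admitted.

Crossing a ladder of phenotypic set sizes with a ladder of molecular set
sizes and counting shared members quantifies how well molecular
thresholds reproduce phenotypic distinctness decisions.
"""

from __future__ import annotations

import numpy as np

from .containers import DistanceMatrix, DSet, ReproductionMatrix


def separation_scores(dm: DistanceMatrix) -> np.ndarray:
    """Per-variety minimum distance to any other variety."""
    if dm.n < 2:
        raise ValueError("need at least 2 varieties")
    v = dm.values.copy()
    np.fill_diagonal(v, np.inf)
    return v.min(axis=1)


def _ranked_varieties(dm: DistanceMatrix) -> tuple[list[int], np.ndarray]:
    """Variety indices by descending separation, ties by id ascending."""
    scores = separation_scores(dm)
    order = sorted(
        range(dm.n), key=lambda i: (-scores[i], dm.variety_ids[i])
    )
    return order, scores


def d_set(dm: DistanceMatrix, size: int) -> DSet:
    """The ``size`` most separated ("D", distinct) varieties.

    Nested by construction: the set at size k is contained in the set at
    size k+1 under the fixed tie rule.
    """
    if not 1 <= size <= dm.n:
        raise ValueError(f"size must be in [1, {dm.n}], got {size}")
    order, scores = _ranked_varieties(dm)
    chosen = order[:size]
    return DSet(
        source=dm.source or "unknown",
        size=size,
        members=frozenset(dm.variety_ids[i] for i in chosen),
        threshold=float(scores[chosen[-1]]),
    )


def fraction_sizes(n: int, fractions: list[float]) -> list[int]:
    """Set sizes from threshold fractions, round-half-up.

    Fractions (0.1, 0.2, 0.4, 0.6, 0.8, 1.0) on a 122-variety panel give
    the ladder 12, 24, 49, 73, 98, 122.
    """
    sizes = []
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fractions must be in (0, 1], got {f}")
        sizes.append(int(np.floor(f * n + 0.5)))
    return sizes


def ladder_sizes(n: int, base_fraction: float = 0.1) -> list[int]:
    """The benchmark size ladder: base x (1, 2, 4, 6, 8) plus the full panel.

    With base_fraction 0.1 on a 122-variety panel this is the classic
    12, 24, 48, 72, 96, 122 ladder.
    """
    base = int(np.floor(base_fraction * n + 0.5))
    sizes = [min(base * k, n) for k in (1, 2, 4, 6, 8)]
    if sizes[-1] != n:
        sizes.append(n)
    # deduplicate while preserving order (tiny panels can saturate early)
    out: list[int] = []
    for s in sizes:
        if not out or s > out[-1]:
            out.append(s)
    return out


def reproduction_matrix(
    dm_phe: DistanceMatrix,
    dm_mol: DistanceMatrix,
    fractions: list[float] | None = None,
    sizes: list[int] | None = None,
) -> ReproductionMatrix:
    """Shared "D"-variety counts over phenotypic x molecular size ladders.

    ``shared[i][j]`` is the overlap between the phenotypic D set at the
    i-th size and the molecular D set at the j-th.  Sizes come from an
    explicit ``sizes`` list, from ``fractions`` of the panel
    (round-half-up), or default to :func:`ladder_sizes`.  Nesting of D
    sets makes every row and column monotone nondecreasing, and the
    full-panel margins equal the requested counts.
    """
    if dm_phe.variety_ids != dm_mol.variety_ids:
        raise ValueError("distance matrices are over different variety sets")
    if sizes is not None and fractions is not None:
        raise ValueError("give either sizes or fractions, not both")
    if sizes is None:
        if fractions is not None:
            sizes = fraction_sizes(dm_phe.n, list(fractions))
        else:
            sizes = ladder_sizes(dm_phe.n)
    if any(not 1 <= s <= dm_phe.n for s in sizes):
        raise ValueError("sizes out of range")
    phe_sets = [d_set(dm_phe, s).members for s in sizes]
    mol_sets = [d_set(dm_mol, s).members for s in sizes]
    shared = np.array(
        [[len(p & m) for m in mol_sets] for p in phe_sets], dtype=int
    )
    return ReproductionMatrix(
        phenotypic_sizes=sizes, molecular_sizes=list(sizes), shared=shared
    )
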