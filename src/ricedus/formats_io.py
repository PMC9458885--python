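"""Readers and writers for the standard formats the pipeline touches.

VCF is read through cyvcf2; everything else is plain delimited text.
No science lives here: genotype dosages come out exactly as coded in the
file (0/0 -> 0, het -> 0.5, 1/1 -> 1, ./. -> missing), and all readers
reject malformed cells instead of coercing them.
"""

from __future__ import annotations

import io
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import DistanceMatrix, GenotypeMatrix, LocusRecord, TraitTable


class FormatError(ValueError):
    """A file violates the expected format."""


def read_vcf(
    path: str | os.PathLike,
    variety_subset: list[str] | None = None,
) -> tuple[GenotypeMatrix, list[LocusRecord]]:
    """Read a diploid biallelic VCF into a dosage matrix.

    Dosages are coded on the unit scale: 0/0 -> 0, 0/1 or 1/0 -> 0.5,
    1/1 -> 1, ./. -> nan.  Phased separators are treated like unphased
    ones (only dosage matters).  Multiallelic or haploid records are
    rejected.  Loci are returned sorted by (chrom, pos); sample order is
    preserved (or follows ``variety_subset`` when given).
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF has no sample columns (GT field required)")
    if variety_subset is not None:
        unknown = [s for s in variety_subset if s not in samples]
        if unknown:
            raise KeyError(f"samples not in VCF: {unknown}")
        keep = [samples.index(s) for s in variety_subset]
        out_samples = list(variety_subset)
    else:
        keep = list(range(len(samples)))
        out_samples = samples

    loci: list[LocusRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; split upstream"
            )
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        col = np.empty(len(keep), dtype=float)
        for i, si in enumerate(keep):
            g = gts[si]
            if len(g) != 3:  # [a1, a2, phased] => diploid
                raise FormatError(
                    f"non-diploid call at {rec.CHROM}:{rec.POS} "
                    f"sample {out_samples[i]}"
                )
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                col[i] = np.nan
            else:
                col[i] = (a1 + a2) / 2.0
        rid = rec.ID if rec.ID not in (None, ".") else ""
        loci.append(
            LocusRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                id=rid,
            )
        )
        columns.append(col)
    vcf.close()

    if not columns:
        values = np.empty((len(out_samples), 0))
    else:
        values = np.column_stack(columns)
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].pos))
    loci = [loci[i] for i in order]
    values = values[:, order] if loci else values
    g = GenotypeMatrix(values=values, variety_ids=out_samples, loci=loci)
    return g, loci


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a dosage matrix back to a minimal VCF 4.2 text file."""
    def gt_of(v: float) -> str:
        if np.isnan(v):
            return "./."
        return {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}[float(v)]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.variety_ids)
            + "\n"
        )
        for j, loc in enumerate(g.loci):
            gts = "\t".join(gt_of(v) for v in g.values[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref_allele}\t"
                f"{loc.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_trait_table(path: str | os.PathLike | io.StringIO) -> TraitTable:
    """Read a delimited grade-code table (first column = variety id).

    Codes must be integers 1..9; blanks become missing.  Delimiter
    (comma or tab) is autodetected.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, index_col=0)
    codes = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            s = str(raw).strip()
            if s == "" or s.lower() == "nan":
                continue
            try:
                val = int(s)
            except ValueError:
                raise FormatError(
                    f"non-integer grade code {s!r} at variety "
                    f"{df.index[i]!r}, trait {col!r}"
                ) from None
            if not 1 <= val <= 9:
                raise FormatError(
                    f"grade code {val} out of 1..9 at variety "
                    f"{df.index[i]!r}, trait {col!r}"
                )
            codes[i, j] = val
    return TraitTable(
        codes=codes,
        trait_names=[str(c) for c in df.columns],
        variety_ids=[str(i) for i in df.index],
    )


def write_trait_table(t: TraitTable, path: str | os.PathLike) -> None:
    """Write grade codes as CSV with blank cells for missing values."""
    df = pd.DataFrame(t.codes, index=t.variety_ids, columns=t.trait_names)
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.index.name = "variety"
    df.to_csv(path)


def write_distance_matrix(dm: DistanceMatrix, path: str | os.PathLike) -> None:
    """Write a labelled square matrix as TSV (header row and column)."""
    df = pd.DataFrame(dm.values, index=dm.variety_ids, columns=dm.variety_ids)
    df.index.name = dm.metric or "distance"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_distance_matrix(
    path: str | os.PathLike, metric: str = "", source: str = ""
) -> DistanceMatrix:
    """Inverse of :func:`write_distance_matrix` (10 significant digits)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row/column labels differ")
    values = df.to_numpy(dtype=float)
    # tolerate last-digit asymmetry from decimal round trip
    values = (values + values.T) / 2.0
    return DistanceMatrix(
        values=values,
        variety_ids=[str(i) for i in df.index],
        metric=metric,
        source=source,
    )
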