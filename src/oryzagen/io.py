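"""Reading and writing the standard formats the pipeline touches.

VCF 4.x for genotypes (read through cyvcf2; multiallelic records are
skipped with a logged count), a headered TSV for sample metadata, and a
BED-like TSV for per-gene median read depths.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    DEPTH_COLUMNS,
    MISSING,
    SAMPLE_COLUMNS,
    DepthTable,
    GenotypeMatrix,
    SampleTable,
    ValidationError,
)

log = logging.getLogger(__name__)


def read_sample_table(path: str | Path) -> SampleTable:
    if not Path(path).exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "country": str})
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index=False, columns=SAMPLE_COLUMNS, float_format="%.6g")


def read_depth_table(path: str | Path) -> DepthTable:
    if not Path(path).exists():
        raise FileNotFoundError(f"depth file not found: {path}")
    return DepthTable(pd.read_csv(path, sep="\t"))


def write_depth_table(depths: DepthTable, path: str | Path) -> None:
    depths.df.to_csv(path, sep="\t", index=False, columns=DEPTH_COLUMNS, float_format="%.6g")


def load_dataset(vcf_path: str | Path, metadata_path: str | Path) -> tuple[GenotypeMatrix, SampleTable]:
    """Load a biallelic-SNP VCF and its matching metadata TSV.

    Multiallelic records are skipped (count logged).  Every VCF sample
    must appear in the metadata; a missing sample raises a
    :class:`ValidationError` naming it.
    """
    if not Path(vcf_path).exists():
        raise FileNotFoundError(f"VCF not found: {vcf_path}")
    samples = read_sample_table(metadata_path)

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    known = set(samples.sample_ids)
    absent = [s for s in sample_ids if s not in known]
    if absent:
        raise ValidationError(f"VCF samples absent from metadata: {absent}")

    chrom, pos, ref, alt = [], [], [], []
    geno_cols = []
    phased_flags = []
    n_skipped = 0
    for record in vcf:
        if len(record.ALT) != 1 or len(record.REF) != 1 or len(record.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom.append(record.CHROM)
        pos.append(record.POS)
        ref.append(record.REF)
        alt.append(record.ALT[0])
        gts = record.genotype.array()  # (n, 3): allele1, allele2, phased
        col = gts[:, :2].astype(np.int8)
        col[col < 0] = MISSING
        geno_cols.append(col)
        phased_flags.append(bool(np.all(gts[:, 2] == 1)))
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP record(s)", n_skipped)
    if not geno_cols:
        raise ValidationError("VCF contains no biallelic SNP records")

    genotypes = np.stack(geno_cols, axis=2)  # (n, 2, m)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=genotypes,
        phased=all(phased_flags),
    )
    return matrix, samples


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file."""
    sep = "|" if matrix.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=oryzagen\n")
        for c in pd.unique(matrix.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        g = matrix.genotypes
        for j in range(matrix.n_sites):
            fields = [
                str(matrix.chrom[j]),
                str(matrix.pos[j]),
                ".",
                str(matrix.ref[j]),
                str(matrix.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            col = g[:, :, j]
            calls = [
                sep.join("." if a == MISSING else str(int(a)) for a in col[i])
                for i in range(matrix.n_samples)
            ]
            fh.write("\t".join(fields + calls) + "\n")
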