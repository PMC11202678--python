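"""Readers and writers for genotype and phenotype files.

Genotypes travel either as biallelic VCF (GT field; read via cyvcf2) or as a
tab-delimited lines x markers dosage table with 0/1/2 and ``NA`` for missing.
The VCF writer emits plain-text VCF 4.2 with the dosage interpreted as the
ALT-allele count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phsgp.genotypes import GenotypeMatrix, RelationshipMatrix

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write the dosage matrix as biallelic VCF (dosage = ALT allele count)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=phsgp\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(pd.Series(g.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.line_ids))
            + "\n"
        )
        for j in range(g.n_markers):
            calls = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[:, j]
            )
            fh.write(
                f"{g.chrom[j]}\t{int(g.pos[j])}\t{g.marker_ids[j]}\tA\tB\t.\tPASS\t.\tGT\t"
                + calls
                + "\n"
            )


def read_vcf(path, program=None, set_label=None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix (ALT-allele counts)."""
    from cyvcf2 import VCF  # lazy: only needed for VCF input

    vcf = VCF(str(path))
    line_ids = np.asarray(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"marker {var.ID} is not biallelic")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
        ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        marker_ids=np.asarray(ids),
        line_ids=line_ids,
        chrom=np.asarray(chroms),
        pos=np.asarray(poss),
        program=program,
        set_label=set_label,
    )


def write_dosage_table(g: GenotypeMatrix, path) -> None:
    """Tab-delimited lines x markers table with line metadata columns."""
    df = pd.DataFrame(g.dosages, index=g.line_ids, columns=g.marker_ids)
    df.insert(0, "program", g.program)
    df.insert(1, "set", g.set_label)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="line")


def read_dosage_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line", na_values="NA")
    meta_cols = [c for c in ("program", "set") if c in df.columns]
    meta = df[meta_cols]
    dos = df.drop(columns=meta_cols)
    return GenotypeMatrix(
        dosages=dos.to_numpy(dtype=float),
        marker_ids=dos.columns.to_numpy(),
        line_ids=df.index.to_numpy(),
        program=meta["program"].to_numpy() if "program" in meta else None,
        set_label=meta["set"].to_numpy() if "set" in meta else None,
    )


def write_grm(A: RelationshipMatrix, path) -> None:
    A.to_frame().to_csv(path, index_label="line")


def read_grm(path) -> RelationshipMatrix:
    df = pd.read_csv(path, index_col="line")
    return RelationshipMatrix(
        values=df.to_numpy(dtype=float),
        line_ids=df.index.to_numpy(),
        p=np.array([]),
        denominator=float("nan"),
    )
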