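"""Readers and writers for the package's tabular formats.

TSV is the canonical interchange format (gene-bank phenotype data are
tabular); VCF ingestion of biallelic SNPs is optional and requires cyvcf2.
Missing labels are encoded as empty fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import DistanceMatrix, GenotypeMatrix, Kinship, PCoAResult

__all__ = [
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "read_records_tsv",
    "write_records_tsv",
    "read_blues_tsv",
    "write_blues_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_kinship_tsv",
    "read_kinship_tsv",
    "write_distance_tsv",
    "write_pcoa_tsv",
]


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Dosage matrix: rows = accessions (first column id), header = marker ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        geno.dosages, index=geno.accession_ids, columns=geno.marker_ids
    ).to_csv(path, sep="\t", index_label="accession")


def read_vcf(path) -> GenotypeMatrix:
    """ALT-allele dosages from the biallelic SNP records of a VCF.

    Note the resulting dosage counts the ALT allele; multi-allelic or
    non-SNP records and records with missing genotypes are skipped.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("VCF support requires the optional cyvcf2 dependency") from e
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        if np.any(gt == 2):
            continue
        dosage = np.where(gt == 3, 2.0, gt)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dosage)
    vcf.close()
    if not rows:
        raise ValueError("no usable biallelic SNP records in VCF")
    return GenotypeMatrix(samples, marker_ids, np.array(rows).T)


def read_records_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"accession": str})


def write_records_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_blues_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession", dtype={"accession": str})


def write_blues_tsv(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, sep="\t", index_label="accession")


def read_labels_tsv(path) -> pd.DataFrame:
    """Label table with an `accession` column; empty fields become NA."""
    return pd.read_csv(path, sep="\t", index_col="accession", dtype=str)


def write_labels_tsv(labels: pd.DataFrame | pd.Series, path) -> None:
    df = labels.to_frame() if isinstance(labels, pd.Series) else labels
    df.to_csv(path, sep="\t", index_label="accession", na_rep="")


def write_kinship_tsv(kin: Kinship, path) -> None:
    pd.DataFrame(kin.G, index=kin.accession_ids, columns=kin.accession_ids).to_csv(
        path, sep="\t", index_label="accession"
    )


def read_kinship_tsv(path) -> Kinship:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Kinship([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.D, index=dist.accession_ids, columns=dist.accession_ids).to_csv(
        path, sep="\t", index_label="accession"
    )


def write_pcoa_tsv(res: PCoAResult, path) -> None:
    k = res.coordinates.shape[1]
    df = pd.DataFrame(
        res.coordinates, index=res.accession_ids, columns=[f"PCo{i + 1}" for i in range(k)]
    )
    df.to_csv(path, sep="\t", index_label="accession")
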