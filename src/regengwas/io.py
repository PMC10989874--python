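"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 (biallelic, GT field) via cyvcf2 on the read side; GFF3 gene models
via gffutils; single-channel 8-bit PNG masks via imageio; CSV/TSV tables via
pandas. Writers emit plain uncompressed text so round-trips are lossless and
diffable.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .popstruct import Kinship
from .simulate import ToyAnnotation
from .traits import SegmentationMask

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write dosages as a minimal biallelic VCF 4.2 (A>T placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(G.chrom.astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j in range(G.n_snps):
            gts = "\t".join(_GT[int(d)] for d in G.dosages[:, j])
            fh.write(f"{G.chrom[j]}\t{G.pos[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic VCF into a GenotypeMatrix (dosage = ALT allele count)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chrom, pos, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        chrom.append(var.CHROM)
        pos.append(var.POS)
        rows.append(gt)
    vcf.close()
    dosages = np.vstack(rows).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(dosages=dosages, chrom=np.asarray(chrom, object),
                          pos=np.asarray(pos), sample_ids=samples)


def write_gff3(ann: ToyAnnotation, path: str) -> None:
    """Write gene features (1-based closed intervals) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, chrom, start, end, strand in ann.genes:
            fh.write(f"{chrom}\tregengwas\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={gid}\n")


def read_gff3(path: str) -> ToyAnnotation:
    """Read gene features from a GFF3 file into a ToyAnnotation."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
    return ToyAnnotation(genes=genes)


def write_traits_csv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_traits_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"genotype_id", "timepoint"}
    if not need <= set(df.columns):
        raise ValueError(f"trait CSV must carry columns {sorted(need)}")
    return df


def write_kinship(kin: Kinship, path: str) -> None:
    """Square TSV with sample header (row index = sample ids)."""
    pd.DataFrame(kin.K, index=kin.sample_ids, columns=kin.sample_ids).to_csv(
        path, sep="\t", float_format="%.10g")


def read_kinship(path: str, method: str = "file") -> Kinship:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Kinship(K=df.to_numpy(float), method=method,
                   sample_ids=[str(s) for s in df.columns])


def read_qmatrix(path: str) -> pd.DataFrame:
    """Ancestry-fraction matrix (Q model): rows = samples, columns = components.

    Tab-separated; rows must sum to 1 within tolerance.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rowsum = df.sum(axis=1).to_numpy()
    if not np.allclose(rowsum, 1.0, atol=1e-3):
        raise ValueError("Q-matrix rows must sum to 1")
    return df


def write_mask_png(mask: SegmentationMask, path: str) -> None:
    iio.imwrite(path, mask.labels.astype(np.uint8))


def read_mask_png(path: str, class_map: dict | None = None) -> SegmentationMask:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # tolerate grayscale saved with a channel axis
        arr = arr[..., 0]
    kwargs = {} if class_map is None else {"class_map": class_map}
    return SegmentationMask(labels=arr.astype(np.int64), **kwargs)
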