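"""VCF 4.2 and tab-delimited table input/output.

Genotypes travel as uncompressed VCF with per-genotype GT, GQ and AD
fields (via pysam); sample sheets, annotations, association tables and
QC reports as tab-delimited text.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .containers import MISSING, GenotypeMatrix

_GT_BY_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 with GT/GQ/AD."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom in pd.unique(matrix.variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    for sid in matrix.samples:
        header.add_sample(str(sid))

    with pysam.VariantFile(path, "w", header=header) as out:
        for j, (vid, row) in enumerate(matrix.variants.iterrows()):
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(vid),
            )
            dos = matrix.dosages[:, j]
            for i, sid in enumerate(matrix.samples):
                sample = rec.samples[str(sid)]
                d = int(dos[i])
                sample["GT"] = (None, None) if d == MISSING else _GT_BY_DOSAGE[d]
                if matrix.gq is not None:
                    sample["GQ"] = int(matrix.gq[i, j])
                if matrix.ad_ref is not None and matrix.ad_alt is not None:
                    sample["AD"] = (
                        int(matrix.ad_ref[i, j]), int(matrix.ad_alt[i, j])
                    )
            out.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read an uncompressed VCF 4.2 into a GenotypeMatrix.

    GT is converted to an additive alt-allele dosage (missing calls to
    -1); GQ and AD channels are populated when present.
    """
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        rows = []
        dosages, gqs, adr, ada = [], [], [], []
        has_gq = has_ad = False
        for rec in vf:
            rows.append(
                (rec.id, str(rec.contig), rec.pos, rec.ref, rec.alts[0])
            )
            d = np.empty(len(samples), dtype=np.int8)
            q = np.zeros(len(samples), dtype=np.int16)
            ar = np.zeros(len(samples), dtype=np.int32)
            aa = np.zeros(len(samples), dtype=np.int32)
            for i, sid in enumerate(samples):
                s = rec.samples[sid]
                gt = s.get("GT")
                if gt is None or any(a is None for a in gt):
                    d[i] = MISSING
                else:
                    d[i] = sum(gt)
                if s.get("GQ") is not None:
                    has_gq = True
                    q[i] = int(s["GQ"])
                ad = s.get("AD")
                if ad is not None and ad[0] is not None:
                    has_ad = True
                    ar[i], aa[i] = int(ad[0]), int(ad[1])
            dosages.append(d)
            gqs.append(q)
            adr.append(ar)
            ada.append(aa)
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    ).set_index("variant_id")
    return GenotypeMatrix(
        dosages=np.column_stack(dosages) if dosages else np.empty((len(samples), 0), np.int8),
        samples=pd.Index(samples, name="sample_id"),
        variants=variants,
        gq=np.column_stack(gqs) if has_gq else None,
        ad_ref=np.column_stack(adr) if has_ad else None,
        ad_alt=np.column_stack(ada) if has_ad else None,
    )


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_table(path: str, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
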