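"""Readers and writers for the plain-text formats the pipeline exchanges.

Every stage communicates through files (VCF 4.2, TSV, FASTA, GFF3, BED,
TRANSFAC matrices) so each stage can be re-run standalone.  Writers emit
deterministic byte-for-byte output for identical inputs; no timestamps.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import MISSING, TRAITS, GenotypeMatrix

# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write genotypes as uncompressed VCF 4.2.

    REF is the major allele (``a2``), ALT the counted minor allele (``a1``),
    so the in-memory 0/1/2 code equals the ALT-allele dosage.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = pd.unique(G.snps["chrom"].astype(str))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.animal_ids)
            + "\n"
        )
        codes = G.codes
        for j, rec in G.snps.iterrows():
            gts = "\t".join(_GT_STRINGS[int(g)] for g in codes[:, j])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.a2}\t{rec.a1}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF back into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    animal_ids = list(vcf.samples)
    rows, meta = [], []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "N"
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), v.POS, alt, v.REF))
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    snps = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "a1", "a2"])
    codes = np.vstack(rows).T if rows else np.empty((len(animal_ids), 0), np.int8)
    return GenotypeMatrix(animal_ids=animal_ids, snps=snps, codes=codes)


# ---------------------------------------------------------------------------
# Phenotypes


def write_phenotypes(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """TSV with ``animal_id`` plus one column per trait; NA for missing."""
    out = table.reset_index() if table.index.name == "animal_id" else table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"animal_id": str})
    if "animal_id" not in table.columns:
        raise ValueError("phenotype TSV must have an animal_id column")
    return table.set_index("animal_id")


def trait_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in TRAITS]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    records = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return records


# ---------------------------------------------------------------------------
# GFF3 (gene features only)

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(genes: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene records (gene_id, chrom, start, end, strand; 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in genes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\tsnp2tf\tgene\t{rec.start}\t{rec.end}\t.\t{rec.strand}"
                f"\t.\tID=gene:{rec.gene_id};Name={rec.gene_id}\n"
            )


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Parse ``gene`` records of a GFF3 file into a tidy frame.

    Only one interval per gene is used downstream, so transcript/exon features
    are ignored.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS, dtype={"seqid": str}
    )
    df = df[df["type"] == "gene"].copy()
    ids = df["attributes"].str.extract(r"ID=(?:gene:)?([^;]+)")[0]
    return pd.DataFrame(
        {
            "gene_id": ids.to_numpy(),
            "chrom": df["seqid"].to_numpy(),
            "start": df["start"].astype(int).to_numpy(),
            "end": df["end"].astype(int).to_numpy(),
            "strand": df["strand"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# BED (0-based half-open)


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=names)
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = names[: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# TRANSFAC matrices

_BASES = "ACGT"


def write_transfac(pwms, path: str | os.PathLike) -> None:
    """Write PWMs as TRANSFAC count blocks (ID/NA/P0 ... XX //)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.matrix_id}\nNA {pwm.tf_name}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(pwm.counts, start=1):
                vals = "  ".join(f"{v:8.4f}" for v in row)
                fh.write(f"{i:02d}  {vals}\n")
            fh.write("XX\n//\n")


def read_transfac(path: str | os.PathLike):
    """Parse TRANSFAC count blocks into :class:`snp2tf.motifs.PWM` objects."""
    from .motifs import PWM

    pwms = []
    matrix_id = tf_name = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("ID"):
                matrix_id = line.split(None, 1)[1].strip()
            elif line.startswith("NA"):
                tf_name = line.split(None, 1)[1].strip()
            elif line[:2].isdigit():
                rows.append([float(x) for x in line.split()[1:5]])
            elif line.startswith("//"):
                if matrix_id is not None and rows:
                    pwms.append(
                        PWM(
                            matrix_id=matrix_id,
                            tf_name=tf_name or matrix_id,
                            counts=np.asarray(rows, dtype=float),
                        )
                    )
                matrix_id = tf_name = None
                rows = []
    return pwms


def sha256_file(path: str | os.PathLike) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
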