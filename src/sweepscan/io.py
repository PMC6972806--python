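"""Genotype, annotation and sample-table I/O.

The pipeline's substrate is a diploid dosage matrix read from a
multi-sample VCF: one row per sample, one column per biallelic SNP, with
entries counting alternate alleles (0/1/2) and ``-1`` for missing calls.
All coordinates are 1-based inclusive internally; conversion to BED's
0-based half-open convention happens only when a BED file is written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

GROUPS = ("early", "mid", "late")


class EmptyInputError(ValueError):
    """Raised when an input file yields no usable records."""


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows of ``dosage``).
    chrom : ndarray of str
        Per-variant chromosome label; variants are grouped by chromosome.
    pos : ndarray of int
        Per-variant 1-based coordinate, strictly increasing within a
        chromosome.
    dosage : ndarray of int8, shape (n_samples, n_variants)
        Alternate-allele counts in {0, 1, 2}; ``-1`` marks a missing call.
    ref, alt : ndarray of str
        Single-base allele strings (only biallelic SNPs are stored).
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    ref: np.ndarray = field(default=None)
    alt: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.ref is None:
            self.ref = np.full(self.n_variants, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_variants, "G", dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.dosage.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("dosage shape does not match sample/variant counts")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        bad = (self.dosage < -1) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2,-1}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def variant_slice(self, chrom: str, start: int, end: int) -> slice:
        """Column slice of variants with ``start <= pos <= end`` on *chrom*."""
        mask = self.chrom == chrom
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return slice(0, 0)
        p = self.pos[idx]
        lo = int(np.searchsorted(p, start, side="left"))
        hi = int(np.searchsorted(p, end, side="right"))
        return slice(int(idx[0]) + lo, int(idx[0]) + hi)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            dosage=self.dosage[:, index],
            ref=self.ref[index],
            alt=self.alt[index],
        )

    def take_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            chrom=self.chrom,
            pos=self.pos,
            dosage=self.dosage[idx, :],
            ref=self.ref,
            alt=self.alt,
        )


def read_vcf(path, min_alleles: int = 2, max_alleles: int = 2) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Multiallelic records, indels and records outside the
    [min_alleles, max_alleles] allele-count range are skipped (counted and
    logged). Missing and half-called genotypes are stored as ``-1``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for v in vcf:
        n_all = 1 + len(v.ALT)
        if not (min_alleles <= n_all <= max_alleles):
            n_skipped += 1
            continue
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        cols.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not cols:
        raise EmptyInputError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=np.column_stack(cols),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


def write_vcf(matrix: GenotypeMatrix, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 with GT-only genotypes."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in matrix.chromosomes():
            if chrom_lengths and c in chrom_lengths:
                fh.write(f"##contig=<ID={c},length={chrom_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        for j in range(matrix.n_variants):
            gts = "\t".join(gt_str[int(d)] for d in matrix.dosage[:, j])
            fh.write(
                f"{matrix.chrom[j]}\t{matrix.pos[j]}\t.\t{matrix.ref[j]}\t"
                f"{matrix.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_gff(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand
    (1-based inclusive, as in GFF3). Only features of type ``gene`` are
    kept; records with end < start are rejected with a warning.
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            if end < start:
                n_bad += 1
                continue
            gene_id = None
            for attr in parts[8].split(";"):
                if attr.startswith("ID="):
                    gene_id = attr[3:].strip()
                    break
            if gene_id is None:
                gene_id = f"{chrom}:{start}-{end}"
            rows.append((gene_id, chrom, start, end, strand if strand in "+-" else "."))
    if n_bad:
        logger.warning("read_gff: rejected %d gene records with end < start", n_bad)
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df.empty:
        logger.warning("read_gff: no gene features found in %s", path)
    elif df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in GFF3")
    return df


def read_sample_table(path) -> pd.DataFrame:
    """Read the sample table TSV with header ``sample\\tgroup\\tregion``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group"}
    if not required.issubset(df.columns):
        raise ValueError("sample table must have columns 'sample' and 'group'")
    if "region" not in df.columns:
        df["region"] = ""
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown blooming groups: {sorted(bad)}; expected {GROUPS}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample table")
    return df[["sample", "group", "region"]]


def group_samples(sample_table: pd.DataFrame, group: str) -> list[str]:
    return sample_table.loc[sample_table["group"] == group, "sample"].tolist()


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write regions (1-based inclusive) as 0-based half-open BED.

    start_bed = start - 1, end_bed = end; output sorted by (chrom, start).
    """
    df = regions.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")
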