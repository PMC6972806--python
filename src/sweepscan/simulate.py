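"""Synthetic genotype panels with Balding-Nichols population structure.

The generator emulates the data a blooming-time sweep scan consumes: a
small diploid panel split into early / mid / late groups, background
differentiation between the early and late groups under the
Balding-Nichols model (group allele frequencies Beta-distributed around
an ancestral frequency with variance F p (1 - p), so the expected F_ST
equals F), and optional planted features - contiguous intervals where one
group's frequencies are pushed to fixation (collapsing its diversity and
inflating F_ST: a selective sweep) and a causal SNP contributing to the
phenotype. Sites are unlinked; defaults mirror a 19-accession panel
(6 early / 5 mid / 8 late).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, write_vcf


@dataclass
class SimConfig:
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"early": 6, "mid": 5, "late": 8}
    )
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    snp_density: float = 0.002  # SNPs per bp (~100 per 50-kb window)
    F: float = 0.1  # Balding-Nichols differentiation between early and late
    # (chrom, start, end, intensity); the swept group is `sweep_group`
    sweep_intervals: list[tuple[str, int, int, float]] = field(
        default_factory=lambda: [("LG1", 2_000_001, 2_500_000, 1.0)]
    )
    sweep_group: str = "early"
    causal_snp: tuple[str, int, float] | None = None  # (chrom, pos, effect)
    phenotype_noise_sd: float = 0.0
    n_genes: int = 200
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"LG{i + 1}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def validate(self) -> None:
        if not (0 < self.F < 1):
            raise ValueError("F must lie strictly between 0 and 1")
        lengths = self.chrom_lengths()
        for c, s, e, inten in self.sweep_intervals:
            if c not in lengths or not (1 <= s <= e <= lengths[c]):
                raise ValueError(f"sweep interval ({c},{s},{e}) outside genome")
            if not (0 <= inten <= 1):
                raise ValueError("sweep intensity must be in [0, 1]")


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw a genotype matrix and sample table under the configured model.

    Per site: ancestral frequency p ~ U(0.05, 0.95); early- and
    late-group frequencies drawn independently from
    Beta(p(1-F)/F, (1-p)(1-F)/F); the mid group uses the average of the
    two realized frequencies; genotypes are Binomial(2, p_g). Inside a
    sweep interval the swept group's frequency is set, with probability
    = intensity, to 1 (with probability p) or 0. Fully seeded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples: list[str] = []
    groups: list[str] = []
    prefix = {"early": "E", "mid": "M", "late": "L"}
    region = {"early": "south", "mid": "central", "late": "east"}
    for g in ("early", "mid", "late"):
        for i in range(config.n_per_group.get(g, 0)):
            samples.append(f"{prefix[g]}{i + 1:02d}")
            groups.append(g)
    sample_table = pd.DataFrame(
        {"sample": samples, "group": groups, "region": [region[g] for g in groups]}
    )
    chroms_all: list[np.ndarray] = []
    pos_all: list[np.ndarray] = []
    dos_all: list[np.ndarray] = []
    ref_all: list[np.ndarray] = []
    alt_all: list[np.ndarray] = []
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    for c in config.chrom_names():
        m = int(round(config.snp_density * config.chrom_length))
        pos = np.sort(rng.choice(config.chrom_length, size=m, replace=False)) + 1
        p = rng.uniform(0.05, 0.95, size=m)
        a = p * (1 - config.F) / config.F
        b = (1 - p) * (1 - config.F) / config.F
        freq = {
            "early": rng.beta(a, b),
            "late": rng.beta(a, b),
        }
        for chrom_i, s, e, inten in config.sweep_intervals:
            if chrom_i != c:
                continue
            inside = (pos >= s) & (pos <= e)
            hit = inside & (rng.random(m) < inten)
            fixed_to = (rng.random(m) < p).astype(float)
            fq = freq[config.sweep_group]
            freq[config.sweep_group] = np.where(hit, fixed_to, fq)
        freq["mid"] = 0.5 * (freq["early"] + freq["late"])
        dosage = np.empty((len(samples), m), dtype=np.int8)
        for i, g in enumerate(groups):
            dosage[i] = rng.binomial(2, freq[g])
        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        chroms_all.append(np.full(m, c, dtype=object))
        pos_all.append(pos.astype(np.int64))
        dos_all.append(dosage)
        ref_all.append(bases[ref_idx])
        alt_all.append(bases[alt_idx])
    matrix = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.concatenate(chroms_all),
        pos=np.concatenate(pos_all),
        dosage=np.concatenate(dos_all, axis=1),
        ref=np.concatenate(ref_all),
        alt=np.concatenate(alt_all),
    )
    return matrix, sample_table


def simulate_phenotype(
    sample_table: pd.DataFrame,
    matrix: GenotypeMatrix,
    causal_snp: tuple[str, int, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Ordinal group code, plus an optional causal-SNP effect and noise.

    phenotype = code(group) + effect * dosage(causal SNP) + N(0, noise_sd),
    aligned to ``matrix.sample_ids``.
    """
    code = {"early": 0.0, "mid": 1.0, "late": 2.0}
    by_sample = dict(zip(sample_table["sample"], sample_table["group"]))
    y = np.array([code[by_sample[s]] for s in matrix.sample_ids])
    if causal_snp is not None:
        chrom, pos, effect = causal_snp
        j = np.flatnonzero((matrix.chrom == chrom) & (matrix.pos == pos))
        if j.size == 0:
            raise ValueError(f"causal SNP {chrom}:{pos} not in matrix")
        dos = matrix.dosage[:, j[0]].astype(float)
        dos[dos < 0] = np.nan
        y = y + effect * np.nan_to_num(dos)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return y


def _write_gff(config: SimConfig, rng: np.random.Generator, path: Path) -> pd.DataFrame:
    names = config.chrom_names()
    chroms = rng.choice(len(names), size=config.n_genes)
    lengths = rng.integers(1_000, 5_001, size=config.n_genes)
    starts = rng.integers(1, config.chrom_length - 5_000, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    rows = sorted(
        (names[c], int(s), int(s + L - 1), str(st))
        for c, s, L, st in zip(chroms, starts, lengths, strands)
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (c, s, e, st) in enumerate(rows):
            fh.write(f"{c}\t.\tgene\t{s}\t{e}\t.\t{st}\t.\tID=g{i + 1:04d}\n")
    return pd.DataFrame(
        [(f"g{i + 1:04d}", c, s, e, st) for i, (c, s, e, st) in enumerate(rows)],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )


def emit_fixtures(config: SimConfig, outdir) -> dict[str, Path]:
    """Write VCF + GFF3 + sample TSV + truth TSV fixtures into *outdir*.

    Byte-identical across runs with the same config (the generator is a
    pure function of the seed). Returns the paths keyed by kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, sample_table = simulate_genotypes(config)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "gff": outdir / "genes.gff3",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(matrix, paths["vcf"], chrom_lengths=config.chrom_lengths())
    gene_rng = np.random.default_rng(config.seed + 1)
    _write_gff(config, gene_rng, paths["gff"])
    sample_table.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tchrom\tstart\tend\tvalue\n")
        for c, s, e, inten in config.sweep_intervals:
            fh.write(f"sweep\t{c}\t{s}\t{e}\t{inten}\n")
        if config.causal_snp is not None:
            c, pos, eff = config.causal_snp
            fh.write(f"causal_snp\t{c}\t{pos}\t{pos}\t{eff}\n")
    return paths
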