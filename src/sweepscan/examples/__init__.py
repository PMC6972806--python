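"""Worked-example tables from a published 19-cultivar *Prunus mume*
resequencing panel.

Three small summary tables serve as ready-made inputs for the arithmetic
the pipeline reports: per-cultivar CDS variant counts, the per-accession
genetic-diversity summary (genotyped/heterozygous site counts with derived
HetObs, pi and F_IS), and the coordinates of 21 published early-vs-late
selective-sweep regions (1-based inclusive). The panel's genome size is
roughly 280 Mb.
"""

from importlib import resources

import pandas as pd

GENOME_SIZE = 280_000_000


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_cds_variant_counts() -> pd.DataFrame:
    """Per-cultivar SNP/indel/SV counts within coding regions."""
    return _load("cds_variant_counts.tsv")


def load_diversity_summary() -> pd.DataFrame:
    """Per-accession site counts and diversity statistics."""
    return _load("diversity_summary.tsv")


def load_sweep_regions() -> pd.DataFrame:
    """Published early-vs-late sweep regions (chrom, start, end, length)."""
    return _load("sweep_regions.tsv")
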