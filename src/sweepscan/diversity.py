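"""Per-individual and per-window diversity statistics.

Per-individual statistics follow the single-diploid convention: with one
diploid genome, the observed heterozygosity is the fraction of genotyped
sites that are heterozygous, the per-individual nucleotide diversity is
half that fraction (two haplotypes differ at exactly the heterozygous
sites), and the inbreeding coefficient F_IS = 1 - Hobs/Hexp evaluates to
-1 at every polymorphic site (Hobs = 1 and, with allele frequency 1/2 in
a single diploid, Hexp = 1/2), hence -1 overall whenever any
heterozygous site exists and undefined otherwise.

Window statistics are the standard frequency-based estimators on unphased
dosages: nucleotide diversity pi with the n/(n-1) small-sample factor,
Watterson's theta from the segregating-site count and the harmonic number
a_{n-1}, and the Weir & Cockerham (1984) F_ST variance-components
estimator aggregated ratio-of-sums across the sites of a window. All
per-bp quantities are divided by the full window span, not the callable
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix


@dataclass
class IndividualDiversity:
    sample_id: str
    n_sites: int
    n_polymorphic: int
    n_invariant: int
    het_obs: float
    pi_ind: float
    f_is: float | None  # None when no heterozygous site exists


def individual_diversity(matrix: GenotypeMatrix, sample_id: str) -> IndividualDiversity:
    """Per-sample genotyped/heterozygous site counts and derived statistics."""
    i = matrix.sample_index([sample_id])[0]
    row = matrix.dosage[i]
    called = row != MISSING
    n_sites = int(called.sum())
    if n_sites == 0:
        raise ValueError(f"sample {sample_id!r} has no genotyped sites")
    n_poly = int((row == 1).sum())
    het_obs = n_poly / n_sites
    return IndividualDiversity(
        sample_id=sample_id,
        n_sites=n_sites,
        n_polymorphic=n_poly,
        n_invariant=n_sites - n_poly,
        het_obs=het_obs,
        pi_ind=het_obs / 2.0,
        f_is=-1.0 if n_poly > 0 else None,
    )


def window_iter(chrom_length: int, window: int = 50_000, step: int = 10_000):
    """Yield 1-based inclusive (start, end) sliding windows.

    Windows start at 1, 1+step, 1+2*step, ...; the last window is truncated
    at chrom_length and may be short. A window whose untruncated end would
    already extend past the previous window's truncated end is not emitted,
    so K = ceil((L - window) / step) + 1 windows for L > window.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if chrom_length <= window:
        yield (1, chrom_length)
        return
    k = -(-(chrom_length - window) // step) + 1  # ceil division
    for i in range(k):
        start = i * step + 1
        yield (start, min(start + window - 1, chrom_length))


def _site_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (alt allele count, called allele count) per site for a
    samples x sites dosage block."""
    called = dosage != MISSING
    alt = np.where(called, dosage, 0).sum(axis=0)
    n = 2 * called.sum(axis=0)
    return alt.astype(np.int64), n.astype(np.int64)


def pi_from_counts(alt: np.ndarray, n: np.ndarray, span: int) -> float:
    """Per-bp pi: sum over sites of [n/(n-1)] 2 p (1-p), divided by span."""
    ok = n >= 2
    if not ok.any():
        return 0.0
    alt, n = alt[ok], n[ok]
    p = alt / n
    per_site = (n / (n - 1)) * 2.0 * p * (1.0 - p)
    return float(per_site.sum()) / span


def window_pi(matrix: GenotypeMatrix, samples, start: int, end: int, chrom: str | None = None) -> float:
    """Nucleotide diversity per bp of [start, end] for the given samples."""
    if chrom is None:
        chrom = matrix.chrom[0]
    sl = matrix.variant_slice(chrom, start, end)
    idx = matrix.sample_index(samples)
    alt, n = _site_counts(matrix.dosage[idx, sl])
    return pi_from_counts(alt, n, end - start + 1)


def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def theta_w_from_counts(alt: np.ndarray, n: np.ndarray, n_haplotypes: int, span: int) -> float:
    """Per-bp Watterson estimator: S / a_{n-1} / span."""
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes for Watterson's theta")
    seg = (alt > 0) & (alt < n) & (n >= 2)
    s = int(seg.sum())
    if s == 0:
        return 0.0
    return s / harmonic(n_haplotypes - 1) / span


def window_theta_w(matrix: GenotypeMatrix, samples, start: int, end: int, chrom: str | None = None) -> float:
    """Watterson's theta per bp over [start, end] for the given samples.

    The haplotype count is 2 x the number of samples with at least one
    non-missing call in the window.
    """
    if chrom is None:
        chrom = matrix.chrom[0]
    sl = matrix.variant_slice(chrom, start, end)
    idx = matrix.sample_index(samples)
    block = matrix.dosage[idx, sl]
    n_with_data = int((block != MISSING).any(axis=1).sum())
    alt, n = _site_counts(block)
    return theta_w_from_counts(alt, n, 2 * n_with_data, end - start + 1)


def wc_fst_components(
    alt1: np.ndarray, n1: np.ndarray, het1: np.ndarray,
    alt2: np.ndarray, n2: np.ndarray, het2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components for two populations.

    Inputs are per-site alternate-allele counts, called *diploid sample*
    counts and heterozygote counts for each population. Returns (a, a+b+c)
    arrays; sites where either population has fewer than 2 called samples
    get 0 in both (they drop out of the ratio of sums).
    """
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, alt1 / (2 * n1), 0.0)
        p2 = np.where(n2 > 0, alt2 / (2 * n2), 0.0)
        h1 = np.where(n1 > 0, het1 / n1, 0.0)
        h2 = np.where(n2 > 0, het2 / n2, 0.0)
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(usable, a, 0.0)
    abc = np.where(usable, a + b + c, 0.0)
    return a, abc


def _group_site_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(alt allele count, called diploid count, het count) per site."""
    called = dosage != MISSING
    alt = np.where(called, dosage, 0).sum(axis=0).astype(np.int64)
    n = called.sum(axis=0).astype(np.int64)
    het = (dosage == 1).sum(axis=0).astype(np.int64)
    return alt, n, het


def window_fst(
    matrix: GenotypeMatrix, group_a, group_b, start: int, end: int, chrom: str | None = None,
    estimator: str = "wc",
) -> float:
    """Multi-locus F_ST between two sample groups over a window.

    ``estimator='wc'`` (default) is Weir-Cockerham 1984 ratio-of-sums;
    ``estimator='hudson'`` is Hudson's (1992) ratio-of-averages
    1 - Hw/Hb. Returns NaN when no site is informative.
    """
    if chrom is None:
        chrom = matrix.chrom[0]
    sl = matrix.variant_slice(chrom, start, end)
    ia = matrix.sample_index(group_a)
    ib = matrix.sample_index(group_b)
    alt1, n1, het1 = _group_site_stats(matrix.dosage[ia, sl])
    alt2, n2, het2 = _group_site_stats(matrix.dosage[ib, sl])
    if estimator == "wc":
        a, abc = wc_fst_components(alt1, n1, het1, alt2, n2, het2)
        denom = abc.sum()
        if denom == 0:
            return float("nan")
        return float(a.sum() / denom)
    if estimator == "hudson":
        return hudson_fst(alt1, 2 * n1, alt2, 2 * n2)
    raise ValueError(f"unknown F_ST estimator {estimator!r}")


def hudson_fst(alt1, n1, alt2, n2) -> float:
    """Hudson F_ST = 1 - mean(Hw)/mean(Hb) from per-site allele counts
    (n1, n2 are haploid counts)."""
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        return float("nan")
    a1, m1, a2, m2 = alt1[ok], n1[ok], alt2[ok], n2[ok]
    p1, p2 = a1 / m1, a2 / m2
    hw = (p1 * (1 - p1) * m1 / (m1 - 1) + p2 * (1 - p2) * m2 / (m2 - 1)) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb.sum() == 0:
        return float("nan")
    return float(1.0 - hw.sum() / hb.sum())
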