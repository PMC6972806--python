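"""Kinship-corrected association of genotype with the blooming-time groups.

The stage mirrors a standard small-panel GWAS: SNPs are filtered on
per-sample call rate (>= 80%), per-SNP missing rate (<= 10%), minor
allele frequency (>= 5%) and a Hardy-Weinberg exact test (drop p < 1e-3);
association uses a single-random-effect linear mixed model
y = X beta + u + e with cov(u) = sigma_g^2 K, solved EMMAX-style: the
variance ratio is estimated once on the null model by REML after an
eigendecomposition of the kinship matrix K, then every SNP is tested by
weighted least squares in the rotated basis with the weight shape held
fixed and the residual scale re-estimated per SNP (t-test, df = n - 2).
P-values are adjusted with the Benjamini-Hochberg step-up procedure and
significant SNPs are assigned to genes within a 2-kb flank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import MISSING, GenotypeMatrix

PHENOTYPE_CODE = {"early": 0.0, "mid": 1.0, "late": 2.0}


@dataclass
class FilterReport:
    n_input: int
    n_after_sample_callrate: int
    n_after_missing: int
    n_after_maf: int
    n_after_hwe: int
    dropped_samples: list[str]


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditional on the allele counts, sums the probabilities of every
    heterozygote count whose probability does not exceed that of the
    observed count (probability-mass criterion, no mid-p correction).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het) = log[ n! / (hr! het! ha!) * 2^het ] - log[ (2n)! / (r! a!) ]
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        special.gammaln(n + 1)
        - special.gammaln(hom_rare + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_common + 1)
        + hets * math.log(2.0)
    )
    logp -= special.logsumexp(logp)
    p_obs = logp[np.flatnonzero(hets == n_het)[0]]
    keep = logp <= p_obs + 1e-12
    return float(min(1.0, math.exp(special.logsumexp(logp[keep]))))


def filter_snps(
    matrix: GenotypeMatrix,
    missing_max: float = 0.10,
    maf_min: float = 0.05,
    sample_callrate_min: float = 0.80,
    hwe_alpha: float = 0.001,
    hwe_literal: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the association-stage SNP and sample filters, in order.

    1) drop samples with call rate < sample_callrate_min;
    2) drop SNPs with missing rate > missing_max (recomputed on kept samples);
    3) drop SNPs with minor allele frequency < maf_min;
    4) drop SNPs failing the HWE exact test (p < hwe_alpha conventionally;
       ``hwe_literal=True`` instead keeps only SNPs with p <= hwe_alpha).
    """
    n_input = matrix.n_variants
    called = matrix.dosage != MISSING
    callrate = called.mean(axis=1)
    keep_samples = [s for s, c in zip(matrix.sample_ids, callrate) if c >= sample_callrate_min]
    dropped = [s for s in matrix.sample_ids if s not in keep_samples]
    m = matrix.take_samples(keep_samples) if dropped else matrix

    called = m.dosage != MISSING
    miss = 1.0 - called.mean(axis=0)
    keep = miss <= missing_max
    n_after_missing = int(keep.sum())

    alt = np.where(called, m.dosage, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / n_alleles, 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep &= maf >= maf_min
    n_after_maf = int(keep.sum())

    for j in np.flatnonzero(keep):
        col = m.dosage[:, j]
        hr = int((col == 0).sum())
        het = int((col == 1).sum())
        ha = int((col == 2).sum())
        pv = hwe_exact_p(hr, het, ha)
        if (pv > hwe_alpha) if hwe_literal else (pv < hwe_alpha):
            keep[j] = False
    n_after_hwe = int(keep.sum())
    if n_after_hwe == 0:
        raise ValueError("all SNPs removed by association filters")
    report = FilterReport(
        n_input=n_input,
        n_after_sample_callrate=n_input,
        n_after_missing=n_after_missing,
        n_after_maf=n_after_maf,
        n_after_hwe=n_after_hwe,
        dropped_samples=dropped,
    )
    return m.take_variants(np.flatnonzero(keep)), report


def kinship(matrix: GenotypeMatrix) -> np.ndarray:
    """Standardized genomic relationship matrix.

    K = (1/m) sum_sites (g - 2p)(g - 2p)^T / (2p(1-p)) with missing
    dosages mean-imputed per site. Sites must be polymorphic (the
    association filters guarantee this upstream).
    """
    if matrix.n_variants < 2:
        raise ValueError("need >= 2 SNPs for kinship")
    g = matrix.dosage.astype(float)
    called = g != MISSING
    alt = np.where(called, g, 0.0).sum(axis=0)
    n_alleles = 2.0 * called.sum(axis=0)
    p = alt / n_alleles
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic site reached kinship; run filter_snps first")
    g = np.where(called, g, 2.0 * p)  # mean imputation
    z = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (z @ z.T) / matrix.n_variants


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    delta = math.exp(log_delta)
    v = lam + delta
    w = 1.0 / v
    xtwx = xr.T @ (xr * w[:, None])
    xtwy = xr.T @ (yr * w)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = yr - xr @ beta
    n, p = xr.shape
    rss = float(resid @ (resid * w))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    _, logdet_xtwx = np.linalg.slogdet(xtwx)
    _, logdet_xtx = np.linalg.slogdet(xr.T @ xr)
    ll = -0.5 * (
        (n - p) * math.log(2 * math.pi * sigma2)
        + float(np.log(v).sum())
        + logdet_xtwx
        - logdet_xtx
        + (n - p)
    )
    return -ll


def fit_null_delta(
    lam: np.ndarray, yr: np.ndarray, xr: np.ndarray, grid: int = 61
) -> float:
    """REML estimate of delta = sigma_e^2 / sigma_g^2 on the null model."""
    logd = np.linspace(math.log(1e-5), math.log(1e5), grid)
    vals = [_reml_neg_loglik(ld, lam, yr, xr) for ld in logd]
    k = int(np.argmin(vals))
    lo = logd[max(k - 1, 0)]
    hi = logd[min(k + 1, grid - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, yr, xr), method="bounded"
    )
    return math.exp(float(res.x))


def lmm_assoc(
    matrix: GenotypeMatrix, phenotype: np.ndarray, K: np.ndarray
) -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    Returns a DataFrame with chrom, pos, beta, se, p_value. Degenerate
    cases (constant phenotype, zero-variance SNP after rotation) report
    beta = 0, se = NaN, p = 1.
    """
    y = np.asarray(phenotype, dtype=float)
    n = matrix.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match sample count")
    lam, u = np.linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    yr = u.T @ y
    ones_r = u.T @ np.ones(n)
    if np.var(y) == 0:
        return pd.DataFrame(
            {"chrom": matrix.chrom, "pos": matrix.pos,
             "beta": 0.0, "se": np.nan, "p_value": 1.0}
        )
    delta = fit_null_delta(lam, yr, ones_r[:, None])
    v = lam + delta
    if (v <= 0).any():
        raise np.linalg.LinAlgError("transformed covariance not positive definite")
    w = 1.0 / v
    g = matrix.dosage.astype(float)
    called = g != MISSING
    alt = np.where(called, g, 0.0).sum(axis=0)
    p_hat = alt / (2.0 * called.sum(axis=0))
    g = np.where(called, g, 2.0 * p_hat)
    gr = u.T @ g  # n x m rotated genotypes
    # WLS with X = [1, g] on whitened data; project out the intercept
    # first (numerically stable when some weights are very large)
    sw = np.sqrt(w)
    yw = yr * sw
    onew = ones_r * sw
    gw = gr * sw[:, None]
    onorm2 = float(onew @ onew)
    y_t = yw - onew * (float(onew @ yw) / onorm2)
    g_t = gw - onew[:, None] * ((onew @ gw) / onorm2)[None, :]
    gtg = (g_t * g_t).sum(axis=0)
    gty = g_t.T @ y_t
    yty = float(y_t @ y_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gty / gtg
        rss = np.maximum(yty - beta * gty, 0.0)
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / gtg)
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # a genotype (near-)collinear with the intercept in whitened space
    # carries no testable signal
    gw_norm2 = (gw * gw).sum(axis=0)
    bad = ~np.isfinite(beta) | (gtg <= 1e-10 * np.maximum(gw_norm2, 1e-300))
    beta = np.where(bad, 0.0, beta)
    se = np.where(bad | ~np.isfinite(se), np.nan, se)
    pvals = np.where(bad | ~np.isfinite(t), 1.0, pvals)
    return pd.DataFrame(
        {"chrom": matrix.chrom, "pos": matrix.pos,
         "beta": beta, "se": se, "p_value": pvals}
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def assign_genes(
    assoc: pd.DataFrame, gene_table: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Attach gene ids to SNPs within a gene body or its flank.

    A SNP is assigned to every gene whose [start - flank, end + flank]
    interval (1-based inclusive) contains the SNP position.
    """
    genes_col = []
    for row in assoc.itertuples(index=False):
        g = gene_table[
            (gene_table["chrom"] == row.chrom)
            & (gene_table["start"] - flank <= row.pos)
            & (gene_table["end"] + flank >= row.pos)
        ]
        genes_col.append(g["gene_id"].tolist())
    out = assoc.copy()
    out["genes"] = genes_col
    return out


def run_association(
    matrix: GenotypeMatrix,
    sample_table: pd.DataFrame,
    gene_table: pd.DataFrame | None = None,
    fdr: float = 0.01,
    flank: int = 2000,
    **filter_kwargs,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter, kinship-correct, test, BH-adjust and annotate in one call."""
    filtered, report = filter_snps(matrix, **filter_kwargs)
    codes = dict(zip(sample_table["sample"], sample_table["group"]))
    y = np.array([PHENOTYPE_CODE[codes[s]] for s in filtered.sample_ids])
    K = kinship(filtered)
    res = lmm_assoc(filtered, y, K)
    res["q_value"] = bh_adjust(res["p_value"].to_numpy())
    res["significant"] = res["q_value"] <= fdr
    if gene_table is not None:
        res = assign_genes(res, gene_table, flank=flank)
    return res, report
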