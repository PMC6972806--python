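"""Sliding-window sweep scan and region calling.

The scan contrasts two blooming-time groups (conventionally the "high" =
late-blooming and "low" = early-blooming cultivars). For each 50-kb
window sliding in 10-kb steps it computes per-group nucleotide diversity
pi, Watterson's theta over the pooled contrast samples, Weir-Cockerham
F_ST between the groups, and the log2 ratio pi_high / pi_low. Candidate
selective sweeps are windows falling jointly in the 5% right tail of the
empirical F_ST distribution AND the 5% right tail of the log2-ratio
distribution; overlapping or book-ended significant windows are merged
into regions. Large positive log2 ratios flag diversity loss in the low
group, the signature of a sweep there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import (
    _group_site_stats,
    harmonic,
    wc_fst_components,
    window_iter,
)
from .io import MISSING, GenotypeMatrix


@dataclass
class ScanThresholds:
    fst_cut: float
    ratio_cut: float
    quantile: float = 0.05


def log2_ratio(pi_high: float, pi_low: float) -> float:
    """log2(pi_high / pi_low); +inf when pi_low = 0 < pi_high, NaN when both 0."""
    if pi_high < 0 or pi_low < 0:
        raise ValueError("negative nucleotide diversity")
    if pi_high == 0 and pi_low == 0:
        return float("nan")
    if pi_low == 0:
        return float("inf")
    if pi_high == 0:
        return float("-inf")
    return math.log2(pi_high / pi_low)


def scan_windows(
    matrix: GenotypeMatrix,
    high_samples,
    low_samples,
    window: int = 50_000,
    step: int = 10_000,
    min_snps: int = 10,
    max_missing_frac: float = 0.5,
    chrom_lengths: dict[str, int] | None = None,
    fst_estimator: str = "wc",
) -> pd.DataFrame:
    """Per-window scan statistics for a two-group contrast.

    Returns a DataFrame with one row per window: chrom, start, end,
    n_snps, pi_high, pi_low, theta_w, fst, log2_ratio, usable. A window
    is usable when it has >= min_snps sites informative in both groups,
    a defined F_ST, and at least one group with nonzero pi. Sites with
    more than ``max_missing_frac`` missing genotypes inside a group (or
    fewer than 2 called samples there) are excluded from that window's
    statistics.
    """
    if len(high_samples) < 2 or len(low_samples) < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    ih = matrix.sample_index(high_samples)
    il = matrix.sample_index(low_samples)
    rows = []
    for c in matrix.chromosomes():
        cmask = matrix.chrom == c
        cpos = matrix.pos[cmask]
        dh = matrix.dosage[np.ix_(ih, np.flatnonzero(cmask))]
        dl = matrix.dosage[np.ix_(il, np.flatnonzero(cmask))]
        alt_h, n_h, het_h = _group_site_stats(dh)
        alt_l, n_l, het_l = _group_site_stats(dl)
        ok_h = (n_h >= 2) & (n_h >= (1 - max_missing_frac) * len(ih))
        ok_l = (n_l >= 2) & (n_l >= (1 - max_missing_frac) * len(il))
        ok = ok_h & ok_l
        # per-site pi contributions (n/(n-1) * 2p(1-p)) on haploid counts
        def site_pi(alt, n, mask):
            m = 2.0 * n
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(m > 0, alt / m, 0.0)
                v = np.where(m > 1, m / (m - 1) * 2.0 * p * (1 - p), 0.0)
            return np.where(mask, v, 0.0)

        pi_h_site = site_pi(alt_h, n_h, ok)
        pi_l_site = site_pi(alt_l, n_l, ok)
        if fst_estimator == "wc":
            a_site, abc_site = wc_fst_components(alt_h, n_h, het_h, alt_l, n_l, het_l)
            a_site = np.where(ok, a_site, 0.0)
            abc_site = np.where(ok, abc_site, 0.0)
        else:
            raise ValueError(f"unsupported scan F_ST estimator {fst_estimator!r}")
        alt_t = alt_h + alt_l
        n_t = n_h + n_l
        seg = ok & (alt_t > 0) & (alt_t < 2 * n_t)
        # per-sample called indicator cumsums for the theta_w haplotype count
        called_hl = (np.vstack([dh, dl]) != MISSING)
        ccum = np.concatenate(
            [np.zeros((called_hl.shape[0], 1), dtype=np.int32),
             np.cumsum(called_hl, axis=1, dtype=np.int32)], axis=1
        )

        def wsum(x, lo, hi):
            cs = np.concatenate([[0.0], np.cumsum(x)])
            return cs[hi] - cs[lo]

        length = int(chrom_lengths[c]) if chrom_lengths else int(cpos[-1])
        wins = list(window_iter(length, window, step))
        starts = np.array([w[0] for w in wins])
        ends = np.array([w[1] for w in wins])
        lo = np.searchsorted(cpos, starts, side="left")
        hi = np.searchsorted(cpos, ends, side="right")
        n_ok = wsum(ok.astype(float), lo, hi).astype(int)
        spans = ends - starts + 1
        pi_h = wsum(pi_h_site, lo, hi) / spans
        pi_l = wsum(pi_l_site, lo, hi) / spans
        s_w = wsum(seg.astype(float), lo, hi)
        a_w = wsum(a_site, lo, hi)
        abc_w = wsum(abc_site, lo, hi)
        n_called_window = (ccum[:, hi] - ccum[:, lo] > 0).sum(axis=0)
        for k in range(len(wins)):
            nh2 = 2 * int(n_called_window[k])
            theta = (s_w[k] / harmonic(nh2 - 1) / spans[k]) if nh2 >= 2 and s_w[k] > 0 else 0.0
            fst = a_w[k] / abc_w[k] if abc_w[k] != 0 else float("nan")
            lr = log2_ratio(float(pi_h[k]), float(pi_l[k]))
            usable = (
                int(n_ok[k]) >= min_snps
                and not math.isnan(fst)
                and not math.isnan(lr)
            )
            rows.append(
                (c, int(starts[k]), int(ends[k]), int(n_ok[k]),
                 float(pi_h[k]), float(pi_l[k]), float(theta), float(fst), lr, usable)
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "pi_high", "pi_low",
                 "theta_w", "fst", "log2_ratio", "usable"],
    )


def thresholds(windows: pd.DataFrame, quantile: float = 0.05) -> ScanThresholds:
    """Empirical right-tail cutoffs over usable windows (nearest-rank).

    The cut is the order statistic at rank ceil((1 - quantile) * n); a
    window is significant iff fst > fst_cut AND log2_ratio > ratio_cut.
    """
    use = windows[windows["usable"]]
    n = len(use)
    if n < 20:
        raise ValueError(f"only {n} usable windows; need >= 20 for empirical tails")
    rank = math.ceil((1.0 - quantile) * n)  # 1-based
    rank = min(max(rank, 1), n)
    fst_cut = float(np.sort(use["fst"].to_numpy())[rank - 1])
    ratio_cut = float(np.sort(use["log2_ratio"].to_numpy())[rank - 1])
    return ScanThresholds(fst_cut=fst_cut, ratio_cut=ratio_cut, quantile=quantile)


def significant_windows(windows: pd.DataFrame, cuts: ScanThresholds) -> pd.DataFrame:
    mask = (
        windows["usable"]
        & (windows["fst"] > cuts.fst_cut)
        & (windows["log2_ratio"] > cuts.ratio_cut)
    )
    return windows[mask]


def call_regions(sig_windows: pd.DataFrame, min_length: int = 0) -> pd.DataFrame:
    """Merge overlapping/book-ended significant windows into sweep regions.

    Returns chrom, start, end, length, n_windows sorted by (chrom, start);
    regions shorter than min_length are dropped.
    """
    out = []
    for c, grp in sig_windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        n_win = 0
        for row in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, n_win = row.start, row.end, 1
            elif row.start <= cur_e + 1:
                cur_e = max(cur_e, row.end)
                n_win += 1
            else:
                out.append((c, cur_s, cur_e, cur_e - cur_s + 1, n_win))
                cur_s, cur_e, n_win = row.start, row.end, 1
        if cur_s is not None:
            out.append((c, cur_s, cur_e, cur_e - cur_s + 1, n_win))
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "length", "n_windows"])
    df = df[df["length"] >= min_length]
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def region_summary(regions: pd.DataFrame, genome_size: int) -> dict:
    """Count, total/mean/max length and percent of genome covered."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if len(regions) == 0:
        raise ValueError("no regions to summarize")
    lengths = regions["length"].to_numpy()
    total = int(lengths.sum())
    return {
        "n_regions": int(len(regions)),
        "total_bp": total,
        "mean_bp": float(lengths.mean()),
        "max_bp": int(lengths.max()),
        "pct_genome": 100.0 * total / genome_size,
    }


def genes_in_regions(regions: pd.DataFrame, gene_table: pd.DataFrame) -> list[list[str]]:
    """Per-region gene-id lists: gene assigned iff closed intervals intersect."""
    result = []
    for reg in regions.itertuples(index=False):
        g = gene_table[
            (gene_table["chrom"] == reg.chrom)
            & (gene_table["start"] <= reg.end)
            & (gene_table["end"] >= reg.start)
        ]
        result.append(g["gene_id"].tolist())
    return result


def segment_genes(
    sweep_genes: pd.DataFrame, bin_size: int = 1_000_000, min_genes: int = 5
) -> pd.DataFrame:
    """Group sweep genes into 1-Mb bins and merge adjacent non-empty bins.

    Genes are assigned to the bin containing their midpoint; runs of
    adjacent non-empty bins on a chromosome are merged into segments;
    segments with no more than ``min_genes`` genes are discarded.
    Returns chrom, start, end, n_genes, gene_ids.
    """
    if sweep_genes.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_genes", "gene_ids"])
    g = sweep_genes.copy()
    g["mid"] = (g["start"] + g["end"]) // 2
    g["bin"] = (g["mid"] - 1) // bin_size
    out = []
    for c, grp in g.groupby("chrom", sort=False):
        counts = grp.groupby("bin")["gene_id"].apply(list).sort_index()
        bins = counts.index.to_numpy()
        run_start = None
        prev = None
        genes: list[str] = []
        for b in bins:
            if run_start is None:
                run_start, prev, genes = b, b, list(counts[b])
            elif b == prev + 1:
                prev = b
                genes.extend(counts[b])
            else:
                out.append((c, int(run_start * bin_size + 1), int((prev + 1) * bin_size), genes))
                run_start, prev, genes = b, b, list(counts[b])
        if run_start is not None:
            out.append((c, int(run_start * bin_size + 1), int((prev + 1) * bin_size), genes))
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "gene_ids"])
    df["n_genes"] = df["gene_ids"].map(len)
    df = df[df["n_genes"] > min_genes]
    return df[["chrom", "start", "end", "n_genes", "gene_ids"]].reset_index(drop=True)
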