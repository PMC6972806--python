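"""Linkage-disequilibrium decay from unphased dosages.

r-squared is the squared Pearson correlation of alternate-allele dosage
vectors over the samples non-missing at both sites (composite LD; no
phasing or haplotype EM). Pairs are pooled into physical-distance bins
and the half-decay distance is where the binned mean r2 first falls to
half its maximum, linearly interpolated between bin midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix


@dataclass
class LDCurve:
    bin_edges: np.ndarray  # length n_bins + 1, bp
    mean_r2: np.ndarray    # length n_bins; NaN for empty bins
    n_pairs: np.ndarray    # length n_bins
    half_decay_distance: float | None  # bp; None if never reached

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def pair_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing at both sites; NaN when fewer than
    two such samples remain or either site is monomorphic among them.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return float("nan")
    va = a - a.mean()
    vb = b - b.mean()
    den = (va @ va) * (vb @ vb)
    if den == 0:
        return float("nan")
    return float((va @ vb) ** 2 / den)


def half_decay(midpoints: np.ndarray, means: np.ndarray) -> float | None:
    """Distance at which mean r2 first reaches half its maximum.

    Linear interpolation between the bin midpoints bracketing the
    crossing; None if the curve never reaches half-maximum (including
    the single-bin case).
    """
    ok = ~np.isnan(means)
    mids, vals = midpoints[ok], means[ok]
    if len(vals) < 2:
        return None
    target = 0.5 * float(vals.max())
    below = np.flatnonzero(vals <= target)
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(mids[0])
    x0, y0, x1, y1 = mids[i - 1], vals[i - 1], mids[i], vals[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))


def _r2_pairs(dosage: np.ndarray, ii: np.ndarray, jj: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """Vectorized pairwise-complete r2 for index pairs (ii[k], jj[k])."""
    out = np.empty(len(ii), dtype=float)
    for s in range(0, len(ii), chunk):
        a = dosage[:, ii[s : s + chunk]].astype(float)
        b = dosage[:, jj[s : s + chunk]].astype(float)
        mask = (a != MISSING) & (b != MISSING)
        a = np.where(mask, a, 0.0)
        b = np.where(mask, b, 0.0)
        m = mask.sum(axis=0)
        sa, sb = a.sum(axis=0), b.sum(axis=0)
        saa = (a * a).sum(axis=0)
        sbb = (b * b).sum(axis=0)
        sab = (a * b).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = m * sab - sa * sb
            den = (m * saa - sa * sa) * (m * sbb - sb * sb)
            r2 = np.where((m >= 2) & (den > 0), cov * cov / den, np.nan)
        out[s : s + chunk] = r2
    return out


def ld_curve(
    matrix: GenotypeMatrix,
    max_dist: int = 500_000,
    bin_width: int = 10_000,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> LDCurve:
    """Binned mean r2 over all intra-chromosomal pairs within max_dist.

    With ``max_pairs`` set, a seeded uniform subsample of the enumerated
    pairs is scored instead of all of them.
    """
    if not (max_dist >= bin_width >= 1):
        raise ValueError("need max_dist >= bin_width >= 1")
    pairs_i: list[np.ndarray] = []
    pairs_j: list[np.ndarray] = []
    for c in matrix.chromosomes():
        idx = np.flatnonzero(matrix.chrom == c)
        pos = matrix.pos[idx]
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for k in range(len(idx)):
            if hi[k] > k + 1:
                j = np.arange(k + 1, hi[k])
                pairs_i.append(np.full(len(j), idx[k]))
                pairs_j.append(idx[0] + j)
    if not pairs_i:
        raise ValueError("no SNP pairs within max_dist")
    ii = np.concatenate(pairs_i)
    jj = np.concatenate(pairs_j)
    if max_pairs is not None and len(ii) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(ii), size=max_pairs, replace=False)
        keep.sort()
        ii, jj = ii[keep], jj[keep]
    dist = matrix.pos[jj] - matrix.pos[ii]
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.minimum(np.maximum(dist - 1, 0) // bin_width, n_bins - 1)
    r2 = _r2_pairs(matrix.dosage, ii, jj)
    ok = ~np.isnan(r2)
    sums = np.bincount(which[ok], weights=r2[ok], minlength=n_bins)
    counts = np.bincount(which[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (edges[:-1] + edges[1:]) / 2.0
    return LDCurve(
        bin_edges=edges,
        mean_r2=means,
        n_pairs=counts,
        half_decay_distance=half_decay(mids, means),
    )
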