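import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sweepscan.assoc import (
    PHENOTYPE_CODE,
    assign_genes,
    bh_adjust,
    filter_snps,
    hwe_exact_p,
    kinship,
    lmm_assoc,
)
from sweepscan.simulate import SimConfig, simulate_genotypes, simulate_phenotype

from conftest import central_common_snp, make_matrix


# ---------------------------------------------------------------- oracles

def hwe_enum_oracle(n_hom_ref, n_het, n_hom_alt):
    """Exact-rational enumeration of the conditional heterozygote-count
    distribution given the allele counts."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_ref + n_het
    nb = 2 * n_hom_alt + n_het
    denom = math.factorial(2 * n) // (math.factorial(na) * math.factorial(nb))
    probs = {}
    for h in range(min(na, nb) + 1):
        if (na - h) % 2:
            continue
        hr, ha = (na - h) // 2, (nb - h) // 2
        num = (math.factorial(n)
               // (math.factorial(hr) * math.factorial(h) * math.factorial(ha))) * 2**h
        probs[h] = Fraction(num, denom)
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


# ----------------------------------------------------------------- filters

def test_filter_snps_threshold_arithmetic():
    """19 samples: MAF >= 5% of 38 alleles means minor count >= 2, so
    singletons go; a SNP missing in 2/19 samples (10.5%) goes too."""
    rng = np.random.default_rng(0)
    dosage = rng.binomial(2, 0.4, size=(19, 6)).astype(np.int8)
    dosage[:, 0] = 0
    dosage[0, 0] = 1            # singleton: MAF = 1/38 < 0.05
    dosage[:2, 1] = -1          # missing rate 2/19 > 0.10
    dosage[:, 2] = 0            # monomorphic
    dosage[:, 3] = [1] * 10 + [0, 0, 0, 0, 0, 2, 2, 2, 2]  # kept
    m = make_matrix(dosage)
    filtered, report = filter_snps(m)
    assert report.n_input == 6
    kept_pos = set(filtered.pos)
    assert {100, 200, 300} & kept_pos == set()
    assert 400 in kept_pos
    assert report.n_after_missing == 5
    assert report.n_after_maf <= report.n_after_missing
    assert report.n_after_hwe == filtered.n_variants


def test_filter_snps_sample_callrate_stage_runs_first():
    dosage = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (10, 1))
    dosage[0, :3] = -1  # sample 0: call rate 1/4 < 0.8
    m = make_matrix(dosage)
    filtered, report = filter_snps(m, maf_min=0.0, hwe_alpha=0.0)
    assert report.dropped_samples == ["S1"]
    assert filtered.n_samples == 9
    # with the bad sample gone no SNP has missing calls
    assert report.n_after_missing == 4


def test_filter_snps_hwe_direction_and_literal_flag():
    # all-het SNP at n=19 has tiny HWE p -> dropped conventionally
    dosage = np.ones((19, 2), dtype=np.int8)
    dosage[:, 1] = [0] * 5 + [1] * 9 + [2] * 5
    m = make_matrix(dosage)
    filtered, _ = filter_snps(m)
    assert list(filtered.pos) == [200]
    literal, _ = filter_snps(m, hwe_literal=True)
    assert list(literal.pos) == [100]


def test_filter_snps_all_removed_raises():
    m = make_matrix(np.zeros((19, 3), dtype=np.int8))
    with pytest.raises(ValueError, match="all SNPs removed"):
        filter_snps(m)


# --------------------------------------------------------------------- HWE

def test_hwe_exact_monomorphic_and_tiny():
    assert hwe_exact_p(10, 0, 0) == 1.0
    assert hwe_exact_p(0, 0, 7) == 1.0
    assert hwe_exact_p(0, 2, 0) == pytest.approx(hwe_enum_oracle(0, 2, 0))


def test_hwe_exact_matches_enumeration_on_random_counts():
    rng = np.random.default_rng(5)
    for _ in range(150):
        n = int(rng.integers(1, 51))
        hr = int(rng.integers(0, n + 1))
        het = int(rng.integers(0, n - hr + 1))
        ha = n - hr - het
        assert hwe_exact_p(hr, het, ha) == pytest.approx(
            hwe_enum_oracle(hr, het, ha), abs=1e-12
        )
    with pytest.raises(ValueError):
        hwe_exact_p(-1, 0, 0)


# ----------------------------------------------------------------- kinship

def test_kinship_duplicate_sample_and_centering():
    rng = np.random.default_rng(6)
    dosage = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(6, 200)).astype(np.int8)
    dosage[5] = dosage[0]  # duplicate individual
    keep = (dosage.sum(axis=0) > 0) & (dosage.sum(axis=0) < 12)
    m = make_matrix(dosage[:, keep], pos=np.arange(1, keep.sum() + 1))
    K = kinship(m)
    assert np.allclose(K, K.T)
    assert K[0, 5] == pytest.approx(K[0, 0]) == pytest.approx(K[5, 5])
    # complete data: columns of the standardized matrix have zero mean
    assert np.abs(K.sum(axis=0)).max() < 1e-9


def test_kinship_separates_groups(neutral_panel):
    _, m, t = neutral_panel
    filtered, _ = filter_snps(m)
    K = kinship(filtered)
    idx = {g: [filtered.sample_ids.index(s)
               for s in t[t["group"] == g]["sample"]] for g in ("early", "late")}
    within = np.mean([K[i, j] for g in ("early", "late")
                      for i in idx[g] for j in idx[g] if i != j])
    between = np.mean([K[i, j] for i in idx["early"] for j in idx["late"]])
    assert within > between


def test_kinship_rejects_monomorphic():
    m = make_matrix(np.array([[0, 1], [0, 1], [0, 0]], dtype=np.int8))
    with pytest.raises(ValueError, match="monomorphic"):
        kinship(m)


# --------------------------------------------------------------------- LMM

def test_lmm_constant_phenotype():
    cfg = SimConfig(seed=8, n_chrom=1, chrom_length=200_000, sweep_intervals=[])
    m, _ = simulate_genotypes(cfg)
    filtered, _ = filter_snps(m)
    res = lmm_assoc(filtered, np.full(filtered.n_samples, 1.0), kinship(filtered))
    assert (res["beta"] == 0).all() and (res["p_value"] == 1.0).all()


def test_lmm_reduces_to_ols_without_relatedness():
    """With K = 0 the GLS weights are uniform and every p-value matches
    ordinary linear regression to 1e-8."""
    cfg = SimConfig(seed=9, n_chrom=1, chrom_length=300_000, sweep_intervals=[])
    m, t = simulate_genotypes(cfg)
    filtered, _ = filter_snps(m)
    y = simulate_phenotype(t, filtered)
    res = lmm_assoc(filtered, y, np.zeros((filtered.n_samples, filtered.n_samples)))
    for j in range(0, filtered.n_variants, 37):
        g = filtered.dosage[:, j].astype(float)
        if np.var(g) == 0:
            continue
        lr = stats.linregress(g, y)
        assert res["p_value"][j] == pytest.approx(lr.pvalue, abs=1e-8)
        assert res["beta"][j] == pytest.approx(lr.slope, abs=1e-8)


def test_lmm_causal_snp_attains_min_p():
    """Large-effect common causal SNP wins the scan in >=95% of 20 seeds
    (n ~ 100 samples; small panels are underpowered for this check)."""
    npg = {"early": 34, "mid": 33, "late": 33}
    hits = 0
    for seed in range(20):
        cfg = SimConfig(seed=200 + seed, n_chrom=1, chrom_length=1_000_000,
                        sweep_intervals=[], n_per_group=npg)
        m, t = simulate_genotypes(cfg)
        filtered, _ = filter_snps(m)
        j = central_common_snp(filtered)
        y = simulate_phenotype(
            t, filtered,
            causal_snp=(filtered.chrom[j], int(filtered.pos[j]), 2.0),
            noise_sd=0.1, seed=300 + seed,
        )
        res = lmm_assoc(filtered, y, kinship(filtered))
        hits += int(np.argmin(res["p_value"].to_numpy())) == j
    assert hits >= 19


def test_lmm_null_calibration_at_moderate_n():
    """Permuted phenotype: fraction of p < alpha within binomial tolerance
    of alpha (n ~ 100 samples)."""
    cfg = SimConfig(seed=500, n_chrom=1, chrom_length=1_000_000, sweep_intervals=[],
                    n_per_group={"early": 34, "mid": 33, "late": 33})
    m, t = simulate_genotypes(cfg)
    filtered, _ = filter_snps(m)
    K = kinship(filtered)
    rng = np.random.default_rng(0)
    y = rng.permutation(simulate_phenotype(t, filtered))
    p = lmm_assoc(filtered, y, K)["p_value"].to_numpy()
    for alpha in (0.05, 0.01):
        tol = 3.5 * math.sqrt(alpha * (1 - alpha) / len(p))
        assert abs((p < alpha).mean() - alpha) <= tol


# ---------------------------------------------------------------------- BH

def test_bh_adjust_worked_example():
    q = bh_adjust([0.001, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.004, 0.04, 0.04, 0.04])
    assert (bh_adjust(np.ones(5)) == 1.0).all()
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_adjust_matches_reference_implementation():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    for _ in range(1000):
        p = rng.uniform(size=rng.integers(1, 40))
        q = bh_adjust(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)
        # monotone in p-rank and never below p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


def test_bh_null_data_rarely_discovers():
    """FDR 0.01 on global-null mixed-model p-values: zero discoveries in
    >=99% of replicates."""
    cfg = SimConfig(seed=42, n_chrom=1, chrom_length=200_000, sweep_intervals=[],
                    n_per_group={"early": 7, "mid": 6, "late": 7})
    m, _ = simulate_genotypes(cfg)
    filtered, _ = filter_snps(m)
    K = kinship(filtered)
    rng = np.random.default_rng(0)
    clean = 0
    for _ in range(100):
        y = rng.normal(size=filtered.n_samples)
        q = bh_adjust(lmm_assoc(filtered, y, K)["p_value"].to_numpy())
        clean += bool((q > 0.01).all())
    assert clean >= 99


# ------------------------------------------------------------ gene mapping

def test_assign_genes_flank_boundaries():
    genes = pd.DataFrame(
        [("g1", "c", 10_000, 12_000, "+")],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    hits = pd.DataFrame({"chrom": ["c", "c", "c"], "pos": [8_500, 8_000, 7_999]})
    out = assign_genes(hits, genes)
    assert out["genes"].tolist() == [["g1"], ["g1"], []]


def test_assign_genes_matches_brute_force():
    rng = np.random.default_rng(13)
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(150)],
        "chrom": rng.choice(["a", "b"], 150),
        "start": (gs := rng.integers(1, 200_000, 150)),
        "end": gs + rng.integers(0, 4_000, 150),
        "strand": "+",
    })
    snps = pd.DataFrame({
        "chrom": rng.choice(["a", "b"], 100),
        "pos": rng.integers(1, 200_000, 100),
    })
    out = assign_genes(snps, genes, flank=2000)
    for k, row in enumerate(snps.itertuples(index=False)):
        brute = [g.gene_id for g in genes.itertuples(index=False)
                 if g.chrom == row.chrom and g.start - 2000 <= row.pos <= g.end + 2000]
        assert out["genes"][k] == brute
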