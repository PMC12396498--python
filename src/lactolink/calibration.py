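"""Reproducible validation studies for the statistical engines.

Each study regenerates synthetic data under the package's reference
conditions, runs the corresponding engine, and returns the measured
operating characteristic (error, rejection rate, power, recovery). They
back both the test suite and the reproduction script, so the numbers a
user sees are always recomputed, never stored.

Independent oracles used here (exact integer combinatorics for the
hypergeometric tail, the definitional BH step-up, the step-by-step
running-sum walk) deliberately avoid the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, hypergeom_upper_tail
from .association import fit_time_model, standardize
from .coexpression import sample_coexpression, reproducibility_summary
from .data import GeneSetLibrary
from .de import _fit_nb, de_hmo_lrt, de_wald
from .enrichment import preranked_enrichment
from .simulate import (
    HMOSpec,
    SimConfig,
    simulate_dataset,
    simulate_de_pseudobulk,
    simulate_hmo_linked_pseudobulk,
    simulate_hmo_panel,
)


# --------------------------------------------------------------------------
# independent oracles


def enum_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exhaustive hypergeometric upper tail with exact integer combinatorics."""
    tot = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    ) / tot


def bh_definitional(p) -> np.ndarray:
    """BH step-up straight from the definition (cumulative min over ranks)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def walk_es(scores, hit_flags, weight: float) -> float:
    """Step-by-step weighted running-sum enrichment score."""
    scores = np.asarray(scores, float)
    hits = np.asarray(hit_flags, bool)
    denom = np.sum(np.abs(scores[hits]) ** weight)
    n_miss = int((~hits).sum())
    running, best, best_abs = 0.0, 0.0, -1.0
    for s, h in zip(scores, hits):
        running += (abs(s) ** weight / denom) if h else (-1.0 / n_miss)
        if abs(running) > best_abs:
            best_abs, best = abs(running), running
    return best


# --------------------------------------------------------------------------
# hypergeometric kernel


def kernel_enumeration_error(max_n: int = 30) -> dict:
    """Max |kernel - enumeration| over every valid configuration with N <= max_n."""
    worst, count = 0.0, 0
    for N in range(max_n + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    err = abs(hypergeom_upper_tail(k, N, K, n) - enum_upper_tail(k, N, K, n))
                    worst = max(worst, err)
                    count += 1
    return {"max_abs_error": worst, "n_configs": count}


def kernel_symmetry_error(seed: int, n_tuples: int = 10_000) -> dict:
    """Max |p(N,K,n,k) - p(N,n,K,k)| over random valid tuples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tuples):
        N = int(rng.integers(1, 1000))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        lo, hi = max(0, K + n - N), min(K, n)
        k = int(rng.integers(lo, hi + 1))
        worst = max(worst, abs(hypergeom_upper_tail(k, N, K, n)
                               - hypergeom_upper_tail(k, N, n, K)))
    return {"max_abs_error": worst, "n_tuples": n_tuples}


# --------------------------------------------------------------------------
# co-expression calibration


def coexpression_null_study(seed: int) -> dict:
    """Per-(pair, sample) significant fraction with nothing planted.

    Thirty disjoint gene pairs over 24 samples with ~40k cells each and
    ~50% detection: large margins keep the exact test's discreteness
    negligible, and disjoint pairs keep records effectively independent.
    """
    cfg = SimConfig(
        seed=seed, n_donors=8, samples_per_donor=3, n_genes=60,
        cells_per_sample_range=(40_000, 45_000), baseline_mean=0.77,
        gene_mean_log_sd=0.15,
        cell_type_mix={"LC1": 0.1, "LC2": 0.8, "immune": 0.1},
    )
    ds = simulate_dataset(cfg)
    genes = [f"G{i + 1:04d}" for i in range(60)]
    pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(30)]
    rec = sample_coexpression(ds.cells, pairs, "LC2", alpha=0.05)
    eligible = rec[rec["eligible"]]
    n = len(eligible)
    rate = float(eligible["significant"].mean())
    half = 1.96 * math.sqrt(0.05 * 0.95 / n)
    return {"rate": rate, "n_records": n, "band": (0.05 - half, 0.05 + half)}


def planted_pair_study(seed: int) -> dict:
    """Reproducibility of one strongly co-regulated pair across 20 samples."""
    cfg = SimConfig(
        seed=seed, n_donors=10, samples_per_donor=2, n_genes=30,
        cells_per_sample_range=(250, 350),
        planted_pairs=[("G0001", "G0002", "LC2", 8.0)],
        mean_overrides=[("G0001", "LC2", 0.3), ("G0002", "LC2", 0.3)],
    )
    ds = simulate_dataset(cfg)
    rec = sample_coexpression(ds.cells, [("G0001", "G0002")], "LC2", alpha=0.05)
    row = reproducibility_summary(rec).iloc[0]
    return {
        "pct_significant": float(row["pct_significant"]),
        "n_eligible": int(row["n_eligible_samples"]),
    }


# --------------------------------------------------------------------------
# mixed-model calibration


LMM_DONOR_SD = 0.3
LMM_RESID_SD = 0.2
LMM_SLOPE = -0.5  # per SD of time postpartum


def _lmm_truth() -> float:
    """Standardized slope implied by the trajectory parameters: the response
    is z-scored, so the fitted coefficient targets b*sd_t/sd_y."""
    sd_signal = abs(LMM_SLOPE)
    sd_y = math.sqrt(LMM_SLOPE**2 + LMM_DONOR_SD**2 + LMM_RESID_SD**2)
    return math.copysign(sd_signal / sd_y, LMM_SLOPE)


def _lmm_panel(seed: int, slope_per_sd: float) -> pd.DataFrame:
    sd_t = (272.0 - 4.0) / math.sqrt(12.0)  # uniform sampling times
    cfg = SimConfig(
        seed=seed, n_donors=10, samples_per_donor=3, n_genes=1,
        hmo_specs={"SIM": HMOSpec(10.0, slope_per_sd / sd_t, LMM_DONOR_SD, LMM_RESID_SD)},
    )
    return simulate_hmo_panel(cfg)


def lmm_recovery_study(seed: int, n_reps: int = 200) -> dict:
    """Mean recovered standardized time slope over replicate cohorts."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    estimates = []
    for s in seeds:
        res = fit_time_model(_lmm_panel(int(s), LMM_SLOPE), "SIM")
        if res.converged:
            estimates.append(res.estimate)
    return {
        "mean_estimate": float(np.mean(estimates)),
        "truth": _lmm_truth(),
        "n_converged": len(estimates),
        "n_reps": n_reps,
    }


def lmm_type1_study(seed: int, n_reps: int = 500) -> dict:
    """Rejection rate at p <= 0.05 under the zero-slope null."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rejections = []
    for s in seeds:
        res = fit_time_model(_lmm_panel(int(s), 0.0), "SIM")
        if res.converged:
            rejections.append(res.pvalue <= 0.05)
    n = len(rejections)
    half = 1.96 * math.sqrt(0.05 * 0.95 / n)
    return {"rate": float(np.mean(rejections)), "n": n,
            "band": (0.05 - half, 0.05 + half)}


# --------------------------------------------------------------------------
# NB-GLM engine calibration


def wald_type1_study(seed: int, n_genes: int = 2000) -> dict:
    """Wald rejection rate at p <= 0.05 with no expression difference.

    Cohort shaped like the integrated resource: 3 studies x 24 samples,
    each contributing an LC1 and an LC2 pseudobulk row.
    """
    pb = simulate_de_pseudobulk(
        seed=seed, n_samples_per_study=24, n_studies=3, n_genes=n_genes,
        dispersion_alpha=0.1,
    ).with_size_factors()
    res = de_wald(pb)
    conv = res[res["converged"]]
    n = len(conv)
    half = 1.96 * math.sqrt(0.05 * 0.95 / n)
    return {"rate": float((conv["pvalue"] <= 0.05).mean()), "n": n,
            "band": (0.05 - half, 0.05 + half)}


def wald_recovery_study(seed: int, n_reps: int = 20) -> dict:
    """Fraction of replicate cohorts recovering a true LFC of 2 within 0.3.

    One planted gene per 150-gene cohort (20 samples/group), so size-factor
    normalization is undisturbed.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    estimates = []
    for s in seeds:
        lfc = np.zeros(150)
        lfc[0] = 2.0
        pb = simulate_de_pseudobulk(seed=int(s), n_samples_per_study=10,
                                    n_studies=2, n_genes=150, lfc=lfc,
                                    dispersion_alpha=0.1).with_size_factors()
        estimates.append(float(de_wald(pb)["log2fc"].iloc[0]))
    estimates = np.asarray(estimates)
    return {
        "fraction_within_0.3": float((np.abs(estimates - 2.0) <= 0.3).mean()),
        "mean_estimate": float(estimates.mean()),
        "n_reps": n_reps,
    }


def lrt_power_study(seed: int, n_linked: int = 20) -> dict:
    """LRT power for a 1 log2-per-SD concentration effect at 20 samples."""
    pb, panel = simulate_hmo_linked_pseudobulk(
        seed=seed, n_donors=10, samples_per_donor=2, n_genes=120,
        dispersion_alpha=0.1, linked_lfc={i: 1.0 for i in range(n_linked)},
    )
    res = de_hmo_lrt(pb, panel, "LNT", cell_type="LC2")
    linked = res.iloc[:n_linked]
    return {
        "power": float((linked["pvalue"] <= 0.05).mean()),
        "sign_positive": float((linked["log2fc"] > 0).mean()),
        "n_linked": n_linked,
    }


def poisson_limit_check(seed: int) -> dict:
    """Max coefficient difference between NB (alpha -> 0) and Poisson fits."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(10):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.poisson(np.exp(1.2 + 0.7 * X[:, 1]))
        offset = np.zeros(n)
        nb, conv = _fit_nb(y, X, 1e-10, offset)
        pois = sm.GLM(y.astype(float), X, family=sm.families.Poisson(),
                      offset=offset).fit()
        if conv:
            worst = max(worst, float(np.abs(nb.params - pois.params).max()))
    return {"max_abs_coef_diff": worst, "n_fits": 10}


# --------------------------------------------------------------------------
# multiple testing and enrichment


def bh_agreement_study(seed: int, n_vectors: int = 1000) -> dict:
    """Max |package BH - definitional BH| over random p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(size=int(rng.integers(1, 80)))
        worst = max(worst, float(np.abs(bh_adjust(p) - bh_definitional(p)).max()))
    return {"max_abs_diff": worst, "n_vectors": n_vectors}


def enrichment_toy_es() -> dict:
    """ES of the 5-gene worked instance, with its brute-force walk value."""
    scores = np.array([3.0, 2.0, 1.0, -1.0, -2.0])
    genes = [f"g{i}" for i in range(5)]
    ranked = pd.DataFrame({"gene": genes, "score": scores,
                           "log2fc": np.sign(scores), "pvalue": 0.5})
    lib = GeneSetLibrary("toy", {"s": ["g0", "g2"]})
    res = preranked_enrichment(ranked, lib, weight=1.0, n_perm=100, seed=0)
    hits = np.array([True, False, True, False, False])
    return {"es": float(res.loc[0, "es"]), "oracle": walk_es(scores, hits, 1.0)}


def ks_reduction_study(seed: int, n_instances: int = 100) -> dict:
    """Max ||ES(weight=0)| - KS statistic| over random instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 60))
        scores = np.sort(rng.normal(size=n))[::-1]
        size = int(rng.integers(2, n - 2))
        members = rng.choice(n, size=size, replace=False)
        genes = [f"g{i}" for i in range(n)]
        ranked = pd.DataFrame({"gene": genes, "score": scores,
                               "log2fc": np.sign(scores), "pvalue": 0.5})
        lib = GeneSetLibrary("r", {"s": [genes[i] for i in members]})
        res = preranked_enrichment(ranked, lib, weight=0.0, n_perm=100, seed=1)
        miss = np.setdiff1d(np.arange(n), members)
        ks = stats.ks_2samp(np.sort(members), miss, method="asymp").statistic
        worst = max(worst, abs(abs(float(res.loc[0, "es"])) - ks))
    return {"max_abs_diff": worst, "n_instances": n_instances}
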