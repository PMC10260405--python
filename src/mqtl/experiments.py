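"""Calibration and power studies run on synthetic cohorts.

Each function simulates its own data from an integer seed and measures one
operating characteristic of the pipeline: credible-set coverage of the
fine mapper, H4 sensitivity / H3 specificity of the colocalization engine,
GWAS type-I error, REML recovery of a planted heritability, PQN recovery
of planted urine dilution, and the EHH contrast on a constructed sweep.
The analysis drivers and the acceptance machinery both consume these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import coloc as _coloc
from . import ehh as _ehh
from . import finemap as _finemap
from . import gwas as _gwas
from . import heritability as _h2
from . import qc as _qc
from . import synthetic as _syn


def _centered(y: np.ndarray, ids: list[str]) -> pd.Series:
    return pd.Series(y - y.mean(), index=ids)


def finemap_coverage(
    n_sims: int = 500,
    n_samples: int = 2000,
    n_snps: int = 50,
    ld_r2: float = 0.9,
    beta: float = 0.35,
    threshold: float = 3.9e-11,
    seed: int = 1,
) -> dict:
    """Fraction of single-causal simulations whose planted SNP lands in
    the >99% credible set.  Also reports mean set size and the share of
    sims with no genome-wide signal (counted as misses)."""
    rng_master = np.random.default_rng(seed)
    covered = 0
    no_signal = 0
    sizes = []
    for s in range(n_sims):
        panel_seed, noise_seed = rng_master.integers(0, 2**31 - 1, 2)
        panel = _syn.simulate_genotypes(
            n_samples, [(n_snps, ld_r2, (0.2, 0.5))], seed=int(panel_seed)
        )
        rng = np.random.default_rng(int(noise_seed))
        causal = n_snps // 2
        y = beta * panel.dosages[:, causal] + rng.normal(0, 1, n_samples)
        res = _finemap.finemap_region(
            list(panel.snps["snp"]), _centered(y, panel.sample_ids), panel, threshold
        )
        if not res.credible_sets:
            no_signal += 1
            continue
        cs = res.credible_sets[0]
        sizes.append(cs.size)
        if panel.snps["snp"].iloc[causal] in cs.snps:
            covered += 1
    return {
        "coverage": covered / n_sims,
        "mean_set_size": float(np.mean(sizes)) if sizes else float("nan"),
        "no_signal": no_signal,
        "n_sims": n_sims,
    }


def coloc_discrimination(
    n_sims: int = 200,
    n_samples: int = 2000,
    n_snps: int = 40,
    beta: float = 0.6,
    z_min: float = 8.0,
    seed: int = 2,
) -> dict:
    """H4 sensitivity on shared-causal pairs (conditioning on both z-peaks
    clearing ``z_min``) and H3 rate on distinct-causal low-LD pairs."""
    rng_master = np.random.default_rng(seed)
    shared_pos = 0
    shared_n = 0
    max_pp_err = 0.0
    for _ in range(n_sims):
        s1, s2 = rng_master.integers(0, 2**31 - 1, 2)
        panel = _syn.simulate_genotypes(
            n_samples, [(n_snps, 0.6, (0.2, 0.5))], seed=int(s1)
        )
        rng = np.random.default_rng(int(s2))
        x = panel.dosages[:, n_snps // 2]
        ta = _gwas.run_gwas(
            _centered(beta * x + rng.normal(0, 1, n_samples), panel.sample_ids), panel
        )
        tb = _gwas.run_gwas(
            _centered(beta * x + rng.normal(0, 1, n_samples), panel.sample_ids), panel
        )
        za = np.abs(ta["beta"] / ta["se"]).max()
        zb = np.abs(tb["beta"] / tb["se"]).max()
        if min(za, zb) < z_min:
            continue
        res = _coloc.coloc_abf(ta, tb)
        shared_n += 1
        max_pp_err = max(max_pp_err, abs(res.posteriors().sum() - 1.0))
        if res.pp_h4 > 0.8:
            shared_pos += 1

    distinct_h3 = 0
    n_distinct = max(1, n_sims // 4)
    for _ in range(n_distinct):
        s1, s2 = rng_master.integers(0, 2**31 - 1, 2)
        panel = _syn.simulate_genotypes(
            n_samples,
            [(n_snps // 2, 0.6, (0.2, 0.5)), (n_snps // 2, 0.6, (0.2, 0.5))],
            seed=int(s1),
        )
        rng = np.random.default_rng(int(s2))
        xa = panel.dosages[:, n_snps // 4]
        xb = panel.dosages[:, 3 * n_snps // 4]
        ta = _gwas.run_gwas(
            _centered(beta * xa + rng.normal(0, 1, n_samples), panel.sample_ids), panel
        )
        tb = _gwas.run_gwas(
            _centered(beta * xb + rng.normal(0, 1, n_samples), panel.sample_ids), panel
        )
        res = _coloc.coloc_abf(ta, tb)
        if res.pp_h3 > 0.8:
            distinct_h3 += 1
    return {
        "h4_sensitivity": shared_pos / shared_n if shared_n else float("nan"),
        "n_shared_used": shared_n,
        "h3_rate_distinct": distinct_h3 / n_distinct,
        "max_posterior_sum_error": max_pp_err,
    }


def gwas_type1_error(
    n_snps: int = 10_000, n_samples: int = 1000, alpha: float = 0.05, seed: int = 3
) -> dict:
    """Fraction of null SNPs with p < alpha (nominal level check)."""
    panel = _syn.simulate_genotypes(
        n_samples, [(1, 0.5, (0.1, 0.9))] * n_snps, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(0, 1, n_samples)
    table = _gwas.run_gwas(_centered(y, panel.sample_ids), panel)
    frac = float((table["p"] < alpha).mean())
    return {"type1_rate": frac, "alpha": alpha, "n_snps": n_snps}


def h2_recovery(
    n_seeds: int = 20,
    n_samples: int = 1000,
    n_snps: int = 1000,
    n_causal: int = 200,
    h2_true: float = 0.5,
    seed: int = 4,
) -> dict:
    """Mean REML h2 estimate over seeds with the planted value."""
    rng_master = np.random.default_rng(seed)
    ests = []
    for _ in range(n_seeds):
        s1, s2 = rng_master.integers(0, 2**31 - 1, 2)
        panel = _syn.simulate_genotypes(
            n_samples, [(1, 0.5, (0.1, 0.9))] * n_snps, seed=int(s1)
        )
        rng = np.random.default_rng(int(s2))
        causal = rng.choice(n_snps, n_causal, replace=False)
        g = panel.dosages[:, causal] @ rng.normal(0, 1, n_causal)
        g = (g - g.mean()) / g.std()
        y = np.sqrt(h2_true) * g + np.sqrt(1 - h2_true) * rng.normal(0, 1, n_samples)
        grm = _h2.compute_grm(panel, quality_min=0.0)
        res = _h2.reml_h2(pd.Series(y, index=panel.sample_ids), grm)
        ests.append(res.h2)
    return {
        "h2_true": h2_true,
        "h2_mean": float(np.mean(ests)),
        "h2_sd": float(np.std(ests, ddof=1)),
        "n_seeds": n_seeds,
    }


def pqn_dilution_recovery(
    n_samples: int = 500, n_metabolites: int = 600, seed: int = 5
) -> dict:
    """Spearman correlation of PQN factors with planted urine dilution."""
    panel = _syn.simulate_genotypes(n_samples, [(2, 0.5, (0.2, 0.5))], seed=seed)
    cov = _syn.simulate_covariates(n_samples, seed=seed + 1)
    plan = _syn.EffectPlan(
        effects=[],
        dilution_sigma=0.5,
        missing_rate=0.05,
        complete_fraction=0.85,
        metabolites=[f"m{i}" for i in range(n_metabolites)],
    )
    _, urine, truth = _syn.simulate_metabolomes(panel, plan, cov, seed=seed + 2)
    _, factors = _qc.pq_normalize(urine)
    rho = stats.spearmanr(
        truth.attrs["dilution"].loc[factors.index], factors
    ).statistic
    return {"spearman_rho": float(rho), "n_samples": n_samples}


def ehh_sweep_contrast(
    n_carriers: int = 40, n_markers: int = 41, seed: int = 6
) -> dict:
    """Integrated-EHH ratio on a constructed sweep (one shared derived
    haplotype) vs scrambled ancestral haplotypes."""
    rng = np.random.default_rng(seed)
    derived = np.tile(rng.integers(0, 2, n_markers), (n_carriers, 1)).astype(np.int8)
    ancestral = rng.integers(0, 2, (n_carriers, n_markers)).astype(np.int8)
    hap = np.vstack([derived, ancestral])
    core = n_markers // 2
    hap[:n_carriers, core] = 1
    hap[n_carriers:, core] = 0
    pos = np.arange(n_markers) * 2000
    _, _, ratio = _ehh.compare_alleles(hap, pos, core)
    return {"area_ratio": float(ratio)}
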