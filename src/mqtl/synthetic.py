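"""Synthetic paired-cohort generator with a machine-readable truth table.

Generates LD-blocked biallelic genotype dosages under Hardy-Weinberg
equilibrium, covariates, and paired plasma/urine metabolite matrices with
additive SNP effects planted as shared, plasma-only or urine-only mQTLs,
optional SNP x sex interaction effects, per-sample multiplicative urine
dilution, and missing-at-random dropout.  Every random draw flows from a
single integer seed, so a cohort is reproducible bit-exact.

The linkage-disequilibrium model is deliberately minimal: each block has a
latent "core" haplotype allele drawn at the block frequency, and each SNP
in the block copies that allele with a per-site flip probability solved
numerically so that the expected pairwise haplotype correlation matches
the requested r^2 target.  This yields exchangeable within-block LD and
(approximate) independence across blocks; it makes no attempt at
coalescent realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq


@dataclass
class GenotypePanel:
    """Sample x SNP dosage matrix with per-SNP metadata.

    Attributes
    ----------
    sample_ids : list of str
    snps : DataFrame with columns snp, chrom, pos, ref, alt, alt_freq,
        imputation_quality (pos 1-based, strictly increasing per chrom).
    dosages : (n_samples, n_snps) float array of alt-allele dosage in [0, 2].
    haplotypes : optional (2 * n_samples, n_snps) int8 array, phased; row
        2i and 2i+1 are the two haplotypes of sample i.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        idx = self.snps.index[self.snps["snp"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(idx[0])

    def validate(self) -> None:
        if self.dosages.shape != (self.n_samples, self.n_snps):
            raise ValueError("dosage matrix shape does not match ids/snps")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages outside [0, 2]")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions not strictly increasing within chromosome")
        if self.haplotypes is not None:
            recon = self.haplotypes[0::2] + self.haplotypes[1::2]
            if not np.array_equal(recon, self.dosages):
                raise ValueError("dosages inconsistent with phased haplotypes")


@dataclass
class PlantedEffect:
    """One planted mQTL: an additive SNP effect on a log2-scale metabolite."""

    snp: str
    metabolite: str
    matrix: str  # "plasma" | "urine" | "both"
    beta: float  # per-alt-allele effect, log2 abundance units
    sex_beta: float = 0.0  # extra per-allele effect in the sex==1 stratum


@dataclass
class EffectPlan:
    """Planted effects plus per-metabolite heritability targets and nuisance.

    ``h2`` maps metabolite -> target fraction of (genetic + residual)
    variance explained by the planted SNPs; ``dilution_sigma`` is the s.d.
    of the log-normal per-sample urine dilution factor (median 1);
    ``missing_rate`` is the per-cell missing-at-random dropout fraction.
    """

    effects: list[PlantedEffect] = field(default_factory=list)
    h2: dict[str, float] = field(default_factory=dict)
    dilution_sigma: float = 0.5
    missing_rate: float = 0.05
    complete_fraction: float = 0.5  # metabolites kept fully observed (PQN reference pool)
    metabolites: list[str] | None = None  # full metabolite universe; default from effects

    def metabolite_ids(self) -> list[str]:
        if self.metabolites is not None:
            return list(self.metabolites)
        seen: dict[str, None] = {}
        for e in self.effects:
            seen.setdefault(e.metabolite, None)
        for m in self.h2:
            seen.setdefault(m, None)
        return list(seen)


def _flip_prob_for_r2(r2_target: float, p: float) -> float:
    """Per-site allele flip probability giving expected haplotype r^2.

    With a latent Bernoulli(p) core allele Z and SNP allele X equal to Z
    flipped independently with probability eps, the correlation between two
    SNPs of the same block is

        r = (1-2 eps)^2 v / ((1-2 eps)^2 v + eps (1-eps)),  v = p (1-p),

    so we solve r = sqrt(r2_target) for eps in [0, 0.5).
    """
    if not 0 <= r2_target <= 1:
        raise ValueError("LD target r2 must be in [0, 1]")
    r = float(np.sqrt(r2_target))
    if r >= 1.0:
        return 0.0
    v = p * (1 - p)

    def f(eps: float) -> float:
        a = (1 - 2 * eps) ** 2 * v
        return a / (a + eps * (1 - eps)) - r

    if r <= 0.0:
        return 0.5
    return float(brentq(f, 1e-12, 0.5 - 1e-12))


def simulate_genotypes(
    n_samples: int,
    block_spec: Sequence[tuple],
    seed: int,
    chrom: str | Sequence[str] = "1",
    spacing_bp: int = 5_000,
    start_bp: int = 1_000_000,
    quality_range: tuple[float, float] = (0.8, 1.0),
) -> GenotypePanel:
    """Simulate phased LD-blocked genotypes under HWE.

    Parameters
    ----------
    n_samples : number of diploid samples (>= 2).
    block_spec : iterable of ``(n_snps, r2_target, (freq_lo, freq_hi))``
        tuples; one LD block each.  Core allele frequency drawn uniformly
        from the given range.
    seed : RNG seed; identical seeds give bit-identical panels.
    chrom : chromosome label for all blocks, or one label per block.
    spacing_bp : distance between consecutive SNPs.
    quality_range : uniform range for the per-SNP imputation-quality tag.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if len(block_spec) == 0:
        raise ValueError("block_spec must contain at least one block")
    if isinstance(chrom, str):
        chroms = [chrom] * len(block_spec)
    else:
        chroms = list(chrom)
        if len(chroms) != len(block_spec):
            raise ValueError("one chromosome label per block required")

    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    hap_cols: list[np.ndarray] = []
    meta: list[dict] = []
    next_pos: dict[str, int] = {}
    snp_counter = 0
    for block_i, ((n_snps, r2_target, freq_range), chrom_label) in enumerate(
        zip(block_spec, chroms)
    ):
        if n_snps <= 0:
            raise ValueError("block n_snps must be positive")
        lo, hi = freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele frequencies must lie in (0, 1)")
        p = float(rng.uniform(lo, hi))
        eps = _flip_prob_for_r2(r2_target, p)
        core = (rng.random(n_hap) < p).astype(np.int8)
        for _ in range(n_snps):
            if eps == 0.0:
                hap = core.copy()
            else:
                flip = rng.random(n_hap) < eps
                hap = np.where(flip, 1 - core, core).astype(np.int8)
            pos = next_pos.get(chrom_label, start_bp)
            next_pos[chrom_label] = pos + spacing_bp
            hap_cols.append(hap)
            meta.append(
                {
                    "snp": f"rs{snp_counter + 1:06d}",
                    "chrom": chrom_label,
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "block": block_i,
                }
            )
            snp_counter += 1

    haplotypes = np.column_stack(hap_cols).astype(np.int8)
    dosages = (haplotypes[0::2] + haplotypes[1::2]).astype(float)
    snps = pd.DataFrame(meta)
    snps["alt_freq"] = dosages.mean(axis=0) / 2.0
    snps["imputation_quality"] = rng.uniform(
        quality_range[0], quality_range[1], size=len(snps)
    )
    panel = GenotypePanel(
        sample_ids=[f"S{i + 1:05d}" for i in range(n_samples)],
        snps=snps,
        dosages=dosages,
        haplotypes=haplotypes,
    )
    panel.validate()
    return panel


def simulate_covariates(n_samples: int, seed: int) -> pd.DataFrame:
    """Covariate table: age, sex, 3 genetic PCs, eGFR and serum albumin.

    Sex is 0/1; eGFR is on the natural scale (ln applied downstream,
    mirroring the adjustment set of the plasma GWAS).
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n_samples)],
            "age": rng.normal(60, 12, n_samples).round(1),
            "sex": rng.integers(0, 2, n_samples),
            "pc1": rng.normal(0, 1, n_samples),
            "pc2": rng.normal(0, 1, n_samples),
            "pc3": rng.normal(0, 1, n_samples),
            "egfr": np.exp(rng.normal(np.log(50), 0.3, n_samples)),
            "albumin": rng.normal(38, 4, n_samples),
        }
    ).set_index("sample_id")


# scale of per-metabolite covariate coefficients on the log2 scale;
# age/sex nonzero so residualization is exercised for every trait.  Each
# metabolite draws its own coefficient ~ N(0, scale^2): effects differ in
# sign and size across metabolites (as in real data), so a sample's
# covariate profile does not mimic a global dilution shift
_COVAR_SCALES = {"age": 0.01, "sex": 0.25, "pc1": 0.1}


def simulate_metabolomes(
    panel: GenotypePanel,
    plan: EffectPlan,
    covariates: pd.DataFrame,
    seed: int,
    covar_scales: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate paired plasma/urine abundance matrices plus truth table.

    Log2 abundance = intercept + sum(dosage * beta) + covariate effects +
    Gaussian noise whose variance is set so the planted SNPs explain the
    metabolite's target h2 of the genetic + residual variance.  Returned
    matrices are on the raw abundance scale (2**log2), samples in rows;
    urine rows are multiplied by a per-sample log-normal dilution factor
    (median 1) and missing-at-random dropout is applied to both matrices.

    Returns ``(plasma, urine, truth)`` where ``truth`` lists one row per
    planted (snp, metabolite, matrix) with the true effect, sex-interaction
    effect, h2 target, and the realized dilution factor table is attached
    as ``truth.attrs["dilution"]``.
    """
    covar_scales = _COVAR_SCALES if covar_scales is None else covar_scales
    for e in plan.effects:
        panel.snp_index(e.snp)  # raises if absent
        if e.matrix not in ("plasma", "urine", "both"):
            raise ValueError(f"unknown matrix {e.matrix!r}")
    for m, h2 in plan.h2.items():
        if not 0 <= h2 < 1:
            raise ValueError(f"h2 target for {m!r} outside [0, 1)")
    if not (0 <= plan.missing_rate < 1):
        raise ValueError("missing rate outside [0, 1)")

    rng = np.random.default_rng(seed)
    n = panel.n_samples
    covariates = covariates.loc[panel.sample_ids]
    cov_cols = {
        name: covariates[name].to_numpy(float) - covariates[name].mean()
        for name in covar_scales
        if name in covariates.columns
    }
    sex = covariates["sex"].to_numpy(float) if "sex" in covariates.columns else np.zeros(n)

    mets = plan.metabolite_ids()
    if not mets:
        raise ValueError("effect plan defines no metabolites")
    by_met: dict[str, list[PlantedEffect]] = {m: [] for m in mets}
    for e in plan.effects:
        by_met[e.metabolite].append(e)

    log2 = {"plasma": {}, "urine": {}}
    truth_rows = []
    for met in mets:
        h2_target = plan.h2.get(met, None)
        cov_term = np.zeros(n)
        for name, col in cov_cols.items():
            cov_term = cov_term + rng.normal(0.0, covar_scales[name]) * col
        for matrix in ("plasma", "urine"):
            genetic = np.zeros(n)
            for e in by_met[met]:
                if e.matrix in (matrix, "both"):
                    x = panel.dosages[:, panel.snp_index(e.snp)]
                    genetic = genetic + e.beta * x + e.sex_beta * x * sex
            var_g = float(np.var(genetic))
            if h2_target is None:
                var_e = 1.0
            elif h2_target == 0.0:
                var_e = 1.0
            elif var_g == 0.0:
                # no planted effect reaches this matrix (e.g. plasma-only
                # mQTL viewed from urine): unit residual variance
                var_e = 1.0
            else:
                var_e = var_g * (1 - h2_target) / h2_target
            noise = rng.normal(0.0, np.sqrt(var_e), n)
            log2[matrix][met] = 10.0 + genetic + cov_term + noise
        for e in by_met[met]:
            truth_rows.append(
                {
                    "snp": e.snp,
                    "metabolite": met,
                    "matrix": e.matrix,
                    "beta": e.beta,
                    "sex_beta": e.sex_beta,
                    "h2_target": np.nan if h2_target is None else h2_target,
                }
            )

    plasma = pd.DataFrame(log2["plasma"], index=panel.sample_ids)
    urine = pd.DataFrame(log2["urine"], index=panel.sample_ids)
    plasma = np.exp2(plasma)
    urine = np.exp2(urine)

    dilution = np.exp(rng.normal(0.0, plan.dilution_sigma, n))
    urine = urine.mul(dilution, axis=0)

    if plan.missing_rate > 0:
        # a fraction of metabolites stays fully observed, mirroring the
        # near-complete "endogenous" metabolites that anchor PQN in real data
        n_complete = int(round(plan.complete_fraction * len(mets)))
        complete = set(rng.choice(mets, size=n_complete, replace=False)) if n_complete else set()
        droppable = np.array([m not in complete for m in mets])
        for mat in (plasma, urine):
            mask = rng.random(mat.shape) < plan.missing_rate
            mask[:, ~droppable] = False
            mat.mask(pd.DataFrame(mask, index=mat.index, columns=mat.columns), inplace=True)

    truth = pd.DataFrame(
        truth_rows,
        columns=["snp", "metabolite", "matrix", "beta", "sex_beta", "h2_target"],
    )
    truth.attrs["dilution"] = pd.Series(dilution, index=panel.sample_ids, name="dilution")
    return plasma, urine, truth
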