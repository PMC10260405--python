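"""Pairwise Bayesian colocalization (PP H0-H4).

For two association tables over a shared region, per-SNP Wakefield log
Bayes factors are computed for each trait and combined over the causal
configurations of the five-hypothesis model (H0: no association; H1/H2:
association with one trait only; H3: two distinct causal variants; H4:
one shared causal variant), weighted by per-SNP priors p1, p2, p12 and
normalized in log space.  A positive colocalization is PP(H4) > 0.8.

Window pairing follows the mQTL study design: two loci are tested when
their +-500 kb index windows overlap, over the union of the windows, and
positive pairs are classified as intraplasma / intraurine / intermatrix
(same or different metabolite).  Colocalization against an external trait
is triggered only when the external table shows a variant with MAF > 0.01
and p below 0.05 / n_index within +-100 kb of the index SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import wakefield_abf

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
# per-trait effect prior inside coloc, on (approximately unit-variance)
# residual-scale effects; intentionally narrower than the fine-mapping prior
DEFAULT_COLOC_PRIOR_SD = 0.15


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one trait pair and region."""

    trait_a: str
    trait_b: str
    chrom: str
    start: int
    end: int
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    group: str = ""

    @property
    def positive(self) -> bool:
        return self.pp_h4 > 0.8

    def posteriors(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def _align(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    """Intersect two summary tables on (chrom, pos, alleles); flip B if needed.

    Alleles are matched unordered; when B's effect allele is A's other
    allele, B's beta is negated.  Unmatchable rows are dropped.
    """
    a = stats_a.copy()
    b = stats_b.copy()
    a["_key"] = [
        (str(c), int(p), tuple(sorted((r, t))))
        for c, p, r, t in zip(a["chrom"], a["pos"], a["ref"], a["alt"])
    ]
    b["_key"] = [
        (str(c), int(p), tuple(sorted((r, t))))
        for c, p, r, t in zip(b["chrom"], b["pos"], b["ref"], b["alt"])
    ]
    m = a.merge(b, on="_key", suffixes=("_a", "_b"))
    if m.empty:
        raise ValueError("no shared SNPs between the two tables")
    flip = (m["alt_a"] != m["alt_b"])
    m.loc[flip, "beta_b"] = -m.loc[flip, "beta_b"]
    return m


def _estimate_sd_y(m: pd.DataFrame, suffix: str) -> float:
    """Trait scale from summary statistics, as coloc estimates sdY.

    Under the null, se_i^2 ~ var(y) / (n 2 p_i (1 - p_i)), so the median of
    se^2 * n * 2p(1-p) across region SNPs is a robust var(y) estimate.
    Putting the effect prior on this scale makes posteriors invariant to a
    uniform rescaling of a trait's effects and standard errors.  Falls back
    to 1.0 (unit-variance trait) when eaf or n are unavailable.
    """
    eaf = m.get(f"eaf{suffix}")
    n = m.get(f"n{suffix}")
    if eaf is None or n is None:
        return 1.0
    eaf = eaf.to_numpy(float)
    var_x = 2 * eaf * (1 - eaf)
    ok = np.isfinite(var_x) & (var_x > 0)
    if not ok.any():
        return 1.0
    var_y = np.median(m[f"se{suffix}"].to_numpy(float)[ok] ** 2
                      * n.to_numpy(float)[ok] * var_x[ok])
    return float(np.sqrt(var_y)) if var_y > 0 else 1.0


def coloc_abf(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd: float = DEFAULT_COLOC_PRIOR_SD,
    trait_a: str = "A",
    trait_b: str = "B",
    group: str = "",
) -> ColocResult:
    """Giambartolomei-style enumeration colocalization on two tables.

    Both tables need columns snp, chrom, pos, ref, alt, beta, se.  The
    hypothesis sums are evaluated entirely in log space.
    """
    m = _align(stats_a, stats_b)
    ok = (m["se_a"] > 0) & (m["se_b"] > 0) & m["beta_a"].notna() & m["beta_b"].notna()
    m = m.loc[ok]
    if m.empty:
        raise ValueError("no usable shared SNPs (non-positive or missing SE)")
    la = wakefield_abf(
        m["beta_a"].to_numpy(), m["se_a"].to_numpy(),
        prior_sd * _estimate_sd_y(m, "_a"), log=True,
    )
    lb = wakefield_abf(
        m["beta_b"].to_numpy(), m["se_b"].to_numpy(),
        prior_sd * _estimate_sd_y(m, "_b"), log=True,
    )

    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    # sum over i != j of ABF_a[i] * ABF_b[j] = sum_a * sum_b - sum_ab
    lh3_core, sign = logsumexp(
        [lsum_a + lsum_b, lsum_ab], b=[1.0, -1.0], return_sign=True
    )
    if sign <= 0:  # single-SNP region: no two-distinct-variant configuration
        lh3_core = -np.inf

    lh = np.array(
        [
            0.0,
            np.log(p1) + lsum_a,
            np.log(p2) + lsum_b,
            np.log(p1) + np.log(p2) + lh3_core,
            np.log(p12) + lsum_ab,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    chrom = str(m["chrom_a"].iloc[0])
    return ColocResult(
        trait_a=trait_a,
        trait_b=trait_b,
        chrom=chrom,
        start=int(m["pos_a"].min()),
        end=int(m["pos_a"].max()),
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
        n_snps=len(m),
        group=group,
    )


def pair_mqtls(mqtls: list, window_bp: int = 500_000) -> list[tuple]:
    """All unordered mQTL pairs whose +-window index windows overlap.

    Returns ``(mqtl_a, mqtl_b, (chrom, start, end))`` with the region the
    union of the two windows.  Pairs never span chromosomes.
    """
    out = []
    for i in range(len(mqtls)):
        for j in range(i + 1, len(mqtls)):
            a, b = mqtls[i], mqtls[j]
            if a.chrom != b.chrom:
                continue
            a_lo, a_hi = max(1, a.pos - window_bp), a.pos + window_bp
            b_lo, b_hi = max(1, b.pos - window_bp), b.pos + window_bp
            if a_lo <= b_hi and b_lo <= a_hi:
                out.append((a, b, (a.chrom, min(a_lo, b_lo), max(a_hi, b_hi))))
    return out


def classify(mqtl_a, mqtl_b) -> str:
    """Four-group label for a positive mQTL-mQTL colocalization."""
    if mqtl_a.matrix == mqtl_b.matrix:
        return "intraplasma" if mqtl_a.matrix == "plasma" else "intraurine"
    if mqtl_a.trait == mqtl_b.trait:
        return "intermatrix_same_metabolite"
    return "intermatrix_different_metabolite"


def external_coloc_trigger(
    mqtl,
    mqtl_stats: pd.DataFrame,
    external_stats: pd.DataFrame,
    n_index: int,
    trigger_window_bp: int = 100_000,
    coloc_window_bp: int = 500_000,
    maf_min: float = 0.01,
    alpha: float = 0.05,
    **coloc_kwargs,
) -> ColocResult | None:
    """Trigger-gated colocalization of an mQTL with an external trait.

    Runs coloc over index +-500 kb iff the external table contains a
    variant with MAF > ``maf_min`` and p < alpha / n_index within
    +-100 kb of the index SNP.  Variants with missing MAF are ineligible
    for the trigger.  Returns None when not triggered.
    """
    threshold = alpha / n_index
    near = external_stats.loc[
        (external_stats["chrom"].astype(str) == str(mqtl.chrom))
        & (external_stats["pos"] >= mqtl.pos - trigger_window_bp)
        & (external_stats["pos"] <= mqtl.pos + trigger_window_bp)
    ]
    if "eaf" in near.columns:
        maf = np.minimum(near["eaf"], 1 - near["eaf"])
        near = near.loc[maf.notna() & (maf > maf_min)]
    else:
        return None
    if near.empty or not (near["p"] < threshold).any():
        return None
    lo, hi = max(1, mqtl.pos - coloc_window_bp), mqtl.pos + coloc_window_bp
    in_win = lambda t: t.loc[  # noqa: E731
        (t["chrom"].astype(str) == str(mqtl.chrom)) & (t["pos"] >= lo) & (t["pos"] <= hi)
    ]
    return coloc_abf(
        in_win(mqtl_stats),
        in_win(external_stats),
        trait_a=f"{mqtl.trait}[{mqtl.matrix}]",
        trait_b="external",
        group="mqtl_vs_external",
        **coloc_kwargs,
    )
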