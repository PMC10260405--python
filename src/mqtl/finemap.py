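"""Conditional signal selection and Wakefield ABF fine mapping.

Independent signals inside an mQTL are found by forward stepwise
selection on individual-level data: at each step every candidate SNP
(excluding those with LD r^2 above the collinearity cutoff to an already
selected SNP) is added to a joint regression of the trait residuals on
the selected set, and the candidate with the smallest conditional p is
kept if that p clears the genome-wide threshold.  Conditional statistics
for each selected SNP come from the joint fit containing all other
selected SNPs.  Per-signal approximate Bayes factors use Wakefield's
closed form with a normal effect prior (s.d. 1.33 by default), posterior
probabilities of association are ABFs normalized over the region
(uniform prior across region SNPs), and the credible set is the minimal
PPA-ranked prefix whose cumulative PPA strictly exceeds 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRIOR_SD = 1.33


@dataclass
class IndependentSignal:
    """One conditionally independent association signal within a locus."""

    lead_snp: str
    beta_conditional: float
    se_conditional: float
    p_conditional: float
    beta_marginal: float
    se_marginal: float
    p_marginal: float


@dataclass
class CredibleSet:
    """PPA-ranked SNPs with the >99% credible-set cut for one signal."""

    lead_snp: str
    table: pd.DataFrame  # columns: snp, abf, ppa, cum_ppa, in_set (PPA-descending)
    size: int
    cumulative_ppa: float

    @property
    def snps(self) -> list[str]:
        return list(self.table.loc[self.table["in_set"], "snp"])


def _joint_fit(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS with intercept; returns (beta, se, p) for the SNP columns."""
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    xtx = design.T @ design
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError("collinear selected SNP set in joint regression") from err
    beta = xtx_inv @ design.T @ y
    res = y - design @ beta
    dof = n - design.shape[1]
    sigma2 = res @ res / dof
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta[1:], se[1:], p[1:]


def ld_r2(panel, snp_a: str, snp_b: str) -> float:
    """Squared dosage correlation between two panel SNPs."""
    a = panel.dosages[:, panel.snp_index(snp_a)]
    b = panel.dosages[:, panel.snp_index(snp_b)]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def stepwise_select(
    region_snps: list[str],
    residuals: pd.Series,
    panel,
    threshold: float,
    collinearity: float = 0.1,
) -> list[IndependentSignal]:
    """Forward stepwise conditional selection of independent signals."""
    if not region_snps:
        raise ValueError("empty fine-mapping region")
    sample_idx = [panel.sample_ids.index(s) for s in residuals.index]
    cols = {s: panel.dosages[sample_idx, panel.snp_index(s)] for s in region_snps}
    y = residuals.to_numpy(float)

    marginal: dict[str, tuple[float, float, float]] = {}
    for s, x in cols.items():
        if x.std() == 0:
            continue
        b, se, p = _joint_fit(y, x[:, None])
        marginal[s] = (b[0], se[0], p[0])

    selected: list[str] = []
    while True:
        candidates = []
        for s in region_snps:
            if s in selected or s not in marginal:
                continue
            if any(ld_r2(panel, s, t) > collinearity for t in selected):
                continue
            candidates.append(s)
        if not candidates:
            break
        best: tuple[float, str, str] | None = None
        for s in candidates:
            x = np.column_stack([cols[t] for t in selected] + [cols[s]])
            _, _, p = _joint_fit(y, x)
            key = (p[-1], panel.snps.iloc[panel.snp_index(s)]["pos"], s)
            if best is None or key < best:
                best = key
        p_cond, _, snp = best
        if p_cond < threshold:
            selected.append(snp)
        else:
            break

    signals = []
    for s in selected:
        if len(selected) == 1:
            b, se, p = marginal[s]
        else:
            others = [t for t in selected if t != s]
            x = np.column_stack([cols[t] for t in others] + [cols[s]])
            bs, ses, ps = _joint_fit(y, x)
            b, se, p = bs[-1], ses[-1], ps[-1]
        bm, sem, pm = marginal[s]
        signals.append(
            IndependentSignal(
                lead_snp=s,
                beta_conditional=float(b),
                se_conditional=float(se),
                p_conditional=float(p),
                beta_marginal=float(bm),
                se_marginal=float(sem),
                p_marginal=float(pm),
            )
        )
    return signals


def wakefield_abf(
    beta: float | np.ndarray,
    se: float | np.ndarray,
    prior_sd: float = DEFAULT_PRIOR_SD,
    log: bool = False,
) -> float | np.ndarray:
    """Wakefield's approximate Bayes factor in favor of association.

    With V = se^2, W = prior_sd^2 and z = beta / se:

        ABF = sqrt(V / (V + W)) * exp(z^2 / 2 * W / (V + W))

    Larger values favor association (H1 over H0).  Evaluated in log space
    for numerical stability; ``log=True`` returns log(ABF).
    """
    se = np.asarray(se, float)
    beta = np.asarray(beta, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    labf = 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)
    out = labf if log else np.exp(labf)
    return out if out.shape else float(out)


def credible_set(
    snp_ids: list[str],
    log_abfs: np.ndarray,
    lead_snp: str = "",
    level: float = 0.99,
) -> CredibleSet:
    """Normalize ABFs to PPAs and take the minimal >level prefix.

    PPA_i = ABF_i / sum_j ABF_j under a uniform prior over region SNPs;
    the set is the smallest PPA-descending prefix with cumulative PPA
    strictly greater than ``level``.
    """
    labf = np.asarray(log_abfs, float)
    if labf.size == 0:
        raise ValueError("empty region")
    if not np.all(np.isfinite(labf)):
        raise ValueError("non-finite log ABF")
    ppa = np.exp(labf - labf.max())
    ppa = ppa / ppa.sum()
    order = np.argsort(-ppa, kind="mergesort")
    tbl = pd.DataFrame(
        {
            "snp": np.asarray(snp_ids)[order],
            "log_abf": labf[order],
            "ppa": ppa[order],
        }
    )
    tbl["cum_ppa"] = tbl["ppa"].cumsum()
    # minimal prefix with cumulative PPA strictly > level; 1e-9 round-off
    # guard so a cumulative of level + O(eps) does not count as exceeding
    cum = tbl["cum_ppa"].to_numpy()
    exceeded = cum > level + 1e-9
    k = int(np.argmax(exceeded)) + 1 if exceeded.any() else len(tbl)
    tbl["in_set"] = np.arange(len(tbl)) < k
    return CredibleSet(
        lead_snp=lead_snp or str(tbl["snp"].iloc[0]),
        table=tbl,
        size=k,
        cumulative_ppa=float(tbl["cum_ppa"].iloc[k - 1]),
    )


def align_regions(mqtls: list, panel, r2_threshold: float = 0.8) -> list[list]:
    """Single-linkage grouping of mQTLs whose index SNPs are in LD.

    Returns a list of groups (lists of the input mQTL objects); each
    group is fine-mapped over the union of its members' intervals.
    """
    n = len(mqtls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        panel.snp_index(mqtls[i].index_snp)  # raises if absent
        for j in range(i + 1, n):
            if mqtls[i].chrom != mqtls[j].chrom:
                continue
            if ld_r2(panel, mqtls[i].index_snp, mqtls[j].index_snp) > r2_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(mqtls[i])
    return list(groups.values())


@dataclass
class FinemapResult:
    """Signals plus one credible set per signal for one region."""

    signals: list[IndependentSignal] = field(default_factory=list)
    credible_sets: list[CredibleSet] = field(default_factory=list)


def finemap_region(
    region_snps: list[str],
    residuals: pd.Series,
    panel,
    threshold: float,
    collinearity: float = 0.1,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> FinemapResult:
    """Stepwise selection then per-signal ABF credible sets.

    With a single signal, ABFs come from marginal effect estimates; with
    several, each signal's ABFs use effects conditional on the other
    selected SNPs (joint regression on individual-level data).
    """
    signals = stepwise_select(region_snps, residuals, panel, threshold, collinearity)
    if not signals:
        return FinemapResult()
    sample_idx = [panel.sample_ids.index(s) for s in residuals.index]
    y = residuals.to_numpy(float)
    sets = []
    selected = [s.lead_snp for s in signals]
    for sig in signals:
        others = [t for t in selected if t != sig.lead_snp]
        labfs = []
        usable = []
        for s in region_snps:
            x_snp = panel.dosages[sample_idx, panel.snp_index(s)]
            if x_snp.std() == 0:
                continue
            if others:
                x = np.column_stack(
                    [panel.dosages[sample_idx, panel.snp_index(t)] for t in others]
                    + [x_snp]
                )
                try:
                    bs, ses, _ = _joint_fit(y, x)
                except ValueError:
                    continue  # SNP collinear with conditioning set
                b, se = bs[-1], ses[-1]
            else:
                bs, ses, _ = _joint_fit(y, x_snp[:, None])
                b, se = bs[0], ses[0]
            if not np.isfinite(se) or se <= 0:
                continue
            labfs.append(wakefield_abf(b, se, prior_sd, log=True))
            usable.append(s)
        sets.append(credible_set(usable, np.asarray(labfs), lead_snp=sig.lead_snp))
    return FinemapResult(signals=signals, credible_sets=sets)
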