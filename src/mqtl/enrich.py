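"""Gene-set over-representation testing.

Two routes: a matched permutation test that redraws gene lists of the
observed size within strata defined by deciles of per-gene independent
SNP count and gene length, and Fisher's exact test against a fixed gene
universe.  Multiple testing is controlled with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class MatchingStrata:
    """Gene -> (snp-count decile, gene-length decile) stratum assignment."""

    strata: pd.Series  # index: gene, values: stratum id tuples

    @classmethod
    def from_annotations(
        cls, n_snps: pd.Series, gene_length: pd.Series, n_bins: int = 10
    ) -> "MatchingStrata":
        """Build deciles of both annotations over the universe genes."""
        common = n_snps.index.intersection(gene_length.index)
        d1 = pd.qcut(n_snps.loc[common].rank(method="first"), n_bins, labels=False) + 1
        d2 = (
            pd.qcut(gene_length.loc[common].rank(method="first"), n_bins, labels=False)
            + 1
        )
        return cls(strata=pd.Series(list(zip(d1, d2)), index=common))


def matched_permutation_test(
    source: list[str],
    annotation_set: set[str],
    universe: list[str],
    strata: MatchingStrata,
    n_draws: int = 100_000,
    seed: int = 0,
) -> dict:
    """Stratum-matched random redraws of the source list.

    Each draw samples, within every stratum, exactly as many universe
    genes (without replacement) as the source list contains there; the
    empirical p-value is (1 + #draws with overlap >= observed) /
    (1 + n_draws) and fold enrichment is observed / mean null overlap.
    """
    universe = list(dict.fromkeys(universe))
    src = set(source)
    if not src <= set(universe):
        raise ValueError("source genes must be a subset of the universe")
    anno = annotation_set & set(universe)
    observed = len(src & anno)

    strat = strata.strata
    rng = np.random.default_rng(seed)
    null = np.zeros(n_draws, dtype=np.int64)
    for sid in sorted(set(strat.loc[list(src)])):
        stratum_genes = [g for g in universe if strat.get(g) == sid]
        k = sum(1 for g in src if strat[g] == sid)
        if k == 0:
            continue
        if len(stratum_genes) < k:
            raise ValueError(f"stratum {sid} has fewer universe genes than source genes")
        member = np.array([g in anno for g in stratum_genes])
        if len(stratum_genes) == k:
            null += int(member.sum())
            continue
        # random k-subsets via top-k of random keys, fully vectorized
        keys = rng.random((n_draws, len(stratum_genes)))
        picked = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null += member[picked].sum(axis=1)

    p = (1 + np.sum(null >= observed)) / (1 + n_draws)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else np.inf
    return {
        "observed": observed,
        "expected": mean_null,
        "fold": fold,
        "p": float(p),
        "n_draws": n_draws,
        "null": null,
    }


def fisher_overrep(
    n_source: int, n_term: int, overlap: int, universe_size: int
) -> tuple[float, float]:
    """One-sided (upper tail) Fisher's exact test on the 2x2 table.

    Returns (sample odds ratio, p).  Zero margins give p = 1.
    """
    if overlap > min(n_source, n_term):
        raise ValueError("overlap exceeds a margin")
    if n_source == 0 or n_term == 0 or n_term == universe_size:
        return float("nan"), 1.0
    a = overlap
    b = n_source - overlap
    c = n_term - overlap
    d = universe_size - n_source - n_term + overlap
    if d < 0:
        raise ValueError("inconsistent 2x2 table")
    p = float(stats.hypergeom.sf(a - 1, universe_size, n_term, n_source))
    oddsratio = (a * d) / (b * c) if b * c > 0 else float("inf")
    return oddsratio, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def independent_snp_counts(panel, r2_prune: float = 0.2, gene_windows=None) -> pd.Series:
    """Greedy LD-pruned SNP counts per gene window from a genotype panel.

    ``gene_windows``: mapping gene -> (chrom, start, end).  For each gene
    the SNPs inside the window are greedily pruned left to right at
    r^2 < ``r2_prune``; the count of retained SNPs is returned.
    """
    if gene_windows is None:
        return pd.Series(dtype=int)
    counts = {}
    snps = panel.snps
    for gene, (chrom, start, end) in gene_windows.items():
        idx = snps.index[
            (snps["chrom"].astype(str) == str(chrom))
            & (snps["pos"] >= start)
            & (snps["pos"] <= end)
        ].to_numpy()
        kept: list[int] = []
        for i in idx:
            x = panel.dosages[:, i]
            if x.std() == 0:
                continue
            ok = True
            for j in kept:
                y = panel.dosages[:, j]
                if np.corrcoef(x, y)[0, 1] ** 2 >= r2_prune:
                    ok = False
                    break
            if ok:
                kept.append(i)
        counts[gene] = len(kept)
    return pd.Series(counts, dtype=int)
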