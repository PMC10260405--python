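"""Iterative mQTL locus definition.

Significant SNPs for one trait are grouped by repeatedly taking the
lowest-p unassigned SNP as an index and claiming all significant SNPs
within a 1-Mb window centered on it; per-trait overlapping intervals are
merged, the extended MHC region (chr6, 25.5-34 Mb) is collapsed into a
single region, rare-variant (MAF < 3%) associations must survive an
inverse-normal re-test, and the index SNP's variance explained is the
squared Pearson correlation with the raw log2 trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwas as _gwas

MHC_CHROM = "6"
MHC_START = 25_500_000
MHC_END = 34_000_000


@dataclass
class Mqtl:
    """One called metabolite QTL (locus) for one trait/matrix."""

    trait: str
    matrix: str
    index_snp: str
    chrom: str
    pos: int
    p: float
    beta: float
    se: float
    eaf: float
    start: int  # 1-based inclusive
    end: int
    members: list[str] = field(default_factory=list)
    variance_explained: float | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "trait", "matrix", "index_snp", "chrom", "pos", "p", "beta", "se",
            "eaf", "start", "end", "variance_explained")}
        d["n_members"] = len(self.members)
        d["members"] = ",".join(self.members)
        return d


def _sort_key(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic peak order: smaller p, then smaller position, then id
    return df.sort_values(["p", "pos", "snp"], kind="mergesort")


def call_mqtls(
    table: pd.DataFrame,
    threshold: float,
    trait: str = "",
    matrix: str = "",
    window_bp: int = 1_000_000,
    mhc: tuple[str, int, int] = (MHC_CHROM, MHC_START, MHC_END),
) -> list[Mqtl]:
    """Iterative peak picking + per-trait interval merging.

    ``table`` is a per-SNP association table (columns snp, chrom, pos,
    beta, se, p, eaf).  Returns merged loci whose index SNP is the
    lowest-p member of each merged union (ties broken by position then
    SNP id).  All significant SNPs inside the extended MHC form one
    region regardless of spacing.
    """
    mask = table["p"] < threshold
    if "undefined" in table.columns:
        mask &= ~table["undefined"].astype(bool)
    sig = table.loc[mask].copy()
    if sig.empty:
        return []
    half = window_bp // 2
    mhc_chrom, mhc_start, mhc_end = mhc

    intervals: list[dict] = []
    in_mhc = (
        (sig["chrom"].astype(str) == str(mhc_chrom))
        & (sig["pos"] >= mhc_start)
        & (sig["pos"] <= mhc_end)
    )
    mhc_snps = sig.loc[in_mhc]
    sig = sig.loc[~in_mhc]

    unassigned = _sort_key(sig)
    while not unassigned.empty:
        top = unassigned.iloc[0]
        lo = max(1, int(top["pos"]) - half)
        hi = int(top["pos"]) + half
        claim = (
            (unassigned["chrom"] == top["chrom"])
            & (unassigned["pos"] >= lo)
            & (unassigned["pos"] <= hi)
        )
        members = unassigned.loc[claim]
        intervals.append(
            {"chrom": top["chrom"], "start": lo, "end": hi, "members": members}
        )
        unassigned = unassigned.loc[~claim]

    if not mhc_snps.empty:
        intervals.append(
            {
                "chrom": str(mhc_chrom),
                "start": mhc_start,
                "end": mhc_end,
                "members": _sort_key(mhc_snps),
            }
        )

    # merge overlapping intervals per chromosome (shared bp = overlap)
    merged: list[dict] = []
    for chrom in sorted({iv["chrom"] for iv in intervals}):
        ivs = sorted(
            (iv for iv in intervals if iv["chrom"] == chrom), key=lambda d: d["start"]
        )
        cur = ivs[0]
        for nxt in ivs[1:]:
            if nxt["start"] <= cur["end"]:
                cur = {
                    "chrom": chrom,
                    "start": cur["start"],
                    "end": max(cur["end"], nxt["end"]),
                    "members": pd.concat([cur["members"], nxt["members"]]),
                }
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)

    out = []
    for iv in merged:
        members = _sort_key(iv["members"])
        idx = members.iloc[0]
        out.append(
            Mqtl(
                trait=trait,
                matrix=matrix,
                index_snp=str(idx["snp"]),
                chrom=str(idx["chrom"]),
                pos=int(idx["pos"]),
                p=float(idx["p"]),
                beta=float(idx["beta"]),
                se=float(idx["se"]),
                eaf=float(idx["eaf"]),
                start=int(iv["start"]),
                end=int(iv["end"]),
                members=[str(s) for s in members["snp"]],
            )
        )
    out.sort(key=lambda q: (q.chrom, q.start))
    return out


def rare_variant_check(
    mqtl: Mqtl,
    trait: pd.Series,
    covariates: pd.DataFrame,
    panel,
    threshold: float,
    matrix_label: str,
    maf_cutoff: float = 0.03,
) -> bool:
    """MAF < 3% gate: keep only if the index SNP survives an INT re-test.

    For common index SNPs the locus is kept unconditionally.  For rare
    ones the raw log2 trait is inverse-normal transformed, residualized
    and re-tested at the index SNP; the locus is kept iff the re-test p
    is strictly below the genome-wide threshold.
    """
    maf = min(mqtl.eaf, 1 - mqtl.eaf)
    if maf >= maf_cutoff:
        return True
    clean = trait.dropna()
    t_int = pd.Series(
        _gwas.inverse_normal_transform(clean), index=clean.index, name=trait.name
    )
    resid = _gwas.residualize(t_int, covariates, matrix_label)
    snp_col = panel.snp_index(mqtl.index_snp)
    table = _gwas.run_gwas(resid, panel, snp_subset=np.array([snp_col]))
    return bool(table["p"].iloc[0] < threshold)


def variance_explained(dosage: np.ndarray, trait: np.ndarray) -> float:
    """Squared Pearson correlation of dosage with the raw log2 trait.

    Computed on complete-case pairs, independent of covariates.  Returns
    NaN for zero-variance input.
    """
    d = np.asarray(dosage, float)
    t = np.asarray(trait, float)
    mask = ~(np.isnan(d) | np.isnan(t))
    d, t = d[mask], t[mask]
    if d.size < 2 or d.std() == 0 or t.std() == 0:
        return float("nan")
    r = np.corrcoef(d, t)[0, 1]
    return float(r * r)
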