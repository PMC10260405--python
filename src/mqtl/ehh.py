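"""Extended haplotype homozygosity (EHH) decay curves.

EHH at a flanking marker x, for the haplotypes carrying a chosen core
allele, is the probability that two randomly drawn carrier haplotypes are
identical at every marker from the core out to x inclusive:

    EHH(x) = (# identical carrier pairs through x) / C(n, 2).

It equals 1 at the core and can only decrease with distance (identity by
state, once lost, is never regained).  Slow decay of the derived-allele
curve relative to the ancestral one is a signature of recent positive
selection.  Computation uses partition refinement: carrier haplotypes
start in one group and groups split at each successive marker, so
EHH(x) = sum_g C(|g|, 2) / C(n, 2) over the current groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EhhCurve:
    """EHH values at flanking marker positions for one core allele."""

    core_snp: int  # column index of the core SNP
    allele: int  # 0 (ancestral) or 1 (derived) by convention of the caller
    positions: np.ndarray  # bp, ascending, includes the core position
    ehh: np.ndarray  # same length; 1.0 at the core
    n_carriers: int

    def integrated(self) -> float:
        """Trapezoid integral of EHH over bp (area under the curve)."""
        return float(np.trapezoid(self.ehh, self.positions))


def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def _ehh_one_side(hap: np.ndarray, order: list[int]) -> list[float]:
    """EHH at successive markers via partition refinement.

    ``hap``: carrier haplotypes (rows) over all markers; ``order``: marker
    column indices walking away from the core.  Rows containing a missing
    call (negative value) at a marker are dropped from that side onward.
    """
    n0 = hap.shape[0]
    denom = _pairs(n0)
    groups = [np.arange(n0)]
    out = []
    for col in order:
        new_groups = []
        for g in groups:
            alleles = hap[g, col]
            keep = g[alleles >= 0]  # drop-per-side on missing calls
            alleles = hap[keep, col]
            for a in np.unique(alleles):
                sub = keep[alleles == a]
                if len(sub) > 0:
                    new_groups.append(sub)
        groups = new_groups
        out.append(sum(_pairs(len(g)) for g in groups) / denom)
    return out


def ehh_curve(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    core_allele: int,
    max_span_bp: int | None = None,
) -> EhhCurve:
    """EHH decay curve around a core SNP for one core allele.

    ``haplotypes`` is a phased (2n, m) binary matrix (negative = missing
    call); ``positions`` the m marker positions in bp.  EHH is computed
    separately leftward and rightward from the core and stitched into one
    curve with EHH = 1 at the core itself.
    """
    hap = np.asarray(haplotypes)
    pos = np.asarray(positions)
    carriers = hap[hap[:, core_idx] == core_allele]
    n = carriers.shape[0]
    if n < 2:
        raise ValueError("need >= 2 carrier haplotypes of the core allele")

    core_pos = pos[core_idx]
    if max_span_bp is None:
        left = list(range(core_idx - 1, -1, -1))
        right = list(range(core_idx + 1, len(pos)))
    else:
        left = [i for i in range(core_idx - 1, -1, -1) if core_pos - pos[i] <= max_span_bp]
        right = [i for i in range(core_idx + 1, len(pos)) if pos[i] - core_pos <= max_span_bp]

    ehh_left = _ehh_one_side(carriers, left)
    ehh_right = _ehh_one_side(carriers, right)

    idx = left[::-1] + [core_idx] + right
    vals = ehh_left[::-1] + [1.0] + ehh_right
    return EhhCurve(
        core_snp=core_idx,
        allele=core_allele,
        positions=pos[idx].astype(float),
        ehh=np.asarray(vals),
        n_carriers=n,
    )


def ehh_brute_force(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    core_allele: int,
    max_span_bp: int | None = None,
) -> EhhCurve:
    """Direct pair-enumeration EHH; reference oracle for the fast path."""
    hap = np.asarray(haplotypes)
    pos = np.asarray(positions)
    carriers = hap[hap[:, core_idx] == core_allele]
    n = carriers.shape[0]
    if n < 2:
        raise ValueError("need >= 2 carrier haplotypes of the core allele")
    core_pos = pos[core_idx]

    def side(order):
        vals = []
        rows = carriers.copy()
        for step, col in enumerate(order):
            rows = rows[rows[:, col] >= 0]
            span = order[: step + 1]
            ident = 0
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    if np.array_equal(rows[i, span], rows[j, span]):
                        ident += 1
            vals.append(ident / _pairs(n))
        return vals

    if max_span_bp is None:
        left = list(range(core_idx - 1, -1, -1))
        right = list(range(core_idx + 1, len(pos)))
    else:
        left = [i for i in range(core_idx - 1, -1, -1) if core_pos - pos[i] <= max_span_bp]
        right = [i for i in range(core_idx + 1, len(pos)) if pos[i] - core_pos <= max_span_bp]
    vals = side(left)[::-1] + [1.0] + side(right)
    idx = left[::-1] + [core_idx] + right
    return EhhCurve(
        core_snp=core_idx,
        allele=core_allele,
        positions=pos[idx].astype(float),
        ehh=np.asarray(vals),
        n_carriers=n,
    )


def compare_alleles(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_idx: int,
    max_span_bp: int | None = None,
    derived_allele: int = 1,
) -> tuple[EhhCurve, EhhCurve, float]:
    """Derived vs ancestral EHH curves plus integrated-EHH ratio.

    Returns (derived, ancestral, area ratio derived/ancestral).  Raises
    on a monomorphic core or when either allele has fewer than two
    carrier haplotypes.
    """
    core = np.asarray(haplotypes)[:, core_idx]
    if len(np.unique(core[core >= 0])) < 2:
        raise ValueError("monomorphic core SNP")
    derived = ehh_curve(haplotypes, positions, core_idx, derived_allele, max_span_bp)
    ancestral = ehh_curve(haplotypes, positions, core_idx, 1 - derived_allele, max_span_bp)
    ratio = derived.integrated() / ancestral.integrated()
    return derived, ancestral, ratio
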