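"""Metabolite matrix cleaning.

Order of operations (fixed, and recorded in the returned report):

1. duplicate-sample detection (pairwise Pearson r on complete pairs),
2. sample missingness filter,
3. metabolite observed-count filter,
4. probabilistic quotient normalization — urine only, to correct
   per-sample dilution,
5. log2 transform,
6. low-variance filter,
7. per-metabolite outlier filter (fraction of samples beyond k s.d.),
8. sample outliers along leading principal components of the
   complete-information metabolites.

All filters operate on a samples-in-rows, metabolites-in-columns
DataFrame of strictly positive raw abundances with NaN for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QcConfig:
    """Thresholds for the cleaning cascade (defaults mirror the study)."""

    duplicate_r_threshold: float = 0.9
    sample_missing_max: float = 0.5
    min_samples_per_metabolite: int = 300
    reference_missing_max: float = 0.01
    variance_min: float = 0.01
    outlier_sd: float = 5.0
    outlier_sample_fraction: float = 0.05
    n_pcs: int = 15
    pc_outlier_sd: float = 5.0

    def validate(self) -> None:
        for name in ("sample_missing_max", "reference_missing_max", "outlier_sample_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "duplicate_r_threshold",
            "min_samples_per_metabolite",
            "variance_min",
            "outlier_sd",
            "n_pcs",
            "pc_outlier_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QcReport:
    """Removals attributed to exactly one rule each, in application order."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)  # (id, rule)
    removed_metabolites: list[tuple[str, str]] = field(default_factory=list)
    dilution_factors: pd.Series | None = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"item": s, "kind": "sample", "rule": r} for s, r in self.removed_samples]
        rows += [{"item": m, "kind": "metabolite", "rule": r} for m, r in self.removed_metabolites]
        return pd.DataFrame(rows, columns=["item", "kind", "rule"])


def validate_abundances(matrix: pd.DataFrame) -> None:
    """Reject zero/negative abundances (log2 undefined downstream)."""
    vals = matrix.to_numpy(float)
    finite = vals[np.isfinite(vals)]
    if finite.size and finite.min() <= 0:
        raise ValueError("non-positive abundance encountered; log2 undefined")


def detect_duplicates(
    matrix: pd.DataFrame, r_threshold: float = 0.9
) -> list[tuple[str, str]]:
    """Sample pairs with pairwise-complete Pearson r strictly above threshold.

    Profiles are compared on the per-metabolite standardized log2 scale so
    the correlation measures shared *relative* position rather than the
    metabolite mean structure (on which any two raw profiles correlate).
    All-missing samples are excluded from comparison.  Both members of a
    reported pair are candidates for removal.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two samples")
    usable = matrix.loc[matrix.notna().any(axis=1)]
    z = np.log2(usable) if (usable > 0).all().all() else usable
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    # pandas corr(min_periods) handles pairwise-complete observations
    corr = z.T.corr(min_periods=2)
    pairs = []
    ids = corr.index.to_list()
    arr = corr.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        if arr[i, j] > r_threshold:
            pairs.append((ids[i], ids[j]))
    return pairs


def pq_normalize(
    matrix: pd.DataFrame, reference_missing_max: float = 0.01
) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization on the raw abundance scale.

    The reference spectrum is the per-metabolite median across samples of
    the metabolites with at most ``reference_missing_max`` missingness
    ("endogenous" reference set).  Each sample's dilution factor is the
    median of its observed value / reference value quotients over the
    reference set; every value in the sample's row is divided by it.
    """
    missing_frac = matrix.isna().mean(axis=0)
    ref_cols = missing_frac.index[missing_frac <= reference_missing_max]
    if len(ref_cols) == 0:
        raise ValueError("no metabolite qualifies for the PQN reference set")
    ref_spectrum = matrix[ref_cols].median(axis=0)
    quotients = matrix[ref_cols].div(ref_spectrum, axis=1)
    factors = quotients.median(axis=1)
    bad = factors.index[factors.isna()]
    if len(bad) > 0:
        raise ValueError(
            f"sample(s) with zero observed reference metabolites: {list(bad)}"
        )
    return matrix.div(factors, axis=0), factors.rename("dilution_factor")


def _pc_outliers(
    log2m: pd.DataFrame, n_pcs: int, sd_mult: float, report: QcReport
) -> list[str]:
    complete = log2m.columns[log2m.notna().all(axis=0)]
    if len(complete) == 0:
        report.warnings.append("no complete-information metabolites; PC rule skipped")
        return []
    x = log2m[complete].to_numpy(float)
    x = x - x.mean(axis=0)
    k = min(n_pcs, min(x.shape))
    # scores = principal-component projections via SVD
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    dev = np.abs(scores - scores.mean(axis=0)) / sd
    mask = (dev > sd_mult).any(axis=1)
    return [sid for sid, m in zip(log2m.index, mask) if m]


def filter_metabolites_and_samples(
    matrix: pd.DataFrame,
    config: QcConfig | None = None,
    matrix_label: str = "plasma",
) -> tuple[pd.DataFrame, QcReport]:
    """Run the full cleaning cascade; returns log2-scale matrix + report.

    ``matrix`` holds raw positive abundances.  Urine is PQN-corrected
    before the log2 transform; plasma is not (dilution is a urine
    phenomenon).  Rerunning on the returned matrix's back-transformed
    values removes nothing further (idempotence checked in tests).
    """
    config = QcConfig() if config is None else config
    config.validate()
    validate_abundances(matrix)
    report = QcReport()
    m = matrix.copy()

    # 1. duplicates
    for a, b in detect_duplicates(m, config.duplicate_r_threshold):
        for sid in (a, b):
            if sid in m.index:
                report.removed_samples.append((sid, "duplicate"))
                m = m.drop(index=sid)

    # 2. sample missingness
    frac = m.isna().mean(axis=1)
    for sid in frac.index[frac > config.sample_missing_max]:
        report.removed_samples.append((sid, "sample_missingness"))
    m = m.loc[frac <= config.sample_missing_max]

    # 3. metabolite observed count
    counts = m.notna().sum(axis=0)
    drop = counts.index[counts < config.min_samples_per_metabolite]
    for met in drop:
        report.removed_metabolites.append((met, "min_samples"))
    m = m.drop(columns=drop)

    # 4. PQN (urine only)
    if matrix_label == "urine":
        m, factors = pq_normalize(m, config.reference_missing_max)
        report.dilution_factors = factors

    # 5. log2
    log2m = np.log2(m)

    # 6. variance
    var = log2m.var(axis=0, ddof=1)
    drop = var.index[var < config.variance_min]
    for met in drop:
        report.removed_metabolites.append((met, "low_variance"))
    log2m = log2m.drop(columns=drop)

    # 7. outlier metabolites
    mu = log2m.mean(axis=0)
    sd = log2m.std(axis=0, ddof=1)
    outlying = (np.abs(log2m - mu) / sd) > config.outlier_sd
    out_frac = outlying.sum(axis=0) / log2m.notna().sum(axis=0)
    drop = out_frac.index[out_frac > config.outlier_sample_fraction]
    for met in drop:
        report.removed_metabolites.append((met, "outliers"))
    log2m = log2m.drop(columns=drop)

    # 8. PC outlier samples
    for sid in _pc_outliers(log2m, config.n_pcs, config.pc_outlier_sd, report):
        report.removed_samples.append((sid, "pc_outlier"))
        log2m = log2m.drop(index=sid)

    return log2m, report
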