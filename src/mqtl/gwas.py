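"""Two-stage additive metabolite GWAS.

Stage 1 residualizes each log2 metabolite trait on its covariate set (age,
sex and three genetic PCs; plasma traits additionally on ln(eGFR) and
serum albumin).  Stage 2 regresses the residuals on each SNP's alt-allele
dosage with an intercept, reporting the per-allele effect, its standard
error and a two-sided p-value from the t distribution with n - 2 degrees
of freedom.  Genome-wide significance is a Bonferroni bound
alpha / n_traits with strict "<" comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PLASMA_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3", "ln_egfr", "albumin")
URINE_COVARIATES = ("age", "sex", "pc1", "pc2", "pc3")


@dataclass(frozen=True)
class SignificanceConfig:
    """Bonferroni significance bound: threshold = base_alpha / n_traits."""

    n_traits: int
    base_alpha: float = 5e-8

    @property
    def threshold(self) -> float:
        return self.base_alpha / self.n_traits


def covariate_design(
    covariates: pd.DataFrame,
    matrix_label: str,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Covariate design for one matrix; plasma adds ln(eGFR) and albumin.

    All-constant columns are dropped; a rank-deficient design raises with
    the names of the collinear columns.
    """
    names = PLASMA_COVARIATES if matrix_label == "plasma" else URINE_COVARIATES
    cols = {}
    for name in names:
        if name in exclude:
            continue
        if name == "ln_egfr":
            cols[name] = np.log(covariates["egfr"].to_numpy(float))
        else:
            cols[name] = covariates[name].to_numpy(float)
    design = pd.DataFrame(cols, index=covariates.index)
    design = design.loc[:, design.nunique() > 1]
    x = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name offending columns by checking rank increments
        bad = []
        keep = np.ones(len(design.index))[:, None]
        for c in design.columns:
            cand = np.column_stack([keep, design[c].to_numpy(float)])
            if np.linalg.matrix_rank(cand) == keep.shape[1]:
                bad.append(c)
            else:
                keep = cand
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    return design


def residualize(
    trait: pd.Series,
    covariates: pd.DataFrame,
    matrix_label: str,
    exclude: tuple[str, ...] = (),
) -> pd.Series:
    """OLS residuals of the trait on the matrix's covariate set.

    Complete-case on trait + covariates; residuals have mean zero and are
    numerically orthogonal to every covariate.
    """
    design = covariate_design(covariates, matrix_label, exclude=exclude)
    df = design.join(trait.rename("_y"), how="inner").dropna()
    y = df["_y"].to_numpy(float)
    x = np.column_stack([np.ones(len(df)), df[design.columns].to_numpy(float)])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return pd.Series(y - x @ beta, index=df.index, name=trait.name)


def run_gwas(residuals: pd.Series, panel, snp_subset: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP simple linear regression of residuals on dosage.

    Returns an association table with one row per SNP: beta (per alt
    allele), se, p (two-sided, t with n-2 df), eaf, n.  Monomorphic SNPs
    are emitted with NaN effect and ``undefined=True`` rather than
    silently dropped.
    """
    sample_idx = [panel.sample_ids.index(s) for s in residuals.index]
    x = panel.dosages[sample_idx, :]
    if snp_subset is not None:
        x = x[:, snp_subset]
        snps = panel.snps.iloc[snp_subset].reset_index(drop=True)
    else:
        snps = panel.snps.reset_index(drop=True)
    y = residuals.to_numpy(float)
    n = len(y)
    xm = x.mean(axis=0)
    xc = x - xm
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    mono = sxx == 0
    sxx_safe = np.where(mono, np.nan, sxx)
    beta = xc.T @ yc / sxx_safe
    # residual SS of y on each single SNP (with intercept)
    syy = float(yc @ yc)
    rss = syy - beta**2 * sxx_safe
    rss = np.clip(rss, 0.0, None)
    dof = n - 2
    se = np.sqrt(rss / dof / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2 * stats.t.sf(np.abs(tval), dof)
    out = snps[["snp", "chrom", "pos", "ref", "alt"]].copy()
    out["eaf"] = xm / 2.0
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["undefined"] = mono
    return out


def apply_threshold(table: pd.DataFrame, config: SignificanceConfig) -> pd.DataFrame:
    """Keep records with p strictly below the Bonferroni threshold."""
    return table.loc[table["p"] < config.threshold].reset_index(drop=True)


def inverse_normal_transform(values: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - 0.5) / n).

    Ties receive the average rank.  Raises on all-equal input.
    NaNs are propagated (excluded from ranking).
    """
    arr = np.asarray(values, float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    x = arr[mask]
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("inverse-normal transform requires >= 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / x.size)
    return out


def test_sex_interaction(
    index_snps: list[str],
    trait: pd.Series,
    covariates: pd.DataFrame,
    panel,
    matrix_label: str,
    n_mqtls: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """SNP x sex interaction tests at index SNPs.

    Fits trait ~ dosage + sex + dosage:sex + remaining covariates from the
    raw log2 trait (sex is excluded from the stage-1 adjustment so it is
    not adjusted twice).  Significance bound is alpha / n_mqtls; for
    significant interactions per-sex stratified effects are reported.
    """
    sex_all = covariates["sex"]
    if sex_all.nunique() < 2:
        raise ValueError("both sexes required for interaction testing")
    resid = residualize(trait, covariates, matrix_label, exclude=("sex",))
    sex = sex_all.loc[resid.index].to_numpy(float)
    sample_idx = [panel.sample_ids.index(s) for s in resid.index]
    y = resid.to_numpy(float)
    threshold = alpha / n_mqtls
    rows = []
    for snp in index_snps:
        g = panel.dosages[sample_idx, panel.snp_index(snp)]
        x = np.column_stack([np.ones(len(y)), g, sex, g * sex])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        res = y - x @ beta
        dof = len(y) - x.shape[1]
        sigma2 = res @ res / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        se_int = np.sqrt(cov[3, 3])
        t_int = beta[3] / se_int
        p_int = 2 * stats.t.sf(abs(t_int), dof)
        row = {
            "snp": snp,
            "beta_interaction": beta[3],
            "se_interaction": se_int,
            "p_interaction": p_int,
            "significant": p_int < threshold,
            "threshold": threshold,
        }
        if row["significant"]:
            for label, mask in (("female", sex == 0), ("male", sex == 1)):
                gs, ys = g[mask], y[mask]
                xs = np.column_stack([np.ones(mask.sum()), gs])
                bs, *_ = np.linalg.lstsq(xs, ys, rcond=None)
                rs = ys - xs @ bs
                s2 = rs @ rs / (mask.sum() - 2)
                ses = np.sqrt(s2 * np.linalg.inv(xs.T @ xs)[1, 1])
                row[f"beta_{label}"] = bs[1]
                row[f"se_{label}"] = ses
        rows.append(row)
    return pd.DataFrame(rows)
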