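"""Cleaning cascade: duplicates, PQN, filters, PC outliers, idempotence."""

import numpy as np
import pandas as pd
import pytest

from mqtl import qc, synthetic as syn


def random_matrix(n_samples, n_mets, seed, scale=10.0):
    rng = np.random.default_rng(seed)
    vals = np.exp2(scale + rng.normal(0, 1, (n_samples, n_mets)))
    return pd.DataFrame(
        vals,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"m{j}" for j in range(n_mets)],
    )


class TestDetectDuplicates:
    def test_duplicated_sample_reported(self):
        m = random_matrix(20, 50, 1)
        m.loc["S_dup"] = m.loc["S3"]
        pairs = qc.detect_duplicates(m, 0.9)
        assert ("S3", "S_dup") in pairs or ("S_dup", "S3") in pairs

    def test_independent_samples_have_no_high_correlation(self):
        m = random_matrix(50, 200, 2)
        assert qc.detect_duplicates(m, 0.9) == []

    def test_strict_threshold_on_noisy_duplicates(self):
        m = random_matrix(10, 100, 3)
        noisy = m.loc["S1"] * np.exp2(np.random.default_rng(4).normal(0, 0.01, 100))
        m.loc["S_noisy"] = noisy
        assert qc.detect_duplicates(m, 1.0) == []

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            qc.detect_duplicates(random_matrix(1, 5, 5))


class TestPqNormalize:
    def test_identical_samples_give_equal_factors(self):
        row = np.exp2(10 + np.random.default_rng(6).normal(0, 1, 30))
        m = pd.DataFrame([row] * 8, index=[f"S{i}" for i in range(8)])
        normed, factors = qc.pq_normalize(m)
        assert np.allclose(factors, factors.iloc[0])
        assert np.allclose(normed.to_numpy() * factors.iloc[0], m.to_numpy())

    def test_scaled_sample_factor_and_restoration(self):
        m = random_matrix(40, 60, 7)
        m.loc["S0"] = m.loc["S1"] * 2  # S0 is a 2x-diluted copy of S1
        normed, factors = qc.pq_normalize(m)
        assert factors["S0"] / factors["S1"] == pytest.approx(2.0, rel=1e-12)
        # normalization makes the diluted copy coincide with its source
        assert np.allclose(normed.loc["S0"], normed.loc["S1"])

    def test_scale_equivariance(self):
        # exact when rescaling does not move the sample through the median
        # reference spectrum: make S5 rank-extreme first
        m = random_matrix(20, 40, 8)
        m.loc["S5"] = m.loc["S5"] * 10
        normed, factors = qc.pq_normalize(m)
        m2 = m.copy()
        m2.loc["S5"] = m2.loc["S5"] * 3.7
        normed2, factors2 = qc.pq_normalize(m2)
        assert factors2["S5"] == pytest.approx(3.7 * factors["S5"], rel=1e-9)
        np.testing.assert_allclose(normed2.loc["S5"], normed.loc["S5"])

    def test_dilution_factor_recovery_on_synthetic_cohort(self):
        # log-normal dilution, n=500: estimated vs true factors nearly
        # perfectly rank-correlated
        from scipy import stats

        panel = syn.simulate_genotypes(500, [(2, 0.5, (0.2, 0.5))], seed=11)
        cov = syn.simulate_covariates(500, seed=12)
        plan = syn.EffectPlan(
            effects=[], dilution_sigma=0.5, missing_rate=0.05,
            complete_fraction=0.85, metabolites=[f"m{i}" for i in range(600)],
        )
        _, urine, truth = syn.simulate_metabolomes(panel, plan, cov, seed=13)
        _, factors = qc.pq_normalize(urine)
        rho = stats.spearmanr(truth.attrs["dilution"].loc[factors.index], factors).statistic
        assert rho > 0.99

    def test_empty_reference_set_rejected(self):
        m = random_matrix(30, 10, 9)
        m.iloc[0, :] = np.nan  # every metabolite >1% missing (1/30)
        with pytest.raises(ValueError, match="reference"):
            qc.pq_normalize(m)


class TestFilterCascade:
    def test_constant_metabolite_removed_by_variance_rule(self):
        m = random_matrix(60, 10, 10)
        m["const"] = 1024.0
        out, report = qc.filter_metabolites_and_samples(
            m, qc.QcConfig(min_samples_per_metabolite=10), "plasma"
        )
        assert "const" not in out.columns
        assert ("const", "low_variance") in report.removed_metabolites

    def test_undersampled_metabolite_removed_by_count_rule(self):
        m = random_matrix(1000, 10, 11)
        m.iloc[299:, 0] = np.nan  # observed in 299 samples only
        out, report = qc.filter_metabolites_and_samples(
            m, qc.QcConfig(min_samples_per_metabolite=300, sample_missing_max=0.9), "plasma"
        )
        assert m.columns[0] not in out.columns
        assert (m.columns[0], "min_samples") in report.removed_metabolites

    def test_pc_displaced_sample_removed(self):
        rng = np.random.default_rng(12)
        n, p = 120, 30
        log2 = rng.normal(10, 1, (n, p))
        # displace one sample 10 s.d. along the leading eigenvector
        u = rng.normal(0, 1, p)
        u /= np.linalg.norm(u)
        log2 += np.outer(rng.normal(0, 1, n), u) * 3  # create a leading PC
        log2[7] += u * 40
        m = pd.DataFrame(np.exp2(log2), index=[f"S{i}" for i in range(n)],
                         columns=[f"m{j}" for j in range(p)])
        out, report = qc.filter_metabolites_and_samples(
            m, qc.QcConfig(min_samples_per_metabolite=10), "plasma"
        )
        assert ("S7", "pc_outlier") in report.removed_samples

    def test_cascade_idempotent(self):
        m = random_matrix(80, 25, 13)
        m.iloc[:: 3, 2] = np.nan
        cfg = qc.QcConfig(min_samples_per_metabolite=10)
        out1, _ = qc.filter_metabolites_and_samples(m, cfg, "plasma")
        out2, report2 = qc.filter_metabolites_and_samples(np.exp2(out1), cfg, "plasma")
        assert report2.removed_samples == []
        assert report2.removed_metabolites == []

    def test_each_removal_attributed_once(self):
        m = random_matrix(100, 20, 14)
        m["const"] = 512.0
        m.iloc[0:90, 1] = np.nan
        out, report = qc.filter_metabolites_and_samples(
            m, qc.QcConfig(min_samples_per_metabolite=20, sample_missing_max=0.9), "plasma"
        )
        items = [i for i, _ in report.removed_metabolites]
        assert len(items) == len(set(items))

    def test_nonpositive_abundance_rejected(self):
        m = random_matrix(10, 5, 15)
        m.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="log2"):
            qc.filter_metabolites_and_samples(m, qc.QcConfig(), "plasma")
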