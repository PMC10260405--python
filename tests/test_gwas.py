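"""Residualization, per-SNP regression, thresholds, INT, sex interaction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtl import gwas, synthetic as syn


@pytest.fixture(scope="module")
def cohort():
    panel = syn.simulate_genotypes(600, [(5, 0.6, (0.2, 0.5))] * 4, seed=31)
    cov = syn.simulate_covariates(600, seed=32)
    return panel, cov


class TestResidualize:
    def test_perfect_covariate_fit_gives_zero_residuals(self, cohort):
        _, cov = cohort
        trait = pd.Series(2.0 * cov["age"].to_numpy(), index=cov.index, name="t")
        res = gwas.residualize(trait, cov, "urine")
        assert np.abs(res).max() < 1e-9

    def test_residuals_orthogonal_to_design(self, cohort):
        panel, cov = cohort
        rng = np.random.default_rng(33)
        trait = pd.Series(
            10 + 0.03 * cov["age"].to_numpy() + rng.normal(0, 1, len(cov)),
            index=cov.index, name="t",
        )
        res = gwas.residualize(trait, cov, "plasma")
        assert abs(res.mean()) < 1e-10
        design = gwas.covariate_design(cov, "plasma")
        for c in design.columns:
            r = np.corrcoef(design.loc[res.index, c], res)[0, 1]
            assert abs(r) < 1e-10

    def test_rank_deficient_design_names_columns(self, cohort):
        _, cov = cohort
        cov2 = cov.copy()
        cov2["pc2"] = 2 * cov2["pc1"]
        trait = pd.Series(np.arange(len(cov2), dtype=float), index=cov2.index, name="t")
        with pytest.raises(ValueError, match="pc2"):
            gwas.residualize(trait, cov2, "urine")


class TestRunGwas:
    def test_perfect_proportionality(self, cohort):
        panel, _ = cohort
        x = panel.dosages[:, 0]
        res = pd.Series(3.5 * (x - x.mean()), index=panel.sample_ids)
        table = gwas.run_gwas(res, panel)
        assert table["beta"].iloc[0] == pytest.approx(3.5)
        assert table["p"].iloc[0] < 1e-300

    def test_planted_effects_recovered_within_3_se(self):
        hits = 0
        n_planted = 20
        for s in range(n_planted):
            panel = syn.simulate_genotypes(800, [(3, 0.5, (0.2, 0.5))], seed=200 + s)
            rng = np.random.default_rng(300 + s)
            x = panel.dosages[:, 1]
            y = 0.4 * x + rng.normal(0, 1, 800)
            table = gwas.run_gwas(pd.Series(y - y.mean(), index=panel.sample_ids), panel)
            row = table.iloc[1]
            if abs(row["beta"] - 0.4) < 3 * row["se"]:
                hits += 1
        assert hits >= int(0.95 * n_planted) - 1

    def test_monomorphic_snp_flagged_not_dropped(self, cohort):
        panel, _ = cohort
        panel2 = syn.GenotypePanel(
            sample_ids=panel.sample_ids,
            snps=panel.snps.copy(),
            dosages=panel.dosages.copy(),
        )
        panel2.dosages[:, 2] = 1.0
        res = pd.Series(np.random.default_rng(34).normal(0, 1, 600),
                        index=panel2.sample_ids)
        table = gwas.run_gwas(res, panel2)
        assert len(table) == panel2.n_snps
        assert bool(table["undefined"].iloc[2])
        assert np.isnan(table["beta"].iloc[2])

    def test_allele_flip_negates_effect(self, cohort):
        panel, _ = cohort
        rng = np.random.default_rng(35)
        res = pd.Series(0.3 * panel.dosages[:, 0] + rng.normal(0, 1, 600),
                        index=panel.sample_ids)
        res -= res.mean()
        t1 = gwas.run_gwas(res, panel)
        flipped = syn.GenotypePanel(
            sample_ids=panel.sample_ids, snps=panel.snps.copy(),
            dosages=2.0 - panel.dosages,
        )
        t2 = gwas.run_gwas(res, flipped)
        np.testing.assert_allclose(t2["beta"], -t1["beta"], rtol=1e-10)
        np.testing.assert_allclose(t2["p"], t1["p"], rtol=1e-8)

    def test_two_stage_matches_joint_fit_closely(self, cohort):
        # residual-on-dosage slope approximates the SNP coefficient of the
        # joint trait ~ dosage + covariates regression to O(1/n)
        panel, cov = cohort
        rng = np.random.default_rng(36)
        x = panel.dosages[:, 3]
        trait = pd.Series(
            0.25 * x + 0.02 * cov["age"].to_numpy() + rng.normal(0, 1, 600),
            index=cov.index, name="t",
        )
        res = gwas.residualize(trait, cov, "urine")
        beta_two_stage = gwas.run_gwas(res, panel)["beta"].iloc[3]
        design = gwas.covariate_design(cov, "urine")
        xj = np.column_stack([np.ones(600), x, design.to_numpy(float)])
        beta_joint = np.linalg.lstsq(xj, trait.to_numpy(), rcond=None)[0][1]
        assert beta_two_stage == pytest.approx(beta_joint, abs=5e-3)


class TestThresholds:
    @pytest.mark.parametrize(
        "n_traits,expected",
        [(1296, 3.9e-11), (1401, 3.6e-11), (1, 5e-8)],
    )
    def test_bonferroni_threshold(self, n_traits, expected):
        cfg = gwas.SignificanceConfig(n_traits=n_traits)
        assert cfg.threshold == pytest.approx(5e-8 / n_traits, rel=1e-15)
        assert cfg.threshold == pytest.approx(expected, rel=0.02)

    def test_strict_inequality(self, assoc_builder):
        cfg = gwas.SignificanceConfig(n_traits=1)
        t = assoc_builder([{"chrom": "1", "pos": 100, "p": 5e-8},
                           {"chrom": "1", "pos": 200, "p": 4.9e-8}])
        kept = gwas.apply_threshold(t, cfg)
        assert list(kept["pos"]) == [200]


class TestInverseNormal:
    def test_three_values_closed_form(self):
        out = gwas.inverse_normal_transform(np.array([5.0, 1.0, 3.0]))
        expected = stats.norm.ppf([(2.5) / 3, 0.5 / 3, 1.5 / 3])
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_tied_minima_share_average_rank(self):
        out = gwas.inverse_normal_transform(np.array([1.0, 1.0, 2.0, 3.0]))
        expected_tie = stats.norm.ppf((1.5 - 0.5) / 4)
        assert out[0] == pytest.approx(expected_tie)
        assert out[1] == pytest.approx(expected_tie)

    def test_rank_preservation_and_moments(self):
        rng = np.random.default_rng(37)
        x = rng.exponential(1, 500)
        out = gwas.inverse_normal_transform(x)
        assert stats.spearmanr(x, out).statistic == pytest.approx(1.0)
        assert abs(out.mean()) < 1e-10
        assert out.std() == pytest.approx(1.0, abs=0.05)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            gwas.inverse_normal_transform(np.ones(10))


class TestSexInteraction:
    def test_interaction_threshold_value(self):
        assert 0.05 / 1299 == pytest.approx(3.8e-5, rel=0.02)

    def test_single_sex_rejected(self, cohort):
        panel, cov = cohort
        cov2 = cov.copy()
        cov2["sex"] = 1
        trait = pd.Series(np.random.default_rng(38).normal(0, 1, 600),
                          index=cov2.index, name="t")
        with pytest.raises(ValueError):
            gwas.test_sex_interaction(["rs000001"], trait, cov2, panel, "urine", 10)

    def test_male_only_effect_detected(self):
        detected = 0
        nsim = 5
        for s in range(nsim):
            panel = syn.simulate_genotypes(4000, [(2, 0.5, (0.3, 0.5))], seed=400 + s)
            cov = syn.simulate_covariates(4000, seed=500 + s)
            rng = np.random.default_rng(600 + s)
            x = panel.dosages[:, 0]
            sex = cov["sex"].to_numpy(float)
            y = 0.6 * x * sex + rng.normal(0, 1, 4000)
            trait = pd.Series(10 + y, index=cov.index, name="t")
            res = gwas.test_sex_interaction(
                [panel.snps["snp"].iloc[0]], trait, cov, panel, "urine", 1299
            )
            if res["p_interaction"].iloc[0] < 0.05 / 1299:
                detected += 1
        assert detected >= 4  # >= 80% power

    def test_equal_effects_give_null_interaction(self):
        pvals = []
        for s in range(40):
            panel = syn.simulate_genotypes(500, [(1, 0.5, (0.3, 0.5))], seed=700 + s)
            cov = syn.simulate_covariates(500, seed=800 + s)
            rng = np.random.default_rng(900 + s)
            x = panel.dosages[:, 0]
            y = 0.5 * x + rng.normal(0, 1, 500)  # same effect in both sexes
            trait = pd.Series(10 + y, index=cov.index, name="t")
            res = gwas.test_sex_interaction(
                [panel.snps["snp"].iloc[0]], trait, cov, panel, "urine", 1
            )
            pvals.append(res["p_interaction"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
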