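"""Stepwise conditional selection, Wakefield ABF, credible sets, alignment."""

import numpy as np
import pandas as pd
import pytest

from mqtl import finemap, loci, synthetic as syn

THRESHOLD = 3.9e-11


def _resid(y, ids):
    return pd.Series(y - y.mean(), index=ids)


class TestWakefieldAbf:
    def test_zero_z_equal_variances(self):
        # z=0 and V=W force ABF = sqrt(1/2) analytically
        assert finemap.wakefield_abf(0.0, 1.33, prior_sd=1.33) == pytest.approx(
            np.sqrt(0.5), rel=1e-12
        )

    def test_dual_implementation_agreement(self):
        # independent direct-scale coding of the same closed form
        def direct(beta, se, w_sd):
            v, w = se**2, w_sd**2
            z = beta / se
            return np.sqrt(v / (v + w)) * np.exp(z * z * w / (2 * (v + w)))

        for beta, se in [(0.3, 0.05), (0.0, 0.2), (-1.2, 0.4), (0.8, 0.03)]:
            assert finemap.wakefield_abf(beta, se, 1.33) == pytest.approx(
                direct(beta, se, 1.33), rel=1e-10
            )

    def test_monotone_in_abs_z(self):
        se = 0.1
        zs = np.linspace(0, 20, 50)
        vals = [finemap.wakefield_abf(z * se, se, 1.33, log=True) for z in zs]
        assert np.all(np.diff(vals) > 0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            finemap.wakefield_abf(0.5, 0.0)


class TestCredibleSet:
    def test_single_snp_region(self):
        cs = finemap.credible_set(["a"], np.array([2.0]))
        assert cs.size == 1
        assert cs.table["ppa"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "ppas,expected_size",
        [([0.95, 0.045, 0.005], 2), ([0.80, 0.15, 0.04, 0.01], 4)],
    )
    def test_strict_prefix_rule(self, ppas, expected_size):
        labf = np.log(ppas)  # ABFs proportional to target PPAs
        cs = finemap.credible_set([f"s{i}" for i in range(len(ppas))], labf)
        assert cs.size == expected_size

    def test_ppa_sums_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(51)
        labf = rng.normal(0, 3, 30)
        cs1 = finemap.credible_set([f"s{i}" for i in range(30)], labf)
        cs2 = finemap.credible_set([f"s{i}" for i in range(30)], labf + 123.4)
        assert cs1.table["ppa"].sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(cs1.table["ppa"], cs2.table["ppa"], rtol=1e-9)
        assert cs1.size == cs2.size

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            finemap.credible_set(["a", "b"], np.array([np.nan, 0.0]))


class TestStepwiseSelect:
    def test_single_causal_with_tight_proxies(self):
        panel = syn.simulate_genotypes(2000, [(10, 0.95, (0.3, 0.5))], seed=52)
        rng = np.random.default_rng(53)
        y = 0.4 * panel.dosages[:, 4] + rng.normal(0, 1, 2000)
        sig = finemap.stepwise_select(
            list(panel.snps["snp"]), _resid(y, panel.sample_ids), panel, THRESHOLD
        )
        assert len(sig) == 1

    def test_two_independent_causals_both_selected(self):
        panel = syn.simulate_genotypes(
            3000, [(6, 0.7, (0.3, 0.5)), (6, 0.7, (0.3, 0.5))], seed=54
        )
        rng = np.random.default_rng(55)
        b1 = b2 = 0.35
        y = b1 * panel.dosages[:, 2] + b2 * panel.dosages[:, 8] + rng.normal(0, 1, 3000)
        sig = finemap.stepwise_select(
            list(panel.snps["snp"]), _resid(y, panel.sample_ids), panel, THRESHOLD
        )
        leads = {s.lead_snp for s in sig}
        causal = {panel.snps["snp"].iloc[2], panel.snps["snp"].iloc[8]}
        # selected leads are the causal SNPs or tight proxies; conditional
        # effects recover the planted values within 3 SE
        assert len(sig) == 2
        for s in sig:
            assert abs(s.beta_conditional - 0.35) < 3 * s.se_conditional

    def test_no_signal_empty(self):
        panel = syn.simulate_genotypes(500, [(5, 0.5, (0.3, 0.5))], seed=56)
        rng = np.random.default_rng(57)
        y = rng.normal(0, 1, 500)
        sig = finemap.stepwise_select(
            list(panel.snps["snp"]), _resid(y, panel.sample_ids), panel, THRESHOLD
        )
        assert sig == []

    def test_empty_region_rejected(self, demo_panel):
        with pytest.raises(ValueError):
            finemap.stepwise_select([], pd.Series(dtype=float), demo_panel, THRESHOLD)


class TestAlignRegions:
    def _mqtl(self, snp, chrom, pos):
        return loci.Mqtl(
            trait="m", matrix="urine", index_snp=snp, chrom=chrom, pos=pos,
            p=1e-20, beta=1, se=0.1, eaf=0.3, start=pos - 500_000, end=pos + 500_000,
        )

    def test_identical_index_snps_grouped(self, demo_panel):
        s = demo_panel.snps["snp"].iloc[0]
        groups = finemap.align_regions(
            [self._mqtl(s, "1", 100), self._mqtl(s, "1", 100)], demo_panel
        )
        assert len(groups) == 1

    def test_different_blocks_stay_separate(self, demo_panel):
        a = demo_panel.snps["snp"].iloc[0]
        c = demo_panel.snps["snp"].iloc[16]  # low-LD block
        groups = finemap.align_regions(
            [self._mqtl(a, "1", 100), self._mqtl(c, "1", 200)], demo_panel
        )
        assert len(groups) == 2

    def test_single_linkage_chains(self):
        # three SNPs pairwise in LD above the cutoff chain into one group
        # even when some pairwise r2 values differ (single linkage)
        panel = syn.simulate_genotypes(3000, [(3, 0.85, (0.4, 0.5))], seed=58)
        snps = list(panel.snps["snp"])
        mqtls = [self._mqtl(s, "1", 100 + i) for i, s in enumerate(snps)]
        groups = finemap.align_regions(mqtls, panel, r2_threshold=0.8)
        assert len(groups) == 1

    def test_missing_index_snp_rejected(self, demo_panel):
        with pytest.raises(KeyError):
            finemap.align_regions([self._mqtl("rs_nope", "1", 5)], demo_panel)


class TestFinemapRegion:
    def test_overwhelming_single_signal_maps_to_one_snp(self):
        panel = syn.simulate_genotypes(3000, [(8, 0.3, (0.3, 0.5))], seed=59)
        rng = np.random.default_rng(60)
        y = 1.0 * panel.dosages[:, 3] + rng.normal(0, 1, 3000)
        res = finemap.finemap_region(
            list(panel.snps["snp"]), _resid(y, panel.sample_ids), panel, THRESHOLD
        )
        assert len(res.signals) == 1
        cs = res.credible_sets[0]
        assert panel.snps["snp"].iloc[3] in cs.snps
        assert cs.size <= 2
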