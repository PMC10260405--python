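"""Colocalization: hypothesis posteriors, pairing, classification, triggers."""

import numpy as np
import pandas as pd
import pytest

from mqtl import coloc, gwas, loci, synthetic as syn


def _gwas_table(panel, y):
    res = pd.Series(y - y.mean(), index=panel.sample_ids)
    return gwas.run_gwas(res, panel)


@pytest.fixture(scope="module")
def strong_pair():
    panel = syn.simulate_genotypes(2000, [(40, 0.6, (0.2, 0.5))], seed=61)
    rng = np.random.default_rng(62)
    x = panel.dosages[:, 20]
    ya = 0.6 * x + rng.normal(0, 1, 2000)
    yb = 0.6 * x + rng.normal(0, 1, 2000)
    return panel, _gwas_table(panel, ya), _gwas_table(panel, yb)


class TestColocAbf:
    def test_self_coloc_gives_h4(self, strong_pair):
        _, ta, _ = strong_pair
        res = coloc.coloc_abf(ta, ta)
        assert res.pp_h4 > 0.95

    def test_shared_causal_variant_gives_h4(self, strong_pair):
        _, ta, tb = strong_pair
        res = coloc.coloc_abf(ta, tb)
        assert res.pp_h4 > 0.8
        assert res.posteriors().sum() == pytest.approx(1.0, abs=1e-9)

    def test_distinct_causal_variants_give_h3(self):
        panel = syn.simulate_genotypes(
            2000, [(20, 0.6, (0.2, 0.5)), (20, 0.6, (0.2, 0.5))], seed=63
        )
        rng = np.random.default_rng(64)
        ya = 0.6 * panel.dosages[:, 10] + rng.normal(0, 1, 2000)
        yb = 0.6 * panel.dosages[:, 30] + rng.normal(0, 1, 2000)
        res = coloc.coloc_abf(_gwas_table(panel, ya), _gwas_table(panel, yb))
        assert res.pp_h3 > 0.95

    def test_double_null_gives_h0(self):
        panel = syn.simulate_genotypes(1000, [(200, 0.3, (0.2, 0.5))], seed=65)
        rng = np.random.default_rng(66)
        res = coloc.coloc_abf(
            _gwas_table(panel, rng.normal(0, 1, 1000)),
            _gwas_table(panel, rng.normal(0, 1, 1000)),
        )
        assert res.pp_h0 > 0.9

    def test_swap_symmetry(self, strong_pair):
        panel, ta, tb = strong_pair
        r1 = coloc.coloc_abf(ta, tb)
        r2 = coloc.coloc_abf(tb, ta)
        assert r1.pp_h1 == pytest.approx(r2.pp_h2, rel=1e-9)
        assert r1.pp_h2 == pytest.approx(r2.pp_h1, rel=1e-9)
        assert r1.pp_h3 == pytest.approx(r2.pp_h3, rel=1e-9)
        assert r1.pp_h4 == pytest.approx(r2.pp_h4, rel=1e-9)

    def test_uniform_scaling_invariance(self, strong_pair):
        _, ta, tb = strong_pair
        r1 = coloc.coloc_abf(ta, tb)
        ta2, tb2 = ta.copy(), tb.copy()
        for t in (ta2, tb2):
            t["beta"] *= 3.0
            t["se"] *= 3.0
        r2 = coloc.coloc_abf(ta2, tb2)
        np.testing.assert_allclose(r1.posteriors(), r2.posteriors(), rtol=1e-9)

    def test_allele_flip_handled(self, strong_pair):
        _, ta, tb = strong_pair
        tb2 = tb.copy()
        tb2["ref"], tb2["alt"] = tb["alt"], tb["ref"]
        tb2["beta"] = -tb2["beta"]
        r1 = coloc.coloc_abf(ta, tb)
        r2 = coloc.coloc_abf(ta, tb2)
        np.testing.assert_allclose(r1.posteriors(), r2.posteriors(), rtol=1e-9)

    def test_empty_intersection_rejected(self, strong_pair, assoc_builder):
        _, ta, _ = strong_pair
        other = assoc_builder([{"chrom": "9", "pos": 1}])
        with pytest.raises(ValueError):
            coloc.coloc_abf(ta, other)


class TestPairing:
    def _mqtl(self, trait, matrix, chrom, pos):
        return loci.Mqtl(trait=trait, matrix=matrix, index_snp="s", chrom=chrom,
                         pos=pos, p=1e-20, beta=1, se=0.1, eaf=0.3,
                         start=pos - 500_000, end=pos + 500_000)

    def test_overlapping_windows_paired_with_union_region(self):
        a = self._mqtl("x", "plasma", "1", 10_000_000)
        b = self._mqtl("y", "urine", "1", 10_600_000)
        pairs = coloc.pair_mqtls([a, b])
        assert len(pairs) == 1
        _, _, (chrom, lo, hi) = pairs[0]
        assert (lo, hi) == (9_500_000, 11_100_000)
        assert hi - lo == 1_600_000

    def test_distant_windows_not_paired(self):
        a = self._mqtl("x", "plasma", "1", 10_000_000)
        b = self._mqtl("y", "urine", "1", 11_100_001)
        assert coloc.pair_mqtls([a, b]) == []

    def test_cross_chromosome_never_paired(self):
        a = self._mqtl("x", "plasma", "1", 10_000_000)
        b = self._mqtl("y", "urine", "2", 10_000_000)
        assert coloc.pair_mqtls([a, b]) == []

    @pytest.mark.parametrize(
        "ma,mb,ta,tb,expected",
        [
            ("plasma", "plasma", "glycine", "serine", "intraplasma"),
            ("urine", "urine", "glycine", "serine", "intraurine"),
            ("plasma", "urine", "glycine", "glycine", "intermatrix_same_metabolite"),
            ("plasma", "urine", "glycine", "serine", "intermatrix_different_metabolite"),
        ],
    )
    def test_classification(self, ma, mb, ta, tb, expected):
        a = self._mqtl(ta, ma, "1", 1_000_000)
        b = self._mqtl(tb, mb, "1", 1_000_000)
        assert coloc.classify(a, b) == expected


class TestExternalTrigger:
    def _setup(self):
        panel = syn.simulate_genotypes(1500, [(30, 0.6, (0.2, 0.5))], seed=67)
        rng = np.random.default_rng(68)
        x = panel.dosages[:, 15]
        ya = 0.6 * x + rng.normal(0, 1, 1500)
        ta = _gwas_table(panel, ya)
        q = loci.Mqtl(trait="met", matrix="plasma",
                      index_snp=panel.snps["snp"].iloc[15], chrom="1",
                      pos=int(panel.snps["pos"].iloc[15]), p=1e-30, beta=0.6,
                      se=0.05, eaf=0.3, start=1, end=2_000_000)
        return panel, ta, q, rng

    def test_trigger_threshold_arithmetic(self):
        assert 0.05 / 409 == pytest.approx(1.222e-4, rel=1e-3)

    def test_weak_external_signal_not_triggered(self):
        panel, ta, q, rng = self._setup()
        ext = ta.copy()
        ext["p"] = 1e-3  # below nominal but above 0.05/409
        assert coloc.external_coloc_trigger(q, ta, ext, n_index=409) is None

    def test_maf_gate_blocks_trigger(self):
        panel, ta, q, rng = self._setup()
        ext = ta.copy()
        ext["p"] = 1e-6
        ext["eaf"] = 0.005
        assert coloc.external_coloc_trigger(q, ta, ext, n_index=409) is None

    def test_joint_gate_triggers_and_colocalizes(self):
        panel, ta, q, rng = self._setup()
        yb = 0.6 * panel.dosages[:, 15] + rng.normal(0, 1, 1500)
        ext = _gwas_table(panel, yb)
        res = coloc.external_coloc_trigger(q, ta, ext, n_index=409)
        assert res is not None
        assert res.group == "mqtl_vs_external"
        assert res.pp_h4 > 0.8
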