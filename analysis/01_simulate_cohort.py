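#!/usr/bin/env python
"""Generate the synthetic paired plasma/urine cohort used by all later steps.

Plants one shared, one plasma-only and one urine-only mQTL (effect 0.6 per
alt allele on the log2 scale, h2 target 0.3) among null metabolites on an
LD-blocked panel, with per-sample urine dilution and missing-at-random
dropout, and writes genotypes (TSV + VCF), metabolite matrices, covariates
and the truth table under scratch/cohort/ (bulky, regenerable intermediates).
"""

from pathlib import Path

from mqtl import io
from mqtl.pipeline import PipelineConfig, build_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
SEED = 20230601


def main() -> None:
    cfg = PipelineConfig(seed=SEED)
    panel, cov, plasma, urine, truth = build_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_dosage_tsv(panel, OUT / "dosages.tsv", seed=cfg.seed)
    io.write_vcf(panel, OUT / "panel.vcf", seed=cfg.seed)
    io.write_metabolite_tsv(plasma, OUT / "plasma_raw.tsv")
    io.write_metabolite_tsv(urine, OUT / "urine_raw.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    truth.attrs["dilution"].to_csv(OUT / "dilution.tsv", sep="\t")
    cov.to_csv(OUT / "covariates.tsv", sep="\t")
    io.write_yaml(cfg.to_dict(), OUT / "config.yaml")
    print(f"cohort: {panel.n_samples} samples, {panel.n_snps} SNPs, "
          f"{plasma.shape[1]} metabolites per matrix")
    print(f"planted mQTLs:\n{truth[['snp', 'metabolite', 'matrix', 'beta']]}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
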