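#!/usr/bin/env python
"""Operating characteristics of the statistical machinery.

Runs the simulation studies at the sizes used throughout this project:
credible-set coverage (500 single-causal sims, n=2,000, 50-SNP block),
colocalization H4 sensitivity / H3 specificity (200 pairs, z-peaks >= 8),
GWAS type-I error (10,000 null SNPs at n=1,000), REML recovery of a
planted h2 = 0.5 (20 seeds, n=1,000), and PQN dilution recovery (n=500).
"""

import json
from pathlib import Path

from mqtl import experiments

BASE = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 20230609


def main() -> None:
    out = BASE / "calibration"
    out.mkdir(parents=True, exist_ok=True)
    studies = {
        "finemap_coverage": experiments.finemap_coverage(n_sims=500, seed=SEED),
        "coloc_discrimination": experiments.coloc_discrimination(n_sims=200,
                                                                 seed=SEED + 1),
        "gwas_type1_error": experiments.gwas_type1_error(seed=SEED + 2),
        "h2_recovery": experiments.h2_recovery(seed=SEED + 3),
        "pqn_dilution_recovery": experiments.pqn_dilution_recovery(seed=SEED + 4),
    }
    (out / "calibration.json").write_text(json.dumps(studies, indent=2))
    for name, res in studies.items():
        print(f"{name}: {res}")


if __name__ == "__main__":
    main()
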