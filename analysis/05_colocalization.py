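#!/usr/bin/env python
"""Pairwise colocalization of all called mQTLs.

Pairs mQTLs whose +-500 kb index windows overlap, runs the five-hypothesis
enumeration over the merged windows with default priors (p1 = p2 = 1e-4,
p12 = 1e-5), and classifies positives (PP H4 > 0.8) into the four groups.
The planted shared metabolite should colocalize across matrices; loci on
different LD blocks should not.
"""

from pathlib import Path

import dataclasses

import pandas as pd

from mqtl import coloc, io, loci

BASE = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    mq = pd.read_csv(BASE / "gwas" / "mqtls.tsv", sep="\t")
    out = BASE / "coloc"
    out.mkdir(parents=True, exist_ok=True)
    mqtls = [
        loci.Mqtl(trait=r.trait, matrix=r.matrix, index_snp=r.index_snp,
                  chrom=str(r.chrom), pos=int(r.pos), p=r.p, beta=r.beta,
                  se=r.se, eaf=r.eaf, start=int(r.start), end=int(r.end))
        for r in mq.itertuples()
    ]
    results = []
    for a, b, (chrom, lo, hi) in coloc.pair_mqtls(mqtls):
        sa = io.read_summary_stats(SCRATCH / "gwas" / f"{a.trait}.{a.matrix}.tsv")
        sb = io.read_summary_stats(SCRATCH / "gwas" / f"{b.trait}.{b.matrix}.tsv")
        win = lambda t: t.loc[(t["chrom"].astype(str) == str(chrom))  # noqa: E731
                              & (t["pos"] >= lo) & (t["pos"] <= hi)]
        res = coloc.coloc_abf(win(sa), win(sb),
                              trait_a=f"{a.trait}[{a.matrix}]",
                              trait_b=f"{b.trait}[{b.matrix}]")
        if res.positive:
            res.group = coloc.classify(a, b)
        results.append(res)

    tab = pd.DataFrame([dataclasses.asdict(r) for r in results])
    tab.to_csv(out / "coloc.tsv", sep="\t", index=False)
    pos = tab.loc[tab["pp_h4"] > 0.8]
    print(f"{len(tab)} pair(s) tested, {len(pos)} positive (PP H4 > 0.8):")
    if not pos.empty:
        print(pos[["trait_a", "trait_b", "pp_h4", "group"]])
    print("group counts:", pos["group"].value_counts().to_dict())


if __name__ == "__main__":
    main()
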