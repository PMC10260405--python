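"""End-to-end driver over a synthetic paired cohort.

Executes qc -> gwas -> locus calling -> fine mapping -> colocalization ->
gene prioritization -> enrichment, with optional heritability and EHH
stages, writing plain-text artifacts and a manifest (stage status, seed,
SHA-256 digests of every output) into a run directory.  All randomness
flows from the single config seed; rerunning with the same config
reproduces every artifact bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as _coloc
from . import ehh as _ehh
from . import enrich as _enrich
from . import finemap as _finemap
from . import genes as _genes
from . import gwas as _gwas
from . import heritability as _h2
from . import io as _io
from . import loci as _loci
from . import qc as _qc
from . import synthetic as _syn

_STAGES = ("qc", "gwas", "loci", "finemap", "coloc", "prioritize", "enrich", "h2", "ehh")


@dataclass
class PipelineConfig:
    """Stage toggles, study thresholds and cohort dimensions.

    Threshold defaults are the study values; cohort dimensions default to
    a desk-scale synthetic cohort that still yields well-powered planted
    loci.  Unknown keys in a YAML override are rejected.
    """

    seed: int = 1
    out_dir: str = "runs/demo"
    stages: tuple[str, ...] = ("qc", "gwas", "loci", "finemap", "coloc", "prioritize", "enrich")
    # cohort
    n_samples: int = 1000
    n_blocks: int = 12
    snps_per_block: int = 10
    ld_r2: float = 0.7
    freq_range: tuple[float, float] = (0.1, 0.5)
    n_null_metabolites: int = 37
    effect_beta: float = 0.6
    h2_target: float = 0.3
    missing_rate: float = 0.02
    dilution_sigma: float = 0.5
    # analysis thresholds (study defaults)
    base_alpha: float = 5e-8
    collinearity: float = 0.1
    finemap_prior_sd: float = 1.33
    coloc_prior_sd: float = 0.15
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    h4_cutoff: float = 0.8
    enrich_draws: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = _io.read_yaml(path) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "freq_range" in raw:
            raw["freq_range"] = tuple(raw["freq_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["freq_range"] = list(d["freq_range"])
        return d


def build_cohort(cfg: PipelineConfig):
    """Simulate panel, covariates, paired metabolomes and the truth table."""
    panel = _syn.simulate_genotypes(
        cfg.n_samples,
        [(cfg.snps_per_block, cfg.ld_r2, cfg.freq_range)] * cfg.n_blocks,
        seed=cfg.seed,
    )
    cov = _syn.simulate_covariates(cfg.n_samples, seed=cfg.seed + 1)
    # plant one shared, one plasma-only and one urine-only mQTL on distinct
    # blocks, plus null metabolites
    mid = cfg.snps_per_block // 2
    snp_at = lambda b: panel.snps["snp"].iloc[b * cfg.snps_per_block + mid]  # noqa: E731
    effects = [
        _syn.PlantedEffect(snp_at(0), "met_shared", "both", cfg.effect_beta),
        _syn.PlantedEffect(snp_at(1), "met_plasma", "plasma", cfg.effect_beta),
        _syn.PlantedEffect(snp_at(2), "met_urine", "urine", cfg.effect_beta),
    ]
    plan = _syn.EffectPlan(
        effects=effects,
        h2={e.metabolite: cfg.h2_target for e in effects},
        dilution_sigma=cfg.dilution_sigma,
        missing_rate=cfg.missing_rate,
        metabolites=[e.metabolite for e in effects]
        + [f"met_null_{i}" for i in range(cfg.n_null_metabolites)],
    )
    plasma, urine, truth = _syn.simulate_metabolomes(panel, plan, cov, seed=cfg.seed + 2)
    return panel, cov, plasma, urine, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    A stage failure aborts the run with the stage name; artifacts written
    by completed stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_yaml(cfg.to_dict(), out / "config.yaml")
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _io.file_digest(path)

    panel, cov, plasma_raw, urine_raw, truth = build_cohort(cfg)
    _io.write_dosage_tsv(panel, out / "dosages.tsv", seed=cfg.seed)
    _io.write_vcf(panel, out / "panel.vcf", seed=cfg.seed)
    _io.write_metabolite_tsv(plasma_raw, out / "plasma_raw.tsv")
    _io.write_metabolite_tsv(urine_raw, out / "urine_raw.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cov.to_csv(out / "covariates.tsv", sep="\t")
    for f in ("dosages.tsv", "panel.vcf", "plasma_raw.tsv", "urine_raw.tsv",
              "truth.tsv", "covariates.tsv"):
        record(out / f)

    current_stage = "setup"
    try:
        matrices: dict[str, pd.DataFrame] = {}
        if "qc" in cfg.stages:
            current_stage = "qc"
            qc_cfg = _qc.QcConfig(min_samples_per_metabolite=min(300, cfg.n_samples // 2))
            reports = []
            for label, raw in (("plasma", plasma_raw), ("urine", urine_raw)):
                cleaned, report = _qc.filter_metabolites_and_samples(raw, qc_cfg, label)
                matrices[label] = cleaned
                rep = report.to_frame()
                rep["matrix"] = label
                reports.append(rep)
                _io.write_metabolite_tsv(cleaned, out / f"{label}_log2.tsv")
                record(out / f"{label}_log2.tsv")
            pd.concat(reports).to_csv(out / "qc_report.tsv", sep="\t", index=False)
            record(out / "qc_report.tsv")
            manifest["stages"]["qc"] = "complete"
        else:
            matrices["plasma"] = np.log2(plasma_raw)
            matrices["urine"] = np.log2(urine_raw)

        thresholds = {
            label: _gwas.SignificanceConfig(
                n_traits=matrices[label].shape[1], base_alpha=cfg.base_alpha
            )
            for label in matrices
        }
        assoc: dict[tuple[str, str], pd.DataFrame] = {}
        residuals: dict[tuple[str, str], pd.Series] = {}
        if "gwas" in cfg.stages:
            current_stage = "gwas"
            for label, mat in matrices.items():
                for met in mat.columns:
                    r = _gwas.residualize(mat[met], cov, label)
                    residuals[(label, met)] = r
                    assoc[(label, met)] = _gwas.run_gwas(r, panel)
            gwas_dir = out / "gwas"
            gwas_dir.mkdir(exist_ok=True)
            for (label, met), table in assoc.items():
                _io.write_summary_stats(table, gwas_dir / f"{met}.{label}.tsv")
            manifest["stages"]["gwas"] = "complete"

        mqtls: list = []
        if "loci" in cfg.stages:
            current_stage = "loci"
            for (label, met), table in assoc.items():
                called = _loci.call_mqtls(
                    table, thresholds[label].threshold, trait=met, matrix=label
                )
                kept = []
                for q in called:
                    if _loci.rare_variant_check(
                        q, matrices[label][met], cov, panel,
                        thresholds[label].threshold, label,
                    ):
                        dosage = panel.dosages[:, panel.snp_index(q.index_snp)]
                        q.variance_explained = _loci.variance_explained(
                            dosage, matrices[label][met].reindex(panel.sample_ids)
                        )
                        kept.append(q)
                mqtls.extend(kept)
            pd.DataFrame([q.to_dict() for q in mqtls]).to_csv(
                out / "mqtls.tsv", sep="\t", index=False
            )
            _io.write_bed_loci(mqtls, out / "loci.bed")
            record(out / "mqtls.tsv")
            record(out / "loci.bed")
            manifest["stages"]["loci"] = "complete"

        if "finemap" in cfg.stages:
            current_stage = "finemap"
            fm_rows, cs_rows = [], []
            for q in mqtls:
                res = _finemap.finemap_region(
                    q.members,
                    residuals[(q.matrix, q.trait)],
                    panel,
                    thresholds[q.matrix].threshold,
                    collinearity=cfg.collinearity,
                    prior_sd=cfg.finemap_prior_sd,
                )
                for sig, cs in zip(res.signals, res.credible_sets):
                    fm_rows.append(
                        {
                            "trait": q.trait, "matrix": q.matrix,
                            "lead_snp": sig.lead_snp,
                            "beta_conditional": sig.beta_conditional,
                            "se_conditional": sig.se_conditional,
                            "p_conditional": sig.p_conditional,
                            "set_size": cs.size,
                        }
                    )
                    t = cs.table.copy()
                    t.insert(0, "trait", q.trait)
                    t.insert(1, "matrix", q.matrix)
                    t.insert(2, "lead_snp", sig.lead_snp)
                    cs_rows.append(t)
            pd.DataFrame(fm_rows).to_csv(out / "signals.tsv", sep="\t", index=False)
            if cs_rows:
                pd.concat(cs_rows).to_csv(out / "credible_sets.tsv", sep="\t", index=False)
                record(out / "credible_sets.tsv")
            record(out / "signals.tsv")
            manifest["stages"]["finemap"] = "complete"

        coloc_results: list = []
        if "coloc" in cfg.stages:
            current_stage = "coloc"
            for a, b, (chrom, lo, hi) in _coloc.pair_mqtls(mqtls):
                sa = assoc[(a.matrix, a.trait)]
                sb = assoc[(b.matrix, b.trait)]
                win = lambda t: t.loc[(t["chrom"].astype(str) == str(chrom))  # noqa: E731
                                      & (t["pos"] >= lo) & (t["pos"] <= hi)]
                res = _coloc.coloc_abf(
                    win(sa), win(sb),
                    p1=cfg.coloc_p1, p2=cfg.coloc_p2, p12=cfg.coloc_p12,
                    prior_sd=cfg.coloc_prior_sd,
                    trait_a=f"{a.trait}[{a.matrix}]", trait_b=f"{b.trait}[{b.matrix}]",
                )
                if res.pp_h4 > cfg.h4_cutoff:
                    res.group = _coloc.classify(a, b)
                coloc_results.append(res)
            pd.DataFrame([dataclasses.asdict(r) for r in coloc_results]).to_csv(
                out / "coloc.tsv", sep="\t", index=False
            )
            record(out / "coloc.tsv")
            manifest["stages"]["coloc"] = "complete"

        winners: list[str] = []
        gene_windows: dict[str, tuple[str, int, int]] = {}
        if "prioritize" in cfg.stages or "enrich" in cfg.stages:
            # synthetic gene model: one gene per LD block, spanning the block
            for b, grp in panel.snps.groupby("block"):
                gene_windows[f"GENE{b:02d}"] = (
                    str(grp["chrom"].iloc[0]), int(grp["pos"].min()), int(grp["pos"].max())
                )
        if "prioritize" in cfg.stages:
            current_stage = "prioritize"
            positive_traits = {
                r.trait_a for r in coloc_results if r.pp_h4 > cfg.h4_cutoff
            } | {r.trait_b for r in coloc_results if r.pp_h4 > cfg.h4_cutoff}
            rows = []
            for q in mqtls:
                evid = []
                for gene, (chrom, gstart, gend) in gene_windows.items():
                    if chrom != q.chrom:
                        continue
                    dist = _genes.distance_to_gene(q.pos, gstart, gend)
                    if dist > 250_000:
                        continue
                    codes = {"h"} if dist == 0 else set()
                    if dist == 0 and f"{q.trait}[{q.matrix}]" in positive_traits:
                        codes |= {"E", "e"}
                    evid.append(_genes.GeneEvidence(gene, frozenset(codes), dist))
                if not evid:
                    continue
                winner, _ranked = _genes.score_genes(evid)
                winners.append(winner.gene)
                rows.append(
                    {"trait": q.trait, "matrix": q.matrix, "index_snp": q.index_snp,
                     "gene": winner.gene, "score": winner.score,
                     "deciding_rule": winner.deciding_rule}
                )
            pd.DataFrame(rows).to_csv(out / "genes.tsv", sep="\t", index=False)
            record(out / "genes.tsv")
            manifest["stages"]["prioritize"] = "complete"

        if "enrich" in cfg.stages and winners:
            current_stage = "enrich"
            universe = list(gene_windows)
            counts = _enrich.independent_snp_counts(panel, gene_windows=gene_windows)
            lengths = pd.Series(
                {g: w[2] - w[1] + 1 for g, w in gene_windows.items()}
            )
            strata = _enrich.MatchingStrata.from_annotations(
                counts, lengths, n_bins=2 if len(universe) < 50 else 10
            )
            anno = set(universe[: max(3, len(universe) // 4)])
            res = _enrich.matched_permutation_test(
                sorted(set(winners)), anno, universe, strata,
                n_draws=cfg.enrich_draws, seed=cfg.seed + 7,
            )
            odds, fisher_p = _enrich.fisher_overrep(
                len(set(winners)), len(anno), res["observed"], len(universe)
            )
            enr = pd.DataFrame(
                [{"set": "planted_blocks", "observed": res["observed"],
                  "expected": res["expected"], "fold": res["fold"],
                  "perm_p": res["p"], "fisher_p": fisher_p, "odds_ratio": odds}]
            )
            enr["bh_p"] = _enrich.bh_adjust(enr["perm_p"])
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            record(out / "enrichment.tsv")
            manifest["stages"]["enrich"] = "complete"

        if "ehh" in cfg.stages and panel.haplotypes is not None and mqtls:
            current_stage = "ehh"
            q = min(mqtls, key=lambda m: m.p)
            core = panel.snp_index(q.index_snp)
            pos = panel.snps["pos"].to_numpy()
            on_chrom = panel.snps["chrom"] == q.chrom
            hap = panel.haplotypes[:, on_chrom.to_numpy()]
            core_local = int(on_chrom.to_numpy()[:core].sum())
            try:
                derived, ancestral, ratio = _ehh.compare_alleles(
                    hap, pos[on_chrom.to_numpy()], core_local
                )
                pd.DataFrame(
                    {"pos": derived.positions, "ehh_derived": derived.ehh,
                     "ehh_ancestral": np.interp(
                         derived.positions, ancestral.positions, ancestral.ehh)}
                ).to_csv(out / "ehh.tsv", sep="\t", index=False)
                record(out / "ehh.tsv")
                manifest["ehh_area_ratio"] = ratio
                manifest["stages"]["ehh"] = "complete"
            except ValueError:
                manifest["stages"]["ehh"] = "skipped (insufficient carriers)"

        if "h2" in cfg.stages:
            current_stage = "h2"
            grm = _h2.compute_grm(panel)
            eig = grm.eigendecompose()
            rows = []
            for label, mat in matrices.items():
                design = _gwas.covariate_design(cov, label)
                for met in mat.columns:
                    res = _h2.reml_h2(mat[met], grm, design, eig=eig)
                    rows.append({"matrix": label, "metabolite": met,
                                 "h2": res.h2, "se": res.se, "n": res.n,
                                 "boundary": res.boundary})
            pd.DataFrame(rows).to_csv(out / "heritability.tsv", sep="\t", index=False)
            record(out / "heritability.tsv")
            manifest["stages"]["h2"] = "complete"

        manifest["stages"] = {s: manifest["stages"].get(s, "skipped") for s in _STAGES}
    except Exception as err:
        manifest["failed_stage"] = current_stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
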