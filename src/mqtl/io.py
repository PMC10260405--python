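"""Plain-text readers and writers shared by all pipeline stages.

All artifacts are diffable text: summary statistics, metabolite matrices,
truth tables and loci as TSV; genotypes as dosage TSV or VCF with a DS
FORMAT field; configuration as YAML.  VCF positions are 1-based; exported
BED intervals are 0-based half-open (start - 1, end), the inverse applied
on import.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import GenotypePanel

SUMMARY_COLUMNS = ["snp", "chrom", "pos", "ref", "alt", "eaf", "beta", "se", "p", "n"]


def write_summary_stats(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ("snp", "chrom", "pos", "beta", "se", "p") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: summary-stat columns missing: {missing}")
    return df


def write_metabolite_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Samples in rows, metabolites in columns, NaN as empty field."""
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_metabolite_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index.name = None
    return df


def write_dosage_tsv(panel: GenotypePanel, path: str | Path, seed: int | None = None) -> None:
    """SNP metadata + one dosage column per sample; seed in a header line."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        cols = ["snp", "chrom", "pos", "ref", "alt", "alt_freq", "imputation_quality"]
        fh.write("\t".join(cols + panel.sample_ids) + "\n")
        for i in range(panel.n_snps):
            meta = panel.snps.iloc[i]
            row = [str(meta[c]) for c in cols]
            row += [format(v, ".6g") for v in panel.dosages[:, i]]
            fh.write("\t".join(row) + "\n")


def read_dosage_tsv(path: str | Path) -> GenotypePanel:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    meta_cols = ["snp", "chrom", "pos", "ref", "alt", "alt_freq", "imputation_quality"]
    if header[: len(meta_cols)] != meta_cols:
        raise ValueError(f"{path}: unexpected dosage TSV header")
    sample_ids = header[len(meta_cols):]
    meta_rows, dose_rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
        meta_rows.append(parts[: len(meta_cols)])
        dose_rows.append([float(v) for v in parts[len(meta_cols):]])
    snps = pd.DataFrame(meta_rows, columns=meta_cols)
    snps["pos"] = snps["pos"].astype(int)
    snps["alt_freq"] = snps["alt_freq"].astype(float)
    snps["imputation_quality"] = snps["imputation_quality"].astype(float)
    dosages = np.asarray(dose_rows, float).T
    panel = GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)
    panel.validate()
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path, seed: int | None = None) -> None:
    """Write the panel as VCF 4.2 with GT (if phased) and DS FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##mqtl_seed={seed}\n")
        for chrom in dict.fromkeys(panel.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        has_gt = panel.haplotypes is not None
        fmt = "GT:DS" if has_gt else "DS"
        for i in range(panel.n_snps):
            m = panel.snps.iloc[i]
            info = f"AF={m['alt_freq']:.6g};R2={m['imputation_quality']:.6g}"
            fields = [str(m["chrom"]), str(m["pos"]), str(m["snp"]), str(m["ref"]),
                      str(m["alt"]), ".", "PASS", info, fmt]
            for s in range(panel.n_samples):
                ds = format(panel.dosages[s, i], ".6g")
                if has_gt:
                    gt = f"{panel.haplotypes[2 * s, i]}|{panel.haplotypes[2 * s + 1, i]}"
                    fields.append(f"{gt}:{ds}")
                else:
                    fields.append(ds)
            fh.write("\t".join(fields) + "\n")


def read_vcf_dosages(path: str | Path) -> GenotypePanel:
    """Read a VCF with DS (and optionally phased GT) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    meta, dose_cols, hap_cols = [], [], []
    any_gt = True
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"{path}: variant {var.ID} lacks DS field")
        dose_cols.append(np.asarray(ds, float).reshape(-1))
        info_r2 = var.INFO.get("R2")
        info_af = var.INFO.get("AF")
        meta.append(
            {
                "snp": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
                "alt_freq": float(info_af) if info_af is not None else np.nan,
                "imputation_quality": float(info_r2) if info_r2 is not None else 1.0,
            }
        )
        gts = var.genotypes  # [[a, b, phased], ...]
        if gts is None or any(g[0] < 0 or g[1] < 0 for g in gts):
            any_gt = False
        else:
            hap_cols.append(np.array([[g[0], g[1]] for g in gts], dtype=np.int8))
    snps = pd.DataFrame(meta)
    dosages = np.column_stack(dose_cols) if dose_cols else np.zeros((len(sample_ids), 0))
    haplotypes = None
    if any_gt and hap_cols:
        haplotypes = np.empty((2 * len(sample_ids), len(hap_cols)), dtype=np.int8)
        for i, col in enumerate(hap_cols):
            haplotypes[0::2, i] = col[:, 0]
            haplotypes[1::2, i] = col[:, 1]
        if not np.allclose(haplotypes[0::2] + haplotypes[1::2], dosages):
            haplotypes = None  # dosages are not GT-derived; keep DS as truth
    if np.isnan(snps["alt_freq"]).any():
        snps.loc[:, "alt_freq"] = dosages.mean(axis=0) / 2.0
    panel = GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages,
                          haplotypes=haplotypes)
    panel.validate()
    return panel


def write_bed_loci(mqtls: list, path: str | Path) -> None:
    """Loci as BED: 0-based half-open, name = trait|matrix|index SNP."""
    with open(path, "w") as fh:
        for q in mqtls:
            name = f"{q.trait}|{q.matrix}|{q.index_snp}"
            fh.write(f"{q.chrom}\t{q.start - 1}\t{q.end}\t{name}\t{q.p:.3g}\n")


def read_bed_loci(path: str | Path) -> pd.DataFrame:
    """BED loci back to 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED fields")
            trait, matrix, snp = parts[3].split("|")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                    "trait": trait,
                    "matrix": matrix,
                    "index_snp": snp,
                }
            )
    return pd.DataFrame(rows)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
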