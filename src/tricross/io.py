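"""Readers and writers for the pipeline's interchange formats.

VCF v4.2 with GT genotypes (1-based positions) for dosages; BED-like TSV
for gene TSS annotation (chrom, tss_pos 1-based, strand, gene_id);
genes x samples TSV for counts; sample-keyed TSV for phenotypes and
covariates; GMT for gene sets; TSV for truth tables and all stage
outputs. Floats are written at 6 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DosageMatrix:
    """Individuals x SNPs alternate-allele dosages with SNP metadata.

    Missing genotypes are encoded as -1 in ``dosages`` and flagged in
    ``missing``.
    """

    dosages: np.ndarray  # (n_ind, n_snps) int8, -1 = missing
    samples: list[str]
    snps: pd.DataFrame  # variant_id, chrom, pos, ref, alt

    @property
    def missing(self) -> np.ndarray:
        return self.dosages < 0


def write_vcf(path, snp_table: pd.DataFrame, sample_ids, haplotypes=None, dosages=None):
    """Write a minimal VCF v4.2. Phased GT from haplotypes when given,
    otherwise unphased GT reconstructed from dosages (0 -> 0/0, 1 -> 0/1,
    2 -> 1/1, negative -> ./.)."""
    if haplotypes is None and dosages is None:
        raise ValueError("need haplotypes or dosages")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j, row in enumerate(snp_table.itertuples(index=False)):
            if haplotypes is not None:
                gts = [f"{haplotypes[i, 0, j]}|{haplotypes[i, 1, j]}" for i in range(len(sample_ids))]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [code.get(int(d), "./.") for d in dosages[:, j]]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
    return path


def read_vcf_dosages(path) -> DosageMatrix:
    """Read GT dosages (alternate-allele counts) from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        gts = rec.genotype.array()
        d = gts[:, :2]
        miss = (d < 0).any(axis=1)
        dos = d.clip(min=0).sum(axis=1).astype(np.int8)
        dos[miss] = -1
        dosage_rows.append(dos)
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    snps = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    return DosageMatrix(np.array(dosage_rows, dtype=np.int8).T, samples, snps)


def write_counts(path, counts: pd.DataFrame):
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_annotation(path, gene_table: pd.DataFrame):
    """4-column BED-like TSV: chrom, tss (1-based), strand, gene_id."""
    gene_table[["chrom", "tss", "strand", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, df: pd.DataFrame, index: bool = True):
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene ids..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path, collection: dict[str, list[str]], descriptions=None):
    with Path(path).open("w") as fh:
        for name, genes in collection.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def write_cohort(cohort, outdir) -> dict[str, Path]:
    """Serialize a simulated cohort: VCFs, counts, annotation, phenotypes,
    truth tables. A round-trip read reproduces dosages and counts exactly."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["founders_vcf"] = write_vcf(
        out / "founders.vcf", cohort.snp_table, cohort.founders.sample_ids,
        haplotypes=cohort.founders.haplotypes,
    )
    paths["f2_vcf"] = write_vcf(
        out / "f2.vcf", cohort.snp_table, cohort.cross.f2_sample_ids,
        haplotypes=cohort.cross.f2_haplotypes,
    )
    for name, df in [
        ("f0_counts", cohort.f0_counts), ("f0rep_counts", cohort.f0rep_counts),
        ("f2_counts", cohort.f2_counts),
    ]:
        paths[name] = out / f"{name}.tsv"
        write_counts(paths[name], df)
    for name, df in [
        ("f0_pheno", cohort.f0_pheno), ("f0rep_pheno", cohort.f0rep_pheno),
        ("f2_pheno", cohort.f2_pheno),
    ]:
        paths[name] = out / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t")
    paths["annotation"] = out / "gene_annotation.tsv"
    write_annotation(paths["annotation"], cohort.gene_table)
    paths["truth_eqtls"] = out / "truth_eqtls.tsv"
    cohort.truth_eqtls.to_csv(paths["truth_eqtls"], sep="\t", index=False)
    paths["truth_qtls"] = out / "truth_qtls.tsv"
    cohort.truth_qtls.to_csv(paths["truth_qtls"], sep="\t", index=False)
    paths["truth_line_de"] = out / "truth_line_de.tsv"
    cohort.planted_line_de.to_csv(paths["truth_line_de"], sep="\t", index=False)
    return paths
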