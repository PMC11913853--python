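#!/usr/bin/env python
"""Simulate the default bHR/bLR cross and write the cohort to disk.

Produces two founder expression cohorts (10+10 each), 250 F2 animals with
genotypes, five behaviors, covariates and counts, and the truth tables of
every planted effect.
"""

import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from tricross import io  # noqa: E402

c = common.cohort()
paths = io.write_cohort(c, common.outdir("cohort"))

fx = (c.snp_table["category"] == "fixed_divergent").sum()
pa = (c.snp_table["category"] == "partially_segregated").sum()
print(f"genome: {c.params.genome.n_chrom} chromosomes, {len(c.snp_table)} SNPs, "
      f"{len(c.gene_table)} genes")
print(f"founder SNP architecture: {fx} fixed-divergent, {pa} partially segregated, "
      f"{len(c.snp_table) - fx - pa} shared-background")
print(f"planted: {len(c.planted_eqtls)} cis-eQTLs ({len(c.pleiotropic_genes)} pleiotropic), "
      f"{len(c.planted_qtls)} behavior QTL effects, {len(c.planted_line_de)} line-DE genes")
print(f"F2 cohort: n={len(c.cross.f2_sample_ids)}; behaviors: "
      f"{[b for b in c.f2_pheno.columns if b.startswith(('Loco', 'EPM', 'PavCA'))]}")
print(f"wrote {len(paths)} files under {common.RESULTS / 'cohort'}")
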