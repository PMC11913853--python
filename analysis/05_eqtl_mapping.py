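#!/usr/bin/env python
"""cis-eQTL mapping in the F2 cohort with permutation-based
beta-approximated p-values and conditional signals."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from tricross import eqtl, io, pipeline  # noqa: E402
from tricross.expression import F2_COVARIATES, build_design, filter_low_expression, log2_cpm, tmm_factors  # noqa: E402

c = common.cohort()
out = common.outdir("eqtl")

kept = filter_low_expression(c.f2_counts)
y = log2_cpm(kept, tmm_factors(kept))
tech = build_design(c.f2_pheno, None, F2_COVARIATES)
res = eqtl.map_cis_eqtls(y, tech, c.cross.f2_dosages, c.snp_table, c.gene_table,
                         n_perm=500, seed=pipeline.derive_seed(common.MASTER_SEED, "eqtl"))
io.write_table(out / "cis_eqtl.tsv", res, index=False)

top = res[res["rank"] == 0]
egenes = top[top["is_egene"]]
cond = res[res["rank"] > 0]
print(f"tested {len(top)} genes (windows of up to "
      f"{top['n_tested_snps'].max()} SNPs within +/-1 Mb of the TSS, MAF>0.01)")
print(f"eGenes at gene-level FDR<0.05: {len(egenes)}; "
      f"conditionally independent secondary signals: {len(cond)}")

planted = set(c.truth_eqtls["gene_id"])
recalled = planted & set(egenes["phenotype_id"])
print(f"planted eQTL genes recalled as eGenes: {len(recalled)}/{len(planted)}")
print(f"median |t| at the top eVariant of eGenes: {egenes['t'].abs().median():.1f}")
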