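#!/usr/bin/env python
"""Differential expression: line contrast in both founder cohorts and the
five F2 behavioral models, with PCA covariate diagnostics."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from tricross import io, sim  # noqa: E402
from tricross.expression import filter_low_expression, log2_cpm, pca_diagnostics, run_de, tmm_factors  # noqa: E402

c = common.cohort()
out = common.outdir("de")

f0 = run_de(c.f0_counts, c.f0_pheno, "f0_lineage")
f0rep = run_de(c.f0rep_counts, c.f0rep_pheno, "f0_lineage")
io.write_table(out / "de_f0.tsv", f0)
io.write_table(out / "de_f0_replication.tsv", f0rep)
print(f"F0 line contrast: {f0.attrs['n_genes_tested']}/{f0.attrs['n_genes_input']} genes "
      f"tested after low-expression filtering; EB prior d0={f0.attrs['d0']:.1f}")
print(f"  genes at FDR<0.10: F0 {int((f0['q'] < 0.1).sum())}, "
      f"replication {int((f0rep['q'] < 0.1).sum())}")

for b in sim.ADULT_BEHAVIORS:
    de = run_de(c.f2_counts, c.f2_pheno, "f2_behavior", behavior=b)
    io.write_table(out / f"de_f2_{b}.tsv", de)
    print(f"F2 ~ {b}: {int((de['p'] < 0.05).sum())} genes at nominal p<0.05, "
          f"{int((de['q'] < 0.1).sum())} at FDR<0.10")

kept = filter_low_expression(c.f2_counts)
y = log2_cpm(kept, tmm_factors(kept))
diag = pca_diagnostics(y, c.f2_pheno[["Sex", "pct_rRNA", "pct_Intergenic", "Dissector",
                                      "STGT_Experience", "SequencingBatch"]])
io.write_table(out / "pca_covariate_correlations.tsv", diag)
print("top-PC |r| per covariate:")
print(diag.max(axis=1).round(2).to_string())
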