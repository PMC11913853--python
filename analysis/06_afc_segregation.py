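#!/usr/bin/env python
"""Allelic fold change of eGenes, founder-line segregation of their
eVariants (G'st), and genotype-based prediction of line differential
expression."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

import numpy as np  # noqa: E402

from tricross import io, pipeline  # noqa: E402

res = pipeline.run_pipeline(pipeline.RunConfig(seed=common.MASTER_SEED))
out = common.outdir("afc_segregation")
io.write_table(out / "afc.tsv", res.afc_records, index=False)
io.write_table(out / "segregation.tsv", res.segregation)
io.write_table(out / "predictions.tsv", res.predictions)

seg = res.segregation
n_seg = int((seg["gst_prime"] > 0.27).sum())
print(f"aFC estimated for {len(res.afc_records)} eGene/eVariant pairs "
      f"({int(res.afc_records['capped'].sum())} at the |log2|<=6.64 cap)")
print(f"eVariants with founder G'st > 0.27: {n_seg}/{len(seg)}")
print(f"signed aFC predictions (bLR-vs-bHR axis): {len(res.predictions)}")

truth = res.cohort.truth_eqtls.set_index("gene_id")
shared = res.predictions.index.intersection(truth.index)
est = res.afc_records.set_index("gene_id")
both = est.index.intersection(truth.index)
r = np.corrcoef(est.loc[both, "afc"].abs(), truth.loc[both, "true_afc"].abs())[0, 1]
print(f"|aFC| estimate vs planted truth over {len(both)} genes: r={r:.2f}")
if res.prediction_stats:
    s = res.prediction_stats
    print(f"prediction vs observed F0 Log2FC: r={s['r']:.2f}, rho={s['rho']:.2f}, "
          f"sign concordance {100 * s['sign_concordance']:.0f}% (n={s['n']})")
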