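#!/usr/bin/env python
"""Cross-dataset concordance, the two-dataset DEG rule, behavior flags,
and overlap enrichment of line DEGs with behavior-associated genes."""

import importlib.util
from pathlib import Path

spec = importlib.util.spec_from_file_location("common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from tricross import concordance as cc, io, sim  # noqa: E402
from tricross.expression import run_de  # noqa: E402

c = common.cohort()
out = common.outdir("concordance")

f0 = run_de(c.f0_counts, c.f0_pheno, "f0_lineage")
f0rep = run_de(c.f0rep_counts, c.f0rep_pheno, "f0_lineage")
f2 = {b: run_de(c.f2_counts, c.f2_pheno, "f2_behavior", behavior=b)
      for b in sim.ADULT_BEHAVIORS}

stats = cc.log2fc_concordance(f0, f0rep)
print(f"F0 vs replication Log2FC: r={stats['r']:.2f}, rho={stats['rho']:.2f} "
      f"(n={stats['n_shared_genes']} genes)")

rrho = cc.rrho_map(f0["mod_t"], f0rep["mod_t"])
io.write_table(out / "rrho_f0_vs_replication.tsv", rrho)
print(f"RRHO map: peak signed -log10 p = {rrho.values.max():.1f} "
      f"(concordant signal on the diagonal)")

deg = cc.define_deg_set(f0, f0rep)
flags = cc.behavior_concordance_flags(deg, f2)
io.write_table(out / "deg_set.tsv", deg.join(flags))
print(f"DEG set: {len(deg)} genes "
      f"({(deg['provenance'] == 'nominal_both_consistent').sum()} by nominal replication)")
print(f"behavior-concordant flags: {(flags == 'bLR_like').sum()} bLR-like, "
      f"{(flags == 'bHR_like').sum()} bHR-like")

# enrichment of bLR-up DEGs for bLR-like behavioral associations
universe = f0.index.intersection(next(iter(f2.values())).index)
blr_up = set(deg.index[deg["direction"] > 0]) & set(universe)
blr_flagged = set(flags.index[flags == "bLR_like"]) & set(universe)
behav_assoc = set()
for b, de in f2.items():
    mult = cc.DEFAULT_SIGN_CONVENTION[b]
    hits = de.index[(de["p"] < 0.05) & (mult * de["log2fc"] > 0)]
    behav_assoc |= set(hits)
enr = cc.overlap_enrichment(blr_up, behav_assoc & set(universe), universe)
print(f"bLR-up DEGs x bLR-like behavioral associations: OR={enr.odds_ratio:.2f} "
      f"(95% CI {enr.ci_low:.2f}-{enr.ci_high:.2f}), Fisher p={enr.p:.2g}")
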