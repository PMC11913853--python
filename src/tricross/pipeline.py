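"""End-to-end orchestration of the triangulation pipeline.

``run_pipeline`` chains every stage on a synthetic cohort: simulation,
differential expression (line contrast, replication, five F2 behaviors),
the two-dataset DEG rule and behavior-concordance flags, optional GSEA,
cis-eQTL mapping, allelic fold change + founder segregation + signed
predictions, the stand-in behavioral GWAS, SMR colocalization, the
six-criterion convergence gate, and its evaluation against the planted
truth. Every stochastic stage draws its seed deterministically from the
master seed and stage name; rerunning a config bit-reproduces all
outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tricross import afc as afc_mod
from tricross import concordance as conc
from tricross import eqtl as eqtl_mod
from tricross import gsea as gsea_mod
from tricross import io
from tricross import sim
from tricross import smr as smr_mod
from tricross.expression import F2_COVARIATES, build_design, run_de


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    crc = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return int(np.random.SeedSequence([master_seed, crc]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """All thresholds and toggles of the pipeline, with study defaults."""

    seed: int = 0
    cohort: sim.CohortParams = field(default_factory=sim.CohortParams)
    filter_fraction: float = 0.75
    nominal_p: float = 0.05
    deg_fdr: float = 0.10
    egene_fdr: float = 0.05
    smr_fdr: float = 0.10
    gst_threshold: float = 0.27
    cis_window_bp: int = 1_000_000
    maf_threshold: float = 0.01
    n_perm_eqtl: int = 500
    n_pcs: int = 5
    run_gsea: bool = False
    nperm_gsea: int = 1000
    run_conditional: bool = True
    chance_permutations: int = 0  # 0 = skip the chance-expectation stage
    outdir: str | None = None

    def to_dict(self):
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: sim.SimulatedCohort
    f0_de: pd.DataFrame
    f0rep_de: pd.DataFrame
    f2_de: dict[str, pd.DataFrame]
    deg_set: pd.DataFrame
    behavior_flags: pd.Series
    concordance_f0_rep: dict
    eqtl: pd.DataFrame
    afc_records: pd.DataFrame
    segregation: pd.DataFrame
    predictions: pd.DataFrame
    prediction_stats: dict | None
    gwas: dict[str, pd.DataFrame]
    smr: pd.DataFrame
    directional: dict | None
    gate: pd.DataFrame
    evaluation: dict
    gsea: pd.DataFrame | None = None
    chance: dict | None = None
    manifest: dict | None = None


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()
    cohort = sim.simulate_cohort(config.cohort, seed=derive_seed(config.seed, "simulate"))

    # --- differential expression -----------------------------------------
    f0_de = run_de(cohort.f0_counts, cohort.f0_pheno, "f0_lineage",
                   filter_fraction=config.filter_fraction)
    f0rep_de = run_de(cohort.f0rep_counts, cohort.f0rep_pheno, "f0_lineage",
                      filter_fraction=config.filter_fraction)
    f2_de = {
        b: run_de(cohort.f2_counts, cohort.f2_pheno, "f2_behavior", behavior=b,
                  filter_fraction=config.filter_fraction)
        for b in sim.ADULT_BEHAVIORS
    }

    # --- concordance + DEG definition ------------------------------------
    deg_set = conc.define_deg_set(f0_de, f0rep_de, fdr=config.deg_fdr, nominal=config.nominal_p)
    flags = conc.behavior_concordance_flags(deg_set, f2_de, nominal=config.nominal_p)
    conc_stats = conc.log2fc_concordance(f0_de, f0rep_de)

    gsea_res = None
    if config.run_gsea:
        stat = gsea_mod.combined_statistic({"f0_lineage": f0_de, "f0_replication": f0rep_de,
                                            **{b: f2_de[b] for b in sim.ADULT_BEHAVIORS}})
        collection = _truth_gene_sets(cohort, stat.index)
        gsea_res = gsea_mod.gsea_test(stat, collection, nperm=config.nperm_gsea,
                                      seed=derive_seed(config.seed, "gsea"))

    # --- cis-eQTL mapping --------------------------------------------------
    from tricross.expression import filter_low_expression, log2_cpm, tmm_factors

    kept = filter_low_expression(cohort.f2_counts, fraction=config.filter_fraction)
    factors = tmm_factors(kept)
    y = log2_cpm(kept, factors)
    tech = build_design(cohort.f2_pheno.loc[kept.columns], None, F2_COVARIATES)
    eqtl_res = eqtl_mod.map_cis_eqtls(
        y, tech, cohort.cross.f2_dosages, cohort.snp_table, cohort.gene_table,
        maf_threshold=config.maf_threshold, window_bp=config.cis_window_bp,
        n_pcs=config.n_pcs, n_perm=config.n_perm_eqtl, alpha=config.egene_fdr,
        seed=derive_seed(config.seed, "eqtl"), conditional=config.run_conditional,
    )
    top = eqtl_res[eqtl_res["rank"] == 0].copy()
    egenes = top[top["is_egene"]]

    # --- aFC + segregation + signed predictions ---------------------------
    vindex = pd.Index(cohort.snp_table["variant_id"])
    D = cohort.cross.f2_dosages
    # same covariates as the eQTL scan: technical design plus the PCs
    snp_maf = eqtl_mod.maf(D)
    poly = snp_maf > config.maf_threshold
    E_res = eqtl_mod.residualize(y, tech)
    E_rint = np.vstack([eqtl_mod.rint(E_res.iloc[g].values) for g in range(len(E_res))])
    pruned = eqtl_mod.ld_prune(D[:, poly])
    pcs = eqtl_mod.compute_pc_covariates(E_rint, D[:, poly][:, pruned], n_pcs=config.n_pcs)
    afc_design = np.hstack([np.asarray(tech, float), pcs])

    afc_rows = []
    for _, row in egenes.iterrows():
        gid, v = row["phenotype_id"], row["variant_id"]
        rec = afc_mod.estimate_afc(
            cohort.f2_counts.loc[gid].values, D[:, vindex.get_loc(v)], afc_design,
            gene_id=gid, variant_id=v,
        )
        afc_rows.append({"gene_id": gid, "variant_id": v, "afc": rec.afc,
                         "c_ref": rec.c_ref, "capped": rec.capped, "flagged": rec.flagged})
    afc_records = pd.DataFrame(afc_rows)

    if len(egenes):
        freqs = afc_mod.founder_allele_freqs(
            cohort.founders.dosages, cohort.founders.line, cohort.snp_table,
            list(dict.fromkeys(egenes["variant_id"])),
        )
        segregation = afc_mod.segregation_records(freqs)
    else:
        segregation = pd.DataFrame(columns=["p_bHR", "p_bLR", "gst_prime", "blr_enriched_allele"])

    pred_rows = []
    for _, row in afc_records.iterrows():
        seg = segregation.loc[row["variant_id"]]
        if seg["gst_prime"] <= config.gst_threshold:
            continue
        pred = afc_mod.signed_prediction(row["afc"], seg["p_bHR"], seg["p_bLR"])
        if pred is None:
            continue
        pred_rows.append({"gene_id": row["gene_id"], "variant_id": row["variant_id"],
                          "predicted_log2fc": pred})
    predictions = pd.DataFrame(pred_rows).set_index("gene_id") if pred_rows else pd.DataFrame(
        columns=["variant_id", "predicted_log2fc"]
    )
    pred_stats = None
    if len(predictions) >= 10:
        pred_stats = afc_mod.prediction_concordance(predictions, f0_de)

    # --- stand-in GWAS + SMR ----------------------------------------------
    sex_cov = (cohort.f2_pheno["Sex"] == "F").astype(float).values
    gwas = {}
    for b in sim.ADULT_BEHAVIORS:
        g = smr_mod.behavior_qtl_scan(cohort.f2_pheno[b].values, D, covariates=sex_cov)
        g.index = vindex
        gwas[b] = g
    smr_res = smr_mod.run_smr(egenes, gwas) if len(egenes) else pd.DataFrame(
        columns=["gene_id", "variant_id", "behavior", "T", "p", "q", "signed_T"]
    )

    directional = None
    validated = predictions.index[
        predictions.index.isin(f0_de.index)
        & (np.sign(predictions["predicted_log2fc"].values)
           == np.sign(f0_de["log2fc"].reindex(predictions.index).values))
    ]
    if len(smr_res):
        try:
            directional = smr_mod.directional_concordance(
                smr_res, f2_de["LocoScore"], "LocoScore", subset_genes=validated
            )
            directional.pop("table", None)
        except ValueError:
            directional = None

    # --- convergence gate + evaluation -------------------------------------
    if len(egenes) and len(smr_res):
        gate = smr_mod.convergence_gate(
            deg_set, flags, top, segregation, predictions, f0_de, smr_res, f2_de,
            smr_fdr_threshold=config.smr_fdr, gst_threshold=config.gst_threshold,
        )
    else:
        gate = pd.DataFrame(columns=smr_mod.GATE_CRITERIA + ["pass"])
    evaluation = evaluate_gate(gate, cohort)

    chance = None
    if config.chance_permutations > 0 and len(gate):
        chance = smr_mod.chance_expectation(
            deg_set, flags, top, segregation, predictions, f0_de, smr_res, f2_de,
            n_permutations=config.chance_permutations,
            seed=derive_seed(config.seed, "chance"),
            smr_fdr_threshold=config.smr_fdr, gst_threshold=config.gst_threshold,
        )
        chance = {k: chance[k] for k in ("mean_passes", "q95_passes")}

    result = PipelineResult(
        config, cohort, f0_de, f0rep_de, f2_de, deg_set, flags, conc_stats,
        eqtl_res, afc_records, segregation, predictions, pred_stats, gwas, smr_res,
        directional, gate, evaluation, gsea=gsea_res, chance=chance,
    )
    result.manifest = _build_manifest(result)
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def evaluate_gate(gate: pd.DataFrame, cohort: sim.SimulatedCohort) -> dict:
    """Recall and precision of the pass list against the planted
    pleiotropic genes."""
    truth = set(cohort.pleiotropic_genes)
    passed = set(gate.index[gate["pass"]]) if len(gate) else set()
    recall = len(passed & truth) / len(truth) if truth else np.nan
    precision = len(passed & truth) / len(passed) if passed else np.nan
    return {
        "n_planted_pleiotropic": len(truth),
        "n_passed": len(passed),
        "recall": recall,
        "precision": precision,
        "passed_genes": sorted(passed),
    }


def _truth_gene_sets(cohort, universe) -> dict[str, list[str]]:
    """Desk-scale gene-set collection built from the planted architecture
    (a stand-in for an external GMT database)."""
    rng = np.random.default_rng(derive_seed(cohort.seed, "gene_sets"))
    uni = list(universe)
    sets = {
        "planted_line_de": cohort.planted_line_de["gene_id"].tolist(),
        "planted_eqtl_genes": cohort.truth_eqtls["gene_id"].tolist(),
        "planted_pleiotropic": cohort.pleiotropic_genes,
    }
    for i in range(10):
        sets[f"random_{i}"] = list(rng.choice(uni, size=30, replace=False))
    return sets


def _build_manifest(result: PipelineResult) -> dict:
    cfg = result.config
    return {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in
                        ("simulate", "eqtl", "gsea", "chance")},
        "n_genes": len(result.cohort.gene_table),
        "n_snps": len(result.cohort.snp_table),
        "n_f2": result.cohort.params.n_f2,
        "n_genes_tested_f0": int(result.f0_de.attrs["n_genes_tested"]),
        "n_degs": int(len(result.deg_set)),
        "n_egenes": int(result.eqtl[result.eqtl["rank"] == 0]["is_egene"].sum())
        if len(result.eqtl) else 0,
        "n_eqtl_signals": int(len(result.eqtl)),
        "n_segregated": int((result.segregation["gst_prime"] > cfg.gst_threshold).sum())
        if len(result.segregation) else 0,
        "n_predictions": int(len(result.predictions)),
        "n_smr_records": int(len(result.smr)),
        "n_gate_pass": int(result.gate["pass"].sum()) if len(result.gate) else 0,
        "evaluation": {k: v for k, v in result.evaluation.items() if k != "passed_genes"},
    }


def _write_outputs(result: PipelineResult, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_cohort(result.cohort, outdir / "cohort")
    io.write_table(outdir / "de_f0.tsv", result.f0_de)
    io.write_table(outdir / "de_f0_replication.tsv", result.f0rep_de)
    for b, de in result.f2_de.items():
        io.write_table(outdir / f"de_f2_{b}.tsv", de)
    io.write_table(outdir / "deg_set.tsv", result.deg_set.join(result.behavior_flags))
    io.write_table(outdir / "eqtl.tsv", result.eqtl, index=False)
    io.write_table(outdir / "afc.tsv", result.afc_records, index=False)
    io.write_table(outdir / "segregation.tsv", result.segregation)
    io.write_table(outdir / "predictions.tsv", result.predictions)
    io.write_table(outdir / "smr.tsv", result.smr, index=False)
    io.write_table(outdir / "candidate_ledger.tsv", result.gate)
    if result.gsea is not None:
        io.write_table(outdir / "gsea.tsv", result.gsea)
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
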