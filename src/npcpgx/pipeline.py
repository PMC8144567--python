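"""End-to-end synthetic demonstration: simulate -> fit -> synergy ->
variants -> differential expression -> signature -> score -> ROC.

``run_demo`` ties every stage together on synthetic data and emits a JSON
report containing the acceptance-relevant statistics (cohort composition,
mutation burden, synergy calls, signature size, AUCs) together with the
configuration used, so any number in the report is auditable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import diffexpr, dose_response, io, scoring, simulate, synergy, variants
from .config import PipelineConfig

log = logging.getLogger("npcpgx")


def _synergy_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    """Mono + combo CRT screens for three drug-IR pairs of varying synergy."""
    seed = cfg.stage_seed("synergy")
    pairs = [
        # (sample, drug, true ic50, synergy offset)
        ("PDO_EC_1", "egfr_inhibitor", 2.0, 0.25),
        ("PDO_EC_2", "egfr_inhibitor", 5.0, 0.15),
        ("PDO_SC_1", "mt_inhibitor", 0.5, 0.0),
    ]
    ir_truth = simulate.DoseResponseTruth(ic50=6.0, hill=1.2)  # Gy scale
    ir_plate = simulate.gen_dose_response(
        ir_truth, doses=(2.0, 4.0, 6.0, 8.0, 10.0), n_reps=6,
        noise_sd=cfg.noise_sd, seed=seed, sample="PDO_EC_1", drug="IR",
    ).rename(columns={"dose_uM": "dose_gy"})
    zero_gy = pd.DataFrame(
        {
            "sample": "PDO_EC_1", "drug": "IR", "dose_gy": 0.0, "ir_gy": 0.0,
            "replicate": list(range(1, 7)), "viability_pct": 100.0,
        }
    )
    ir_profile = dose_response.ir_survival(
        pd.concat([zero_gy, ir_plate], ignore_index=True)
    )
    e1 = dose_response.ir_inhibition_at(ir_profile, cfg.ir_dose_gy)

    rows, plates = [], []
    for i, (sample, drug, ic50, offset) in enumerate(pairs):
        truth = simulate.DoseResponseTruth(ic50=ic50)
        mono = simulate.gen_dose_response(
            truth, doses=cfg.doses_uM, n_reps=cfg.n_reps,
            noise_sd=cfg.noise_sd, seed=seed + 10 * i + 1,
            sample=sample, drug=drug, ir_gy=0.0,
        )
        combo = simulate.gen_combo_screen(
            truth, ir_inhibition_at_4gy=e1, synergy_offset=offset,
            doses=cfg.doses_uM, n_reps=cfg.n_reps, noise_sd=cfg.noise_sd,
            seed=seed + 10 * i + 2, sample=sample, drug=drug,
            ir_gy=cfg.ir_dose_gy,
        )
        plates += [mono, combo]
        est_mono = dose_response.ic50_with_proxy(dose_response.fit_plate(mono))
        est_combo = dose_response.ic50_with_proxy(dose_response.fit_plate(combo))
        call = synergy.call_pair(
            mono, combo, e1, est_mono, est_combo,
            tol=cfg.synergy_tol, min_points=cfg.synergy_min_points,
        )
        rows.append(
            {
                "sample": sample,
                "drug": drug,
                "true_ic50": ic50,
                "true_offset": offset,
                "ic50_mono": est_mono.value,
                "ic50_combo": est_combo.value,
                "verdict": call.verdict,
                "fold_change": call.fold_change,
                "good_combination": call.good_combination,
            }
        )
    calls = pd.DataFrame(rows)
    io.write_plate_csv(pd.concat(plates, ignore_index=True), outdir / "plates.csv")
    calls.to_csv(outdir / "synergy_calls.csv", index=False)
    return {
        "ir_inhibition_at_4gy": e1,
        "calls": calls.to_dict(orient="records"),
        "n_synergistic": int((calls["verdict"] == "synergistic").sum()),
    }


def _variant_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    seed = cfg.stage_seed("variants")
    sample_ids = [f"T{i}" for i in range(1, 9)]
    callsets, truth, lookup = simulate.gen_caller_callsets(
        n_true=120, fp_per_caller=(12, 12, 12), seed=seed, samples=sample_ids
    )
    for name, df in callsets.items():
        io.write_callset_tsv(df, outdir / f"calls_{name}.tsv")
    consensus = variants.merge_callers(callsets, min_callers=cfg.min_callers)
    fcfg = variants.FilterConfig(
        max_pop_af=cfg.max_pop_af, min_t_depth=cfg.min_t_depth,
        min_t_alt=cfg.min_t_alt, max_n_alt=cfg.max_n_alt, min_vaf=cfg.min_vaf,
        min_callers=cfg.min_callers,
    )
    filtered, rejected = variants.apply_filters(consensus, fcfg)
    io.write_callset_tsv(filtered, outdir / "consensus_filtered.tsv")
    burden = variants.burden_summary(filtered, sample_ids)
    catalog = variants.trinucleotide_contexts(filtered, lookup)
    reference = variants.load_reference_signatures()
    fit = variants.refit_signatures(catalog, reference)
    true_keys = set(map(tuple, truth.loc[truth.is_true, ["chrom", "pos"]].values))
    cons_keys = set(map(tuple, consensus[["chrom", "pos"]].values))
    precision = (
        len(cons_keys & true_keys) / len(cons_keys) if cons_keys else float("nan")
    )
    return {
        "n_consensus": len(consensus),
        "n_filtered": len(filtered),
        "n_rejected": len(rejected),
        "consensus_precision": precision,
        "burden": burden,
        "signature_exposures": fit.weights.to_dict(),
        "signature_cosine": fit.cosine,
    }


def _expression_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    seed = cfg.stage_seed("expression")
    genes = [f"G{i:05d}" for i in range(2000)]
    pathway_names = [
        "apoptotic_signaling", "microtubule", "mitotic_cell_cycle",
        "androgen_response", "tnfa_via_nfkb",
    ]
    # five disjoint 21-gene pathway blocks -> 105 signature genes
    pathway_sets = {
        name: genes[21 * i: 21 * (i + 1)] for i, name in enumerate(pathway_names)
    }
    counts, meta, truth = simulate.gen_expression(
        n_genes=2000, n_samples=40, signature_sets=pathway_sets,
        group_log2fc=3.0, dispersion=(0.02, 0.1), seed=seed,
    )
    counts.to_csv(outdir / "expression_counts.tsv", sep="\t")
    meta.to_csv(outdir / "expression_meta.csv")
    io.write_gmt(pathway_sets, outdir / "pathways.gmt")

    counts_nz = diffexpr.drop_all_zero_genes(counts)
    _, norm = diffexpr.normalize_counts(counts_nz)
    res_a = diffexpr.de_test(norm, meta["group"], method="A")
    res_b = diffexpr.de_test(norm, meta["group"], method="B")
    res_a.to_csv(outdir / "de_method_a.csv")
    res_b.to_csv(outdir / "de_method_b.csv")
    sig = diffexpr.overlap_filter(
        res_a, res_b, min_abs_log2fc=cfg.min_abs_log2fc,
        max_p=cfg.max_p, max_padj=cfg.max_padj,
    )
    signature = diffexpr.assemble_pathway_signature(sig, pathway_sets)
    io.write_gmt({k: v for k, v in signature.items() if v},
                 outdir / "signature.gmt")

    scores = scoring.score_genesets(
        norm, {k: v for k, v in signature.items() if len(v) >= 2},
        alpha=cfg.ssgsea_alpha,
    )
    scores.to_csv(outdir / "ssgsea_scores.csv")
    labels = scoring.label_by_ic50(meta["ic50_uM"], q=cfg.label_quantile)
    labels.to_csv(outdir / "labels.csv")
    roc = scoring.roc_auc(scores["combined"], labels)
    pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
        outdir / "roc_points.csv", index=False
    )
    null = scoring.random_signature_null(
        norm, labels, n_genes=cfg.null_n_genes, n_iter=cfg.null_n_iter,
        seed=cfg.stage_seed("null"), alpha=cfg.ssgsea_alpha,
    )
    corr = scoring.score_response_correlation(scores, labels)
    corr.to_csv(outdir / "score_response_correlation.csv", index=False)
    return {
        "n_de_overlap": len(sig),
        "signature_sizes": {k: len(v) for k, v in signature.items()},
        "combined_auc": roc.auc,
        "null_mean_auc": null["mean_auc"],
        "null_sd_auc": null["sd_auc"],
        "n_labeled": int((labels != "unlabeled").sum()),
    }


def run_demo(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic pipeline; returns (and writes) the report."""
    cfg = config or PipelineConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("demo start: seed=%d outdir=%s", cfg.seed, outdir)

    cohort = simulate.gen_cohort(
        cfg.n_patients, cfg.subtype_fractions, seed=cfg.stage_seed("cohort")
    )
    cohort.to_csv(outdir / "cohort.csv", index=False)
    report = {
        "config": cfg.to_dict(),
        "cohort": simulate.cohort_report(cohort),
    }
    for name, stage in (
        ("synergy", _synergy_stage),
        ("variants", _variant_stage),
        ("expression", _expression_stage),
    ):
        log.info("stage %s", name)
        try:
            report[name] = stage(cfg, outdir)
        except Exception:
            log.exception("stage %s failed", name)
            raise
    io.write_json_report(report, outdir / "report.json")
    log.info("demo complete")
    return report
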