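"""End-to-end orchestration: QC -> harmonize -> score -> PCA/TW -> association.

`run_pipeline` executes the full replication workflow for a set of scoring
files against one genotype panel and phenotype table, writing per-score
harmonization audits and PRS tables, per-model association reports
(Bonferroni-corrected across scores), and a JSON run log with the seeds,
thresholds and entity counts at every stage.  Any stage's hard failure
raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import prscad
from prscad import association, data_io, harmonize, qc, scoring, structure_pca, synthetic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    panel_path: str
    phenotype_path: str
    score_paths: list[str]
    out_dir: str
    ld_path: str | None = None
    sample_call_rate: float = 0.95
    het_k_sd: float = 3.0
    variant_call_rate: float = 0.98
    hwe_alpha: float = 1e-4
    r2_min: float = 0.8
    proxy_window_bp: int = 500_000
    palindromic_policy: str = "drop"
    missing_policy: str = "mean"
    models: tuple[str, ...] = ("model1", "model2")
    pc_policy: str = "tw"        # "tw" (Tracy-Widom count, capped) or "fixed15"
    k_max: int = 20
    tw_alpha: float = 0.05
    pc_cap: int = 15
    or_scale: str = "per_sd"
    bonferroni_alpha: float = 0.05
    seed: int = 0


def _load_ld_pairs(path) -> dict:
    pairs = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            ca, pa, cb, pb, r2 = line.rstrip("\n").split("\t")
            pairs[((ca, int(pa)), (cb, int(pb)))] = float(r2)
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the run log (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": prscad.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": [],
    }

    # ---- data_io ----------------------------------------------------------
    try:
        panel = data_io.read_genotypes_vcf(config.panel_path)
        phenotypes = data_io.read_phenotypes(config.phenotype_path,
                                             panel_sample_ids=panel.sample_ids)
        scoresets = [data_io.read_score_file(p) for p in config.score_paths]
    except Exception as exc:
        raise PipelineError("data_io", str(exc)) from exc
    log["stages"].append({"stage": "data_io", "n_samples": panel.n_samples,
                          "n_variants": panel.n_variants,
                          "n_scores": len(scoresets)})

    # ---- qc ---------------------------------------------------------------
    try:
        panel, sreport = qc.sample_qc(panel, call_rate_min=config.sample_call_rate,
                                      het_k_sd=config.het_k_sd)
        panel, vreport = qc.variant_qc(panel, hwe_alpha=config.hwe_alpha,
                                       call_rate_min=config.variant_call_rate)
        sreport.variants_removed = vreport.variants_removed
        sreport.thresholds_used.update(vreport.thresholds_used)
        sreport.to_tsv(out / "qc_report.tsv")
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc
    log["stages"].append({"stage": "qc",
                          "n_samples_removed": len(sreport.samples_removed),
                          "n_variants_removed": len(sreport.variants_removed),
                          "n_samples": panel.n_samples,
                          "n_variants": panel.n_variants})

    # ---- pca / Tracy-Widom ------------------------------------------------
    try:
        pcres = structure_pca.pca_with_tw(panel, k_max=config.k_max,
                                          alpha=config.tw_alpha, k_cap=config.pc_cap)
        n_pcs = config.pc_cap if config.pc_policy == "fixed15" else pcres.n_significant
        n_pcs = min(n_pcs, pcres.pc_coords.shape[1])
        pcres.coords_tsv(panel.sample_ids, out / "pc_coords.tsv")
        with open(out / "tw_report.tsv", "w") as fh:
            fh.write("component\teigenvalue\ttw_stat\n")
            for j, (ev, tw) in enumerate(zip(pcres.eigenvalues, pcres.tw_stats)):
                fh.write(f"{j+1}\t{ev!r}\t{tw!r}\n")
    except Exception as exc:
        raise PipelineError("structure_pca", str(exc)) from exc
    log["stages"].append({"stage": "structure_pca",
                          "tw_selected": pcres.n_significant,
                          "n_pcs_used": int(n_pcs)})

    # ---- harmonize / score / associate ------------------------------------
    ld_ref = None
    if config.ld_path is not None:
        ld_ref = harmonize.LDReference(panel=panel,
                                       pairs=_load_ld_pairs(config.ld_path),
                                       window_bp=config.proxy_window_bp)
    results: dict[str, list[association.AssociationResult]] = {m: [] for m in config.models}
    for scoreset in scoresets:
        try:
            hs = harmonize.harmonize_scoreset(
                scoreset, panel, ld_ref=ld_ref, r2_min=config.r2_min,
                window_bp=config.proxy_window_bp,
                palindromic_policy=config.palindromic_policy)
            hs.to_tsv(out / f"harmonize_{scoreset.pgs_id}.tsv")
        except Exception as exc:
            raise PipelineError("harmonize", f"{scoreset.pgs_id}: {exc}") from exc
        try:
            prs = scoring.compute_prs(hs, panel, missing_policy=config.missing_policy)
            prs = scoring.standardize_prs(prs)
            prs.to_tsv(out / f"prs_{scoreset.pgs_id}.tsv")
        except Exception as exc:
            raise PipelineError("scoring", f"{scoreset.pgs_id}: {exc}") from exc
        try:
            for model in config.models:
                spec = association.ModelSpec(name=model, n_pcs=int(n_pcs))
                res = association.evaluate_prs(prs, phenotypes, pcres.pc_coords,
                                               spec, or_scale=config.or_scale)
                results[model].append(res)
        except Exception as exc:
            raise PipelineError("association", f"{scoreset.pgs_id}: {exc}") from exc
        log["stages"].append({"stage": "harmonize+score",
                              "pgs_id": scoreset.pgs_id,
                              "actions": hs.action_counts(),
                              "n_used": hs.n_used, "n_dropped": hs.n_dropped})

    # ---- bonferroni + reports ---------------------------------------------
    try:
        for model, rows in results.items():
            flags, threshold = association.bonferroni_adjust(
                [r.p_value for r in rows], alpha=config.bonferroni_alpha)
            for r, f in zip(rows, flags):
                r.bonferroni_significant = bool(f)
            data_io.write_report(rows, out / f"report_{model}.tsv")
            log["stages"].append({"stage": "report", "model": model,
                                  "bonferroni_threshold": threshold,
                                  "n_significant": int(flags.sum())})
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    log["results"] = results
    return log


# ---------------------------------------------------------------------------
# Dataset emission (used by the `simulate` subcommand and tests)
# ---------------------------------------------------------------------------

def simulate_dataset(out_dir, config: synthetic.SimulationConfig,
                     n_scores: int = 9, corruption: dict | None = None) -> dict:
    """Write a complete synthetic dataset: VCF panel, phenotypes, one planted
    (optionally corrupted) scoring file plus ``n_scores - 1`` null scoring
    files, and a ground-truth ledger JSON.  Returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, truth = synthetic.simulate_panel(config)
    _, planted_panel = synthetic.emit_score_file(
        truth, panel, corruption=corruption, seed=config.seed + 1,
        path=out / "score_SIM000001.tsv", pgs_id="SIM000001")
    panel = planted_panel
    phenotypes = synthetic.simulate_phenotypes(panel, truth, config)
    score_paths = [str(out / "score_SIM000001.tsv")]
    for k in range(1, n_scores):
        pgs_id = f"SIMNULL{k:02d}"
        synthetic.emit_null_score_file(
            panel, truth, n_variants=min(20, config.n_causal + 10),
            seed=config.seed + 100 + k, path=out / f"score_{pgs_id}.tsv", pgs_id=pgs_id)
        score_paths.append(str(out / f"score_{pgs_id}.tsv"))
    data_io.write_genotypes_vcf(panel, out / "panel.vcf")
    data_io.write_phenotypes(phenotypes, out / "phenotypes.tsv")
    synthetic.write_ld_tsv(truth, out / "ld.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "causal_keys": [list(k) for k in truth.causal_keys],
            "causal_weights": truth.causal_weights.tolist(),
            "per_sd_log_or": truth.per_sd_log_or,
            "proxy_pairs": [[list(a), list(b), r] for a, b, r in truth.proxy_pairs],
            "corruption_ledger": truth.corruption_ledger,
            "seed": config.seed,
        }, fh, indent=2)
    return {"panel": str(out / "panel.vcf"),
            "phenotypes": str(out / "phenotypes.tsv"),
            "scores": score_paths,
            "ld": str(out / "ld.tsv"),
            "truth": str(out / "truth.json")}
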