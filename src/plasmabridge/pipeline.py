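"""The end-to-end bridging workflow with QC gates as hard decision points.

Steps, in order: log2 transform → per-protein concordance screen and protein
selection → sample pairing QC → contamination QC (when panels and a reference
are available) → generalizability QC (when a reference is available) →
scaling-factor fitting → serum scaling → bridging QC (pair co-clustering,
plus prediction agreement when a predictor is plugged in).

Each gate either passes or halts the run with a distinct machine-readable
status; ``force=True`` downgrades halts to warnings and carries the flags
into the final report (batches flagged as contaminated have been knowingly
investigated this way — the override must exist, but it is never silent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pbio
from .bridging import pair_coclustering, prediction_agreement
from .concordance import protein_concordance, ratio_classification, select_proteins
from .config import BridgeConfig
from .core import PairedDataset, ProteomicMatrix, Scale
from .sample_qc import (QCReport, contamination_scores, generalizability_qc,
                        pairing_qc, scale_factor_filter)
from .scaling import apply_scaling, fit_scaling_factors, fit_scaling_factors_cv
from .transform import IterativeScaleParams, log2_transform

__all__ = ["PipelineResult", "run_pipeline", "GATES", "GATE_EXIT_CODES"]

GATES = ("assay_qc", "protein_selection", "pairing_qc", "contamination_qc",
         "generalizability_qc", "bridging_qc")

#: Exit code per failed gate (0 = clean run, 1 = input error).
GATE_EXIT_CODES = {
    "assay_qc": 10,
    "protein_selection": 11,
    "pairing_qc": 12,
    "contamination_qc": 13,
    "generalizability_qc": 14,
    "bridging_qc": 15,
}


@dataclass
class PipelineResult:
    status: str                      # "ok" | "halted"
    halted_at: str | None
    gates: dict                      # gate name -> "pass" | "halt" | "forced" | "skipped"
    qc_report: QCReport
    factors: object = None
    scaled_serum: ProteomicMatrix | None = None
    concordance: pd.DataFrame | None = None
    agreement: object = None
    coclustering: object = None
    manifest: dict = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        if self.status == "ok":
            return 0
        return GATE_EXIT_CODES.get(self.halted_at, 1)


def run_pipeline(pairs: PairedDataset, config: BridgeConfig | None = None,
                 reference_serum: ProteomicMatrix | None = None,
                 reference_plasma: ProteomicMatrix | None = None,
                 panels=None, predictor=None, pairing_panel=None,
                 force: bool = False, use_cv: bool = True,
                 outdir=None) -> PipelineResult:
    """Run the full bridging workflow on a paired serum–plasma dataset.

    ``pairs`` may be raw RFU (log2 applied here) or already log2. Factors are
    fitted with patient-grouped cross-validation when ``use_cv`` (the scaled
    output then covers the fitting cohort itself without leakage); otherwise
    a full fit is applied back to the serum side. When ``outdir`` is given,
    all artifacts plus a manifest of every threshold used are written there.
    """
    config = config or BridgeConfig()
    gates = {g: "skipped" for g in GATES}
    report = QCReport()
    manifest: dict = {"config": config.to_dict()}
    it_params = IterativeScaleParams(sd_bound=config.sd_bound,
                                     max_iterations=config.max_iterations,
                                     ddof=config.ddof)

    raw_pairs = pairs if pairs.scale is Scale.RAW_RFU else None
    if pairs.scale is Scale.RAW_RFU:
        pairs = PairedDataset(serum=log2_transform(pairs.serum),
                              plasma=log2_transform(pairs.plasma),
                              pair_index=list(pairs.pair_index))
    for name, ref in (("reference_serum", reference_serum),
                      ("reference_plasma", reference_plasma)):
        if ref is not None and ref.scale is Scale.RAW_RFU:
            ref = log2_transform(ref)
        if name == "reference_serum":
            reference_serum = ref
        else:
            reference_plasma = ref

    def halted(gate: str) -> PipelineResult:
        res = PipelineResult(status="halted", halted_at=gate, gates=gates,
                             qc_report=report, manifest=manifest)
        _write_artifacts(res, outdir)
        return res

    # -- gate 1: assay QC on normalization scale factors ---------------------
    meta = pd.concat([pairs.serum.metadata, pairs.plasma.metadata])
    frag = scale_factor_filter(meta, low=config.scale_factor_low,
                               high=config.scale_factor_high,
                               pair_index=pairs.pair_index)
    report = report.merge(frag)
    if frag.excluded_pairs:
        pairs = pairs.drop_pairs([k for k, _ in frag.excluded_pairs])
    gates["assay_qc"] = "pass"
    if pairs.n_pairs < 3:
        gates["assay_qc"] = "halt"
        return halted("assay_qc")

    # -- step 2: concordance screen and protein selection --------------------
    conc = protein_concordance(pairs)
    if raw_pairs is not None:
        conc = conc.join(ratio_classification(
            raw_pairs, multiplier=config.iqr_multiplier,
            method=config.quartile_method))
    selected = select_proteins(conc, q_threshold=config.q_threshold,
                               r_floor=config.r_floor)
    conc["selected"] = conc.index.isin(selected)
    manifest["n_selected_proteins"] = len(selected)
    if len(selected) < config.min_selected_proteins:
        gates["protein_selection"] = "halt" if not force else "forced"
        report.flags.append(("protein_selection",
                             f"only {len(selected)} proteins pass the "
                             "concordance screen"))
        if not force:
            res = halted("protein_selection")
            res.concordance = conc
            _write_artifacts(res, outdir)
            return res
    else:
        gates["protein_selection"] = "pass"

    # -- gate 3: pairing QC --------------------------------------------------
    pq = pairing_qc(pairs, panel=pairing_panel,
                    multiplier=config.iqr_multiplier, ddof=config.ddof,
                    halt_median_r=config.pairing_halt_median_r,
                    method=config.quartile_method)
    report = report.merge(pq.report)
    if pq.halt:
        gates["pairing_qc"] = "halt" if not force else "forced"
        if not force:
            res = halted("pairing_qc")
            res.concordance = conc
            _write_artifacts(res, outdir)
            return res
    else:
        gates["pairing_qc"] = "pass"
    if pq.report.excluded_pairs:
        pairs = pairs.drop_pairs([k for k, _ in pq.report.excluded_pairs])

    # -- gate 4: contamination QC -------------------------------------------
    if panels and (reference_plasma is not None or reference_serum is not None):
        flagged = False
        for specimen, matrix, reference in (
                ("plasma", pairs.plasma, reference_plasma),
                ("serum", pairs.serum, reference_serum)):
            if reference is None:
                continue
            rep = contamination_scores(matrix, panels, reference,
                                       params=it_params,
                                       multiplier=config.iqr_multiplier,
                                       method=config.quartile_method)
            report.summary[f"contamination_{specimen}"] = {
                "cohort_medians": rep.cohort_medians.round(4).to_dict(),
                "flagged_cohorts": rep.flagged_cohorts,
            }
            for panel_id, msg in rep.flags:
                report.flags.append((f"contamination_{specimen}/{panel_id}", msg))
            flagged = flagged or rep.any_cohort_flagged
        if flagged:
            gates["contamination_qc"] = "halt" if not force else "forced"
            if not force:
                res = halted("contamination_qc")
                res.concordance = conc
                _write_artifacts(res, outdir)
                return res
        else:
            gates["contamination_qc"] = "pass"

    # -- gate 5: generalizability QC ----------------------------------------
    if reference_serum is not None or reference_plasma is not None:
        flagged = False
        for specimen, matrix, reference in (
                ("serum", pairs.serum, reference_serum),
                ("plasma", pairs.plasma, reference_plasma)):
            if reference is None:
                continue
            check = generalizability_qc(
                matrix, reference, multiplier=config.iqr_multiplier,
                tail_fraction_threshold=config.generalizability_tail_fraction,
                spearman_floor=config.generalizability_spearman_floor,
                method=config.quartile_method)
            report.summary[f"generalizability_{specimen}"] = {
                "pearson_r": check.pearson_r, "spearman_r": check.spearman_r,
                "n_outlier_proteins": len(check.outlier_proteins),
                "verdict": check.verdict, "notes": check.notes,
            }
            flagged = flagged or check.verdict == "flag"
        if flagged:
            gates["generalizability_qc"] = "halt" if not force else "forced"
            if not force:
                res = halted("generalizability_qc")
                res.concordance = conc
                _write_artifacts(res, outdir)
                return res
        else:
            gates["generalizability_qc"] = "pass"

    # -- steps 6–7: factor fitting and scaling -------------------------------
    fit_pairs = pairs.subset_proteins(
        [p for p in pairs.protein_ids if p in selected])
    if use_cv:
        cv = fit_scaling_factors_cv(fit_pairs, k=min(config.cv_k,
                                                     fit_pairs.n_pairs),
                                    seed=config.seed)
        factors = fit_scaling_factors(fit_pairs, provenance="full")
        scaled = cv.scaled_serum
        manifest["cv_folds"] = min(config.cv_k, fit_pairs.n_pairs)
    else:
        factors = fit_scaling_factors(fit_pairs, provenance="full")
        scaled = apply_scaling(fit_pairs.serum, factors, policy="drop")
    factors = factors.with_concordance(conc)
    manifest["n_factors"] = len(factors)

    # -- gate 8: bridging QC -------------------------------------------------
    scaled_pairs = PairedDataset(
        serum=scaled.subset_proteins(
            [p for p in scaled.protein_ids
             if p in set(fit_pairs.protein_ids)]),
        plasma=fit_pairs.plasma.subset_proteins(scaled.protein_ids),
        pair_index=list(fit_pairs.pair_index))
    cocluster = pair_coclustering(scaled_pairs, ddof=config.ddof)
    report.summary["bridging_qc"] = {
        "mnn_fraction": cocluster.mnn_fraction,
        "specimen_split_ari": cocluster.specimen_split_ari,
    }
    agreement = None
    if predictor is not None:
        p_plasma = predictor.predict(scaled_pairs.plasma)
        p_serum = predictor.predict(scaled_pairs.serum)
        agreement = prediction_agreement(p_plasma, p_serum,
                                         threshold=config.class_threshold)
        report.summary["prediction_agreement"] = {
            "r2_unity": agreement.r2_unity, "r2_fitted": agreement.r2_fitted,
            "class_agreement_pct": agreement.class_agreement_pct,
            "p_value": agreement.p_value,
        }
    gates["bridging_qc"] = "pass"

    res = PipelineResult(status="ok", halted_at=None, gates=gates,
                         qc_report=report, factors=factors,
                         scaled_serum=scaled, concordance=conc,
                         agreement=agreement, coclustering=cocluster,
                         manifest=manifest)
    _write_artifacts(res, outdir)
    return res


def _write_artifacts(res: PipelineResult, outdir) -> None:
    if outdir is None:
        return
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(res.manifest)
    manifest["status"] = res.status
    manifest["halted_at"] = res.halted_at
    manifest["gates"] = res.gates
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    (outdir / "qc_report.json").write_text(
        json.dumps(res.qc_report.to_dict(), indent=2, sort_keys=True,
                   default=str) + "\n")
    if res.concordance is not None:
        res.concordance.to_csv(outdir / "concordance.tsv", sep="\t",
                               float_format="%.9g")
    if res.factors is not None:
        pbio.write_factor_table(res.factors, outdir / "factors.tsv")
    if res.scaled_serum is not None:
        pbio.write_matrix(res.scaled_serum, outdir / "scaled_serum.tsv")
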