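"""Pre-scaling quality-control checkpoints.

Four checks gate the derivation of scaling factors:

1. **Assay QC** — samples whose per-sample normalization scale factor falls
   outside an acceptance window (default 0.4–2.5, inclusive) are excluded;
   a pair is excluded when either member fails.
2. **Pairing QC** — pairs whose cross-specimen correlation (Pearson, on
   per-protein z-scores over a biomarker panel) is a low IQR outlier are
   excluded. If pairs are generally uncorrelated the whole run should halt:
   bridging is not valid on unmatched samples.
3. **Contamination QC** — platelet/erythrocyte marker-panel scores per
   sample, standardized against an external reference of the same specimen
   type via iterative scaling; a cohort whose median score stands out is
   flagged as a possible source of bias.
4. **Generalizability QC** — per-protein medians of a cohort vs an external
   reference: poor correlation or a heavy outlier tail means factors fitted
   on that cohort will not transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MarkerPanel, PairedDataset, ProteomicMatrix, Scale
from .transform import (IterativeScaleParams, OutlierBounds, iqr_bounds,
                        iterative_reference_moments, zscore_per_protein)

__all__ = [
    "QCReport",
    "PairingQC",
    "ContaminationReport",
    "ConcordanceCheck",
    "scale_factor_filter",
    "pairing_qc",
    "contamination_scores",
    "generalizability_qc",
    "REASON_SCALE_FACTOR",
    "REASON_PAIRING",
    "REASON_CONTAMINATION",
    "REASON_USER",
]

REASON_SCALE_FACTOR = "scale_factor_out_of_range"
REASON_PAIRING = "pairing_failure"
REASON_CONTAMINATION = "contamination"
REASON_USER = "user"


@dataclass
class QCReport:
    """Machine-readable QC outcome: exclusions with reason codes, free-form
    flags, and per-check summary statistics."""

    excluded_samples: list = field(default_factory=list)
    excluded_pairs: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            excluded_samples=self.excluded_samples + other.excluded_samples,
            excluded_pairs=self.excluded_pairs + other.excluded_pairs,
            flags=self.flags + other.flags,
            summary={**self.summary, **other.summary},
        )

    def to_dict(self) -> dict:
        return {
            "excluded_samples": [[str(s), r] for s, r in self.excluded_samples],
            "excluded_pairs": [[list(map(str, k)), r]
                               for k, r in self.excluded_pairs],
            "flags": [[scope, msg] for scope, msg in self.flags],
            "summary": self.summary,
        }


def scale_factor_filter(metadata: pd.DataFrame, low: float = 0.4,
                        high: float = 2.5, pair_index=None) -> QCReport:
    """Exclude samples whose assay normalization scale factor lies outside
    [low, high] (bounds inclusive: 0.4 and 2.5 pass).

    A missing factor yields a flag, not an exclusion. When ``pair_index`` is
    given, a pair is excluded if either of its members fails.
    """
    report = QCReport()
    if "norm_scale_factor" not in metadata.columns:
        report.flags.append(("assay_qc",
                             "norm_scale_factor column absent; assay QC skipped"))
        report.summary["assay_qc"] = {"screened": 0, "excluded": 0}
        return report
    nsf = pd.to_numeric(metadata["norm_scale_factor"], errors="coerce")
    for sid in metadata.index[nsf.isna()]:
        report.flags.append(("assay_qc", f"sample {sid}: norm_scale_factor missing"))
    failing = set(metadata.index[nsf.notna() & ((nsf < low) | (nsf > high))])
    report.excluded_samples = [(sid, REASON_SCALE_FACTOR) for sid in
                               metadata.index if sid in failing]
    if pair_index is not None:
        for key in pair_index:
            if key.serum_sample_id in failing or key.plasma_sample_id in failing:
                report.excluded_pairs.append((key, REASON_SCALE_FACTOR))
    report.summary["assay_qc"] = {
        "screened": int(nsf.notna().sum()),
        "excluded": len(report.excluded_samples),
        "excluded_pairs": len(report.excluded_pairs),
        "range": [low, high],
    }
    return report


@dataclass
class PairingQC:
    """Pairing-QC outcome: per-pair cross-specimen correlations, the IQR
    bounds on them, excluded pairs, and a halt flag when pairs are generally
    uncorrelated."""

    report: QCReport
    correlations: pd.Series
    bounds: OutlierBounds
    halt: bool


def pairing_qc(pd_: PairedDataset, panel=None, multiplier: float = 1.5,
               ddof: int = 1, halt_median_r: float = 0.2,
               method: str = "linear") -> PairingQC:
    """Exclude serum–plasma pairs whose cross-specimen correlation is a low
    IQR outlier.

    Protein levels are z-scored per protein within each specimen (pooled
    across cohorts), then each pair's Pearson correlation is computed over
    the panel proteins (all proteins when no panel is given). Exclusion
    decisions are therefore invariant to protein-wise affine rescaling of
    either matrix. If the median correlation falls below ``halt_median_r``
    the result carries a halt flag: bridging unmatched samples is invalid.
    """
    if pd_.n_pairs < 8:
        raise ValueError("pairing_qc requires ≥8 pairs for a meaningful "
                         "correlation distribution")
    proteins = pd_.protein_ids
    if panel is not None:
        panel_ids = panel.protein_ids if isinstance(panel, MarkerPanel) else set(panel)
        proteins = [p for p in proteins if p in panel_ids]
    if len(proteins) < 10:
        raise ValueError(f"pairing_qc needs ≥10 panel proteins measured, "
                         f"got {len(proteins)}")
    sub = pd_.subset_proteins(proteins)
    zs = zscore_per_protein(sub.serum, ddof=ddof)
    zp = zscore_per_protein(sub.plasma, ddof=ddof)
    drop = {p for p, f in {**zs.flags, **zp.flags}.items() if f}
    keep = [p for p in proteins if p not in drop]
    if len(keep) < 10:
        raise ValueError("fewer than 10 informative panel proteins after "
                         "removing zero-variance columns")
    xs = zs.values[keep].to_numpy(dtype=float)
    xp = zp.values[keep].to_numpy(dtype=float)
    xs = xs - xs.mean(axis=1, keepdims=True)
    xp = xp - xp.mean(axis=1, keepdims=True)
    num = (xs * xp).sum(axis=1)
    den = np.sqrt((xs * xs).sum(axis=1) * (xp * xp).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / den
    corr = pd.Series(corr, index=[k.serum_sample_id for k in pd_.pair_index],
                     name="pair_correlation")
    bounds = iqr_bounds(corr.dropna(), multiplier=multiplier, method=method)
    excluded = [key for key, r in zip(pd_.pair_index, corr)
                if np.isfinite(r) and r < bounds.lower]
    report = QCReport(
        excluded_pairs=[(k, REASON_PAIRING) for k in excluded],
        summary={"pairing_qc": {
            "n_pairs": pd_.n_pairs,
            "n_panel_proteins": len(keep),
            "median_correlation": float(corr.median()),
            "lower_bound": bounds.lower,
            "excluded": len(excluded),
        }},
    )
    halt = bool(corr.median() < halt_median_r)
    if halt:
        report.flags.append(("pairing_qc",
                             "pairs generally uncorrelated (median r "
                             f"{corr.median():.3f} < {halt_median_r}); "
                             "halting is advisable — bridging would be invalid"))
    return PairingQC(report=report, correlations=corr, bounds=bounds, halt=halt)


@dataclass
class ContaminationReport:
    """Marker-panel contamination scores (z-units relative to the reference
    distribution): per sample, per cohort, with flagged cohorts/samples."""

    sample_scores: pd.DataFrame
    cohort_medians: pd.DataFrame
    flagged_cohorts: dict
    flagged_samples: dict
    flags: list = field(default_factory=list)

    @property
    def any_cohort_flagged(self) -> bool:
        return any(len(v) for v in self.flagged_cohorts.values())


def contamination_scores(m: ProteomicMatrix, panels,
                         reference: ProteomicMatrix,
                         params: IterativeScaleParams | None = None,
                         multiplier: float = 1.5,
                         method: str = "linear") -> ContaminationReport:
    """Score samples for marker-panel contamination against an external
    reference of the same specimen type.

    Iterative-scaling moments (outlier-robust mean/sd per protein) are fitted
    on the reference; the screened samples' panel proteins are standardized
    with those moments (clipped at ±sd_bound, mirroring the outlier
    imputation rule) and averaged into one score per sample and panel. A
    clean sample scores ≈ 0; a sample spiked by δ reference-sds on every
    panel protein scores ≈ δ.

    A cohort is flagged when its median score exceeds the IQR upper bound of
    the per-sample scores pooled over the *other* cohorts (leave-one-out).
    """
    params = params or IterativeScaleParams()
    if m.scale is not Scale.LOG2 or reference.scale is not Scale.LOG2:
        raise ValueError("contamination_scores expects log2 matrices")
    spec_m, spec_r = m.specimen_type(), reference.specimen_type()
    if spec_m and spec_r and spec_m != spec_r:
        raise ValueError(f"specimen mismatch: samples are {spec_m!r} but the "
                         f"reference is {spec_r!r}")
    ref_mean, ref_sd, degenerate = iterative_reference_moments(reference, params)
    cohorts = m.metadata["cohort_id"]
    scores = {}
    flags = []
    for panel in panels:
        shared = [p for p in m.protein_ids
                  if p in panel.protein_ids and p in set(reference.protein_ids)
                  and not degenerate.get(p, True)]
        if not shared:
            raise ValueError(f"panel {panel.panel_id!r} has no usable proteins "
                             "shared with both matrix and reference")
        dropped = len(panel.protein_ids) - len(shared)
        if dropped:
            flags.append((panel.panel_id,
                          f"{dropped} panel protein(s) unusable (unmeasured "
                          "or degenerate in reference)"))
        z = ((m.values[shared] - ref_mean[shared]) / ref_sd[shared])
        z = z.clip(lower=-params.sd_bound, upper=params.sd_bound)
        scores[panel.panel_id] = z.mean(axis=1)
    sample_scores = pd.DataFrame(scores)
    cohort_medians = sample_scores.groupby(cohorts).median()
    flagged_cohorts = {}
    flagged_samples = {}
    for panel_id in sample_scores.columns:
        s = sample_scores[panel_id]
        flagged = []
        for cohort in cohort_medians.index:
            others = s[cohorts != cohort]
            if len(others) < 4:
                continue
            bounds = iqr_bounds(others, multiplier=multiplier, method=method)
            if cohort_medians.loc[cohort, panel_id] > bounds.upper:
                flagged.append(str(cohort))
        flagged_cohorts[panel_id] = flagged
        if len(s) >= 4:
            sb = iqr_bounds(s, multiplier=multiplier, method=method)
            flagged_samples[panel_id] = s.index[s > sb.upper].tolist()
        else:
            flagged_samples[panel_id] = []
        for cohort in flagged:
            flags.append((panel_id, f"cohort {cohort} median score "
                          f"{cohort_medians.loc[cohort, panel_id]:.2f} exceeds "
                          "the across-cohort bound"))
    return ContaminationReport(sample_scores=sample_scores,
                               cohort_medians=cohort_medians,
                               flagged_cohorts=flagged_cohorts,
                               flagged_samples=flagged_samples, flags=flags)


@dataclass
class ConcordanceCheck:
    """Generalizability check of a cohort against an external reference:
    per-protein median differences (cohort − reference, log2), correlation of
    the median vectors, outlier proteins, and a pass/flag verdict."""

    differences: pd.Series
    pearson_r: float
    spearman_r: float
    bounds: OutlierBounds
    outlier_proteins: list
    verdict: str
    notes: list = field(default_factory=list)


def generalizability_qc(cohort: ProteomicMatrix, reference: ProteomicMatrix,
                        multiplier: float = 1.5,
                        tail_fraction_threshold: float = 0.05,
                        spearman_floor: float = 0.8,
                        offset_note_threshold: float = 0.2,
                        method: str = "linear") -> ConcordanceCheck:
    """Compare per-protein medians of a cohort against an external reference
    of the same specimen type.

    Outlier proteins are IQR outliers of the difference distribution (a
    uniform global shift inflates no protein beyond the bounds — it is noted,
    not flagged). The verdict is ``"flag"`` when the outlier tail exceeds
    ``tail_fraction_threshold`` or the Spearman correlation of the median
    vectors falls below ``spearman_floor``.
    """
    if cohort.scale is not Scale.LOG2 or reference.scale is not Scale.LOG2:
        raise ValueError("generalizability_qc expects log2 matrices")
    spec_c, spec_r = cohort.specimen_type(), reference.specimen_type()
    if spec_c and spec_r and spec_c != spec_r:
        raise ValueError(f"specimen mismatch: cohort is {spec_c!r}, reference "
                         f"is {spec_r!r}")
    shared = [p for p in cohort.protein_ids if p in set(reference.protein_ids)]
    if len(shared) == 0:
        raise ValueError("no shared proteins between cohort and reference")
    if len(shared) < 50:
        raise ValueError(f"generalizability_qc requires ≥50 shared proteins, "
                         f"got {len(shared)}")
    med_c = cohort.values[shared].median(axis=0)
    med_r = reference.values[shared].median(axis=0)
    diff = (med_c - med_r).rename("median_difference")
    bounds = iqr_bounds(diff, multiplier=multiplier, method=method)
    outliers = diff.index[(diff > bounds.upper) | (diff < bounds.lower)].tolist()
    pearson = float(np.corrcoef(med_c, med_r)[0, 1])
    spearman = float(stats.spearmanr(med_c, med_r)[0])
    notes = []
    offset = float(diff.median())
    if abs(offset) > offset_note_threshold:
        notes.append(f"systematic offset of {offset:+.3f} log2 units between "
                     "cohort and reference medians")
    tail_fraction = len(outliers) / len(shared)
    verdict = "pass"
    if tail_fraction > tail_fraction_threshold:
        verdict = "flag"
        notes.append(f"outlier tail fraction {tail_fraction:.3f} exceeds "
                     f"{tail_fraction_threshold}")
    if spearman < spearman_floor:
        verdict = "flag"
        notes.append(f"Spearman correlation of medians {spearman:.3f} below "
                     f"floor {spearman_floor}")
    return ConcordanceCheck(differences=diff, pearson_r=pearson,
                            spearman_r=spearman, bounds=bounds,
                            outlier_proteins=outliers, verdict=verdict,
                            notes=notes)
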