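"""Per-protein serum→plasma linear scaling factors.

For each protein, ordinary least squares of plasma log2(RFU) (response) on
serum log2(RFU) (predictor) across matched pairs yields a slope and an
intercept; a serum measurement is then mapped to its plasma equivalent by

    log2(RFU)_scaled = log2(RFU)_raw · slope + intercept

No regularization is applied: the relationship is protein-local and the
model deliberately stays a two-parameter line. Variants here: a
patient-grouped k-fold cross-validated fit (so factors can be applied to the
same cohort they came from without leakage), a mismatched-pair negative
control (seeded derangement of the plasma side), and a factor-set comparison
for judging cross-cohort consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PairedDataset, PairKey, ProteomicMatrix, Scale

__all__ = [
    "ScalingFactorSet",
    "FactorSetComparison",
    "CVScalingResult",
    "fit_scaling_factors",
    "fit_scaling_factors_cv",
    "mismatched_control",
    "apply_scaling",
    "compare_factor_sets",
]

FACTOR_TABLE_COLUMNS = ("slope", "intercept", "n_pairs", "pearson_r",
                        "residual_sd", "spearman_r", "spearman_p", "spearman_q")


@dataclass
class ScalingFactorSet:
    """Per-protein slope/intercept (+ fit diagnostics) of the serum→plasma map.

    ``table`` is indexed by protein id with columns ``slope``, ``intercept``
    (log2 units), ``n_pairs``, ``pearson_r`` and ``residual_sd``; optional
    ``spearman_r``/``spearman_p``/``spearman_q`` columns can be merged in
    from a concordance screen. Proteins that could not be fitted (zero serum
    variance) are absent from the table, never zero-filled; their ids are
    kept in ``skipped``.
    """

    table: pd.DataFrame
    provenance: str = "full"
    skipped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("slope", "intercept", "n_pairs"):
            if col not in self.table.columns:
                raise ValueError(f"factor table missing column {col!r}")
        if len(self.table) and (self.table["n_pairs"] < 3).any():
            raise ValueError("every fitted protein needs n_pairs ≥ 3")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate protein ids in factor table")

    @property
    def protein_ids(self) -> list:
        return self.table.index.tolist()

    def __len__(self) -> int:
        return len(self.table)

    def with_concordance(self, concordance: pd.DataFrame) -> "ScalingFactorSet":
        """Merge Spearman statistics from a concordance table (by protein)."""
        t = self.table.copy()
        for col in ("spearman_r", "spearman_p", "spearman_q"):
            t[col] = concordance[col].reindex(t.index)
        return ScalingFactorSet(table=t, provenance=self.provenance,
                                skipped=list(self.skipped))


def fit_scaling_factors(pd_: PairedDataset, provenance: str = "full",
                        min_pairs: int = 3) -> ScalingFactorSet:
    """Ordinary least squares of plasma on serum, per protein.

    Uses the closed-form solution slope = cov(serum, plasma)/var(serum),
    intercept = mean(plasma) − slope·mean(serum), minimizing the residual sum
    of squares. Proteins with zero serum variance are skipped (recorded in
    ``skipped``), never silently zero-filled.
    """
    if pd_.scale is not Scale.LOG2:
        raise ValueError("fit_scaling_factors expects log2-scale data")
    n = pd_.n_pairs
    if n < min_pairs or n < 3:
        raise ValueError(f"fit_scaling_factors requires ≥{max(min_pairs, 3)} pairs")
    x = pd_.serum_values()
    y = pd_.plasma_values()
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    xc = x - xm
    yc = y - ym
    sxx = (xc * xc).sum(axis=0)
    sxy = (xc * yc).sum(axis=0)
    syy = (yc * yc).sum(axis=0)
    fit_ok = sxx > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
        r = sxy / np.sqrt(sxx * syy)
        sse = syy - slope * sxy  # residual sum of squares after OLS
        resid_sd = np.sqrt(np.maximum(sse, 0.0) / max(n - 2, 1))
    r = np.where(syy > 0, r, np.nan)
    proteins = np.asarray(pd_.protein_ids, dtype=object)
    table = pd.DataFrame(
        {
            "slope": slope[fit_ok],
            "intercept": intercept[fit_ok],
            "n_pairs": n,
            "pearson_r": np.clip(r[fit_ok], -1, 1),
            "residual_sd": resid_sd[fit_ok],
        },
        index=pd.Index(proteins[fit_ok], name="protein_id"),
    )
    return ScalingFactorSet(table=table, provenance=provenance,
                            skipped=proteins[~fit_ok].tolist())


def apply_scaling(serum: ProteomicMatrix, factors: ScalingFactorSet,
                  policy: str = "error") -> ProteomicMatrix:
    """Map serum log2 measurements to plasma equivalents:
    scaled = value·slope + intercept, per protein.

    ``policy`` governs proteins without a fitted factor: ``"error"`` (default)
    raises, ``"drop"`` removes them from the output, ``"passthrough"`` leaves
    them unscaled (flagged).
    """
    if serum.scale is not Scale.LOG2:
        raise ValueError("apply_scaling expects a log2 matrix; log2-transform first")
    if policy not in ("error", "drop", "passthrough"):
        raise ValueError(f"unknown policy {policy!r}")
    have = factors.table.index
    missing = [p for p in serum.protein_ids if p not in set(have)]
    if missing and policy == "error":
        raise ValueError(
            f"{len(missing)} protein(s) lack scaling factors "
            f"(e.g. {missing[:5]}); use policy='drop' or 'passthrough'")
    keep = [p for p in serum.protein_ids if p in set(have)]
    slope = factors.table["slope"].reindex(keep).to_numpy()
    intercept = factors.table["intercept"].reindex(keep).to_numpy()
    scaled = serum.values[keep].to_numpy(dtype=float) * slope + intercept
    out = pd.DataFrame(scaled, index=serum.values.index, columns=keep)
    if policy == "passthrough" and missing:
        out = pd.concat([out, serum.values[missing]], axis=1)
        out = out[[p for p in serum.protein_ids if p in set(out.columns)]]
        flags = {p: "not_scaled" for p in missing}
        return serum.with_values(out, extra_flags=flags)
    return serum.with_values(out)


@dataclass
class CVScalingResult:
    """Outcome of the patient-grouped k-fold cross-validated fit: per-fold
    factor sets, the concatenated out-of-fold scaled serum matrix (every pair
    scaled exactly once, by factors fitted without it), and the fold of each
    patient."""

    fold_factors: list
    scaled_serum: ProteomicMatrix
    fold_of_patient: dict
    dropped_proteins: list = field(default_factory=list)


def fit_scaling_factors_cv(pd_: PairedDataset, k: int = 5,
                           seed: int = 0) -> CVScalingResult:
    """k-fold cross-validated factor fitting with patient-grouped folds.

    All pairs of one patient (e.g. its T0 and T1 samples) land in the same
    fold, preventing within-patient leakage. Factors fitted on k−1 folds are
    applied to the held-out serum samples; the returned matrix covers every
    pair exactly once, in the original pair order. Proteins that could not be
    fitted in every fold are dropped from the scaled matrix (recorded in
    ``dropped_proteins``).
    """
    n = pd_.n_pairs
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pairs ({n})")
    patients = [key.patient_id for key in pd_.pair_index]
    unique_patients = sorted(set(patients))
    if k > len(unique_patients):
        raise ValueError(f"k={k} exceeds the number of patients "
                         f"({len(unique_patients)})")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(unique_patients))
    fold_of_patient = {p: i % k for i, p in enumerate(shuffled)}
    fold_of_pair = np.array([fold_of_patient[p] for p in patients])

    fold_factors = []
    scaled_rows = {}
    fitted_in_all = None
    for fold in range(k):
        train_idx = np.flatnonzero(fold_of_pair != fold)
        test_idx = np.flatnonzero(fold_of_pair == fold)
        if len(train_idx) < 3:
            raise ValueError(f"fold {fold} leaves fewer than 3 training pairs")
        factors = fit_scaling_factors(pd_.subset_pairs(train_idx),
                                      provenance=f"cv_fold {fold}")
        fold_factors.append(factors)
        fitted = set(factors.protein_ids)
        fitted_in_all = fitted if fitted_in_all is None else fitted_in_all & fitted
        held_out = pd_.subset_pairs(test_idx).serum
        scaled = apply_scaling(held_out, factors, policy="drop")
        for sid in scaled.sample_ids:
            scaled_rows[sid] = scaled.values.loc[sid]

    keep = [p for p in pd_.protein_ids if p in fitted_in_all]
    dropped = [p for p in pd_.protein_ids if p not in fitted_in_all]
    order = [key.serum_sample_id for key in pd_.pair_index]
    mat = pd.DataFrame([scaled_rows[sid] for sid in order], index=order)[keep]
    scaled_serum = ProteomicMatrix(values=mat, scale=Scale.LOG2,
                                   metadata=pd_.serum.metadata)
    return CVScalingResult(fold_factors=fold_factors, scaled_serum=scaled_serum,
                           fold_of_patient=fold_of_patient,
                           dropped_proteins=dropped)


def mismatched_control(pd_: PairedDataset, seed: int = 0) -> PairedDataset:
    """Negative control: re-pair every serum sample with a *wrong* plasma
    sample via a seeded derangement (no pair keeps its original mate).

    Fitting factors on the result should yield slopes centered near 0 and
    intercepts near the per-protein plasma mean — the signature of absent
    signal.
    """
    n = pd_.n_pairs
    if n < 2:
        raise ValueError("mismatched_control needs ≥2 pairs (no derangement "
                         "exists for n=1)")
    if n < 3:
        perm = np.array([1, 0])
    else:
        rng = np.random.default_rng(seed)
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
    keys = pd_.pair_index
    new_keys = [PairKey(keys[i].patient_id, keys[i].timepoint,
                        keys[i].serum_sample_id,
                        keys[int(perm[i])].plasma_sample_id)
                for i in range(n)]
    plasma = pd_.plasma.subset_samples([k.plasma_sample_id for k in new_keys])
    return PairedDataset(serum=pd_.serum, plasma=plasma, pair_index=new_keys)


@dataclass
class FactorSetComparison:
    """Cross-cohort agreement of two factor sets over shared proteins."""

    n_shared: int
    slope_r: float
    intercept_r: float
    fit_corr_spearman_r: float
    slope_hist2d: tuple | None = None
    intercept_hist2d: tuple | None = None


def compare_factor_sets(a: ScalingFactorSet, b: ScalingFactorSet,
                        bins: int = 40) -> FactorSetComparison:
    """Pearson r of slopes and of intercepts over the proteins shared by two
    factor sets, plus the Spearman correlation of the per-protein fit
    correlations and 2-D histogram summaries."""
    shared = a.table.index.intersection(b.table.index)
    if len(shared) < 10:
        raise ValueError(f"compare_factor_sets requires ≥10 shared proteins, "
                         f"got {len(shared)}")
    sa, sb = a.table.loc[shared], b.table.loc[shared]
    slope_r = float(np.corrcoef(sa["slope"], sb["slope"])[0, 1])
    intercept_r = float(np.corrcoef(sa["intercept"], sb["intercept"])[0, 1])
    fit_rho = np.nan
    if "pearson_r" in sa.columns and "pearson_r" in sb.columns:
        ok = sa["pearson_r"].notna() & sb["pearson_r"].notna()
        if ok.sum() >= 10:
            fit_rho = float(stats.spearmanr(sa.loc[ok, "pearson_r"],
                                            sb.loc[ok, "pearson_r"])[0])
    slope_h = np.histogram2d(sa["slope"], sb["slope"], bins=bins)
    int_h = np.histogram2d(sa["intercept"], sb["intercept"], bins=bins)
    return FactorSetComparison(n_shared=int(len(shared)), slope_r=slope_r,
                               intercept_r=intercept_r,
                               fit_corr_spearman_r=fit_rho,
                               slope_hist2d=slope_h, intercept_hist2d=int_h)
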