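"""Synthetic paired serum/plasma cohorts with known ground truth.

The generator emulates the statistical structure of multiplexed aptamer-assay
(RFU) data from matched serum–plasma pairs, so every pipeline stage can be
exercised and validated against planted truth without any download:

* log-normal measurements: per-protein log2 baselines ~ N(8, 2), the typical
  dynamic range of a multiplexed affinity assay;
* a protein-wise linear serum→plasma relation in log2 space:
  plasma = slope·serum + intercept + independent noise (the linear law acts
  on the serum *measurement*, so ordinary least squares of plasma on serum
  recovers the planted slope without errors-in-variables attenuation);
  slopes near 1 and intercepts near 0 for the "normal" majority;
* patient effects built from a modest number of latent factors with a
  bounded per-patient amplitude, so that profiles of the same patient
  correlate strongly across specimens and timepoints, the leading principal
  components carry structured pair-shared variance (as real proteomes do)
  rather than white noise, and the spread of pair correlations reflects
  bounded sample-quality variation rather than an unbounded tail;
* an LOD subpopulation: proteins compressed onto a noisy floor in both
  specimens, destroying rank correlation;
* coagulation-like extreme-ratio proteins with intercepts of ±log2(100),
  reproducing the ~100× plasma-retained and ~0.01× serum-accumulated tails;
* contamination-marker spikes in one flagged cohort's plasma;
* small per-cohort batch shifts, weaker than the specimen difference;
* longitudinal T1 re-samples sharing a damped patient effect;
* optional mismatch-injected pairs whose plasma comes from a different
  patient effect.

Everything is driven by a single mandatory seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (MarkerPanel, PairedDataset, PairKey, ProteomicMatrix,
                   Scale, build_pairs)

__all__ = [
    "SynthConfig",
    "SyntheticTruth",
    "SyntheticData",
    "generate_cohorts",
    "inject_pair_mismatches",
]

CLASS_NORMAL = "normal"
CLASS_LOD = "lod"
CLASS_COAG_HIGH_PLASMA = "coag_high_plasma"
CLASS_COAG_HIGH_SERUM = "coag_high_serum"
CLASS_CONTAMINATION_MARKER = "contamination_marker"


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs of the generator. Defaults describe three
    cohorts of matched pairs with an external clean reference per specimen,
    one contaminated plasma cohort, and small LOD/coagulation subpopulations.

    All values are in log2(RFU) units unless stated otherwise; the seed is
    mandatory.
    """

    seed: int
    n_cohorts: int = 3
    pairs_per_cohort: int = 40
    n_proteins: int = 500
    n_reference_serum: int = 60
    n_reference_plasma: int = 60
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    n_latent: int = 25
    latent_decay: float = 1.0
    patient_effect_sd: float = 1.0
    amplitude_jitter: float = 0.0
    noise_jitter: float = 0.4
    t1_fraction: float = 0.2
    t1_perturb_factor: float = 0.5
    cohort_shift_sd: float = 0.2
    noise_sd: float = 0.3
    slope_mean: float = 1.0
    slope_sd: float = 0.1
    intercept_mean: float = 0.0
    intercept_sd: float = 0.3
    fraction_lod: float = 0.05
    lod_floor_offset: float = -1.0
    lod_floor_noise_sd: float = 0.15
    fraction_coag: float = 0.02
    coag_log2_magnitude: float = math.log2(100.0)
    contaminated_cohort: str | None = "auto"
    contamination_panel_size: int = 20
    contamination_spike_sd: float = 1.5
    n_mismatched: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("t1_fraction", "fraction_lod", "fraction_coag"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fraction_lod + self.fraction_coag > 1.0:
            raise ValueError("special protein fractions exceed 1")
        if self.n_cohorts < 1 or self.pairs_per_cohort < 1 or self.n_proteins < 1:
            raise ValueError("cohort/pair/protein counts must be positive")
        if self.contaminated_cohort == "auto":
            # last cohort when there are ≥3 cohorts, mirroring a multi-site
            # study with one problematic collection protocol; else none
            object.__setattr__(self, "contaminated_cohort",
                               self.cohort_ids()[-1] if self.n_cohorts >= 3
                               else None)
        if self.contaminated_cohort is not None \
                and self.contaminated_cohort not in self.cohort_ids():
            raise ValueError(
                f"contaminated_cohort {self.contaminated_cohort!r} not among "
                f"generated cohorts {self.cohort_ids()}")
        if self.contamination_panel_size > self.n_proteins:
            raise ValueError("contamination panel larger than the proteome")
        if self.noise_sd < 0 or self.patient_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for name in ("amplitude_jitter", "noise_jitter"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    def cohort_ids(self) -> list:
        return [chr(ord("A") + i) for i in range(self.n_cohorts)]


@dataclass
class SyntheticTruth:
    """Ground truth aligned by id with the emitted matrices: per protein the
    true slope/intercept and class; per sample the contamination status; per
    pair whether it is genuinely matched."""

    proteins: pd.DataFrame
    samples: pd.DataFrame
    pairs: pd.DataFrame


@dataclass
class SyntheticData:
    """Generator output: pooled serum and plasma matrices (metadata carries
    cohort/patient/timepoint), clean external references per specimen, the
    contamination marker panel, and the truth tables."""

    serum: ProteomicMatrix
    plasma: ProteomicMatrix
    reference_serum: ProteomicMatrix
    reference_plasma: ProteomicMatrix
    contamination_panel: MarkerPanel | None
    truth: SyntheticTruth
    config: SynthConfig

    def paired(self, cohort: str | None = None) -> PairedDataset:
        """Build the PairedDataset (optionally restricted to one cohort)."""
        pairs = build_pairs(self.serum, self.plasma)
        return pairs if cohort is None else pairs.subset_cohort(cohort)


def _latent_loadings(rng, cfg: SynthConfig) -> np.ndarray:
    """Protein × latent loadings scaled so the per-protein patient-effect
    variance equals patient_effect_sd² in expectation, with (optionally
    decaying) factor strengths."""
    w = cfg.latent_decay ** np.arange(cfg.n_latent)
    w = w / np.sqrt(np.sum(w ** 2)) * cfg.patient_effect_sd
    raw = rng.normal(size=(cfg.n_proteins, cfg.n_latent))
    return raw * w


def _patient_factors(rng, n: int, cfg: SynthConfig) -> np.ndarray:
    """Latent factor vectors with a fixed norm times a bounded Uniform
    amplitude: patients differ in overall deviation within a bounded range,
    so derived per-pair statistics have short tails (as sample-quality
    variation does in practice) instead of a χ² tail."""
    raw = rng.normal(size=(n, cfg.n_latent))
    norms = np.linalg.norm(raw, axis=1, keepdims=True)
    unit = raw / np.where(norms == 0, 1.0, norms)
    amp = rng.uniform(1.0 - cfg.amplitude_jitter, 1.0 + cfg.amplitude_jitter,
                      size=(n, 1))
    return unit * np.sqrt(cfg.n_latent) * amp


def generate_cohorts(cfg: SynthConfig) -> SyntheticData:
    """Generate paired serum/plasma cohorts plus clean references.

    Serum log2 value = baseline + cohort shift + patient effect + noise;
    plasma log2 value = slope·serum + intercept + independent noise. In the
    degenerate limit (noise → 0, slopes 1, intercepts 0) serum equals plasma
    exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    protein_ids = [f"SOMA{i:05d}" for i in range(1, cfg.n_proteins + 1)]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins)
    slope = rng.normal(cfg.slope_mean, cfg.slope_sd, cfg.n_proteins)
    intercept = rng.normal(cfg.intercept_mean, cfg.intercept_sd, cfg.n_proteins)

    # assign special protein classes on disjoint index blocks (shuffled)
    classes = np.array([CLASS_NORMAL] * cfg.n_proteins, dtype=object)
    order = rng.permutation(cfg.n_proteins)
    n_lod = int(round(cfg.fraction_lod * cfg.n_proteins))
    n_coag = int(round(cfg.fraction_coag * cfg.n_proteins))
    n_coag_hp = n_coag // 2 + n_coag % 2
    n_coag_hs = n_coag // 2
    lod_idx = order[:n_lod]
    coag_hp_idx = order[n_lod:n_lod + n_coag_hp]
    coag_hs_idx = order[n_lod + n_coag_hp:n_lod + n_coag_hp + n_coag_hs]
    classes[lod_idx] = CLASS_LOD
    classes[coag_hp_idx] = CLASS_COAG_HIGH_PLASMA
    classes[coag_hs_idx] = CLASS_COAG_HIGH_SERUM
    intercept[coag_hp_idx] = cfg.coag_log2_magnitude \
        + (1.0 - slope[coag_hp_idx]) * baseline[coag_hp_idx]
    intercept[coag_hs_idx] = -cfg.coag_log2_magnitude \
        + (1.0 - slope[coag_hs_idx]) * baseline[coag_hs_idx]
    normal_pool = order[n_lod + n_coag_hp + n_coag_hs:]
    if cfg.contamination_panel_size > len(normal_pool):
        raise ValueError("not enough normal-class proteins for the "
                         "contamination panel")
    marker_idx = normal_pool[:cfg.contamination_panel_size]
    if len(marker_idx):
        classes[marker_idx] = CLASS_CONTAMINATION_MARKER

    loadings = _latent_loadings(rng, cfg)
    cohort_shift = {c: rng.normal(0.0, cfg.cohort_shift_sd, cfg.n_proteins)
                    for c in cfg.cohort_ids()}

    lod_floor = baseline + cfg.lod_floor_offset
    # sd of clean plasma values around the protein mean (used to express the
    # contamination spike in reference-sd units)
    plasma_sd = np.sqrt((slope * cfg.patient_effect_sd) ** 2 + cfg.noise_sd ** 2)

    def emit(cohort: str | None, n_subjects: int, rng,
             specimen_only: str | None = None, t1: bool = False):
        """Rows for one cohort (or a reference set when cohort is None)."""
        serum_rows, plasma_rows, meta_rows = [], [], []
        tag = cohort if cohort is not None else ("RS" if specimen_only == "serum"
                                                 else "RP")
        factors = _patient_factors(rng, n_subjects, cfg)
        n_t1 = int(round(cfg.t1_fraction * n_subjects)) if t1 else 0
        t1_subjects = set(range(n_t1))  # first patients get a T1 re-sample
        for i in range(n_subjects):
            patient = f"{tag}P{i + 1:03d}"
            tps = ["T0"] + (["T1"] if i in t1_subjects else [])
            f0 = factors[i]
            for tp in tps:
                f = f0 if tp == "T0" else f0 + cfg.t1_perturb_factor \
                    * rng.normal(size=cfg.n_latent)
                effect = loadings @ f
                signal = baseline + effect
                if cohort is not None:
                    signal = signal + cohort_shift[cohort]
                # per-sample bounded technical-quality multiplier on the noise
                u_s, u_p = rng.uniform(1.0 - cfg.noise_jitter,
                                       1.0 + cfg.noise_jitter, size=2)
                serum = signal + u_s * rng.normal(0.0, cfg.noise_sd,
                                                  cfg.n_proteins) \
                    if cfg.noise_sd > 0 else signal.copy()
                plasma = slope * serum + intercept
                if cfg.noise_sd > 0:
                    plasma = plasma + u_p * rng.normal(0.0, cfg.noise_sd,
                                                       cfg.n_proteins)
                # LOD proteins: both specimens collapse onto a noisy floor
                if len(lod_idx):
                    for arr in (serum, plasma):
                        arr[lod_idx] = lod_floor[lod_idx] + np.abs(
                            rng.normal(0.0, cfg.lod_floor_noise_sd, len(lod_idx)))
                contaminated = (cohort is not None
                                and cohort == cfg.contaminated_cohort)
                if contaminated:
                    plasma[marker_idx] += cfg.contamination_spike_sd \
                        * plasma_sd[marker_idx]
                for spec, arr, rows in (("serum", serum, serum_rows),
                                        ("plasma", plasma, plasma_rows)):
                    if specimen_only and spec != specimen_only:
                        continue
                    sid = f"{tag}_{patient}_{tp}_{spec[0].upper()}"
                    rows.append((sid, arr))
                    meta_rows.append({
                        "sample_id": sid, "patient_id": patient,
                        "cohort_id": cohort if cohort is not None else
                        ("REF_SERUM" if spec == "serum" else "REF_PLASMA"),
                        "specimen": spec, "timepoint": tp,
                        "norm_scale_factor": 1.0,
                        "contaminated": bool(contaminated and spec == "plasma"),
                    })
        return serum_rows, plasma_rows, meta_rows

    serum_rows, plasma_rows, meta_rows = [], [], []
    for cohort in cfg.cohort_ids():
        s, p, m = emit(cohort, cfg.pairs_per_cohort, rng, t1=True)
        serum_rows += s
        plasma_rows += p
        meta_rows += m
    rs_rows, _, rs_meta = emit(None, cfg.n_reference_serum, rng,
                               specimen_only="serum")
    _, rp_rows, rp_meta = emit(None, cfg.n_reference_plasma, rng,
                               specimen_only="plasma")

    def to_matrix(rows, meta) -> ProteomicMatrix:
        values = pd.DataFrame({sid: arr for sid, arr in rows},
                              index=protein_ids).T
        values.index.name = "sample_id"
        md = pd.DataFrame(meta).set_index("sample_id")
        md = md.loc[values.index]
        return ProteomicMatrix(values=values, scale=Scale.LOG2, metadata=md)

    meta_all = meta_rows + rs_meta + rp_meta
    serum = to_matrix(serum_rows, meta_all)
    plasma = to_matrix(plasma_rows, meta_all)
    reference_serum = to_matrix(rs_rows, rs_meta)
    reference_plasma = to_matrix(rp_rows, rp_meta)

    truth_proteins = pd.DataFrame(
        {
            "true_slope": slope,
            "true_intercept": intercept,
            "protein_class": classes,
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    all_meta = pd.DataFrame(meta_all).set_index("sample_id")
    truth_samples = all_meta[["contaminated"]].copy()

    panel = None
    if len(marker_idx):
        panel = MarkerPanel("synthetic_contamination",
                            frozenset(np.array(protein_ids)[marker_idx]),
                            direction="contamination")

    pairs = build_pairs(serum, plasma)
    truth_pairs = pd.DataFrame(
        {"matched": True},
        index=pd.MultiIndex.from_tuples(
            [(k.patient_id, k.timepoint) for k in pairs.pair_index],
            names=("patient_id", "timepoint")),
    )
    data = SyntheticData(serum=serum, plasma=plasma,
                         reference_serum=reference_serum,
                         reference_plasma=reference_plasma,
                         contamination_panel=panel,
                         truth=SyntheticTruth(proteins=truth_proteins,
                                              samples=truth_samples,
                                              pairs=truth_pairs),
                         config=cfg)
    if cfg.n_mismatched:
        mismatch_rng = np.random.default_rng(cfg.seed + 1)
        data = _regenerate_mismatched(data, cfg, mismatch_rng, loadings,
                                      baseline, slope, intercept, cohort_shift,
                                      lod_idx, lod_floor)
    return data


def _regenerate_mismatched(data: SyntheticData, cfg: SynthConfig, rng,
                           loadings, baseline, slope, intercept, cohort_shift,
                           lod_idx, lod_floor) -> SyntheticData:
    """Replace the plasma of n_mismatched random pairs with plasma generated
    from a fresh (different) patient effect, and record the truth flags."""
    pairs = build_pairs(data.serum, data.plasma)
    pick = rng.choice(pairs.n_pairs, size=cfg.n_mismatched, replace=False)
    plasma_values = data.plasma.values.copy()
    truth_pairs = data.truth.pairs.copy()
    for i in pick:
        key = pairs.pair_index[i]
        cohort = data.plasma.metadata.loc[key.plasma_sample_id, "cohort_id"]
        f = _patient_factors(rng, 1, cfg)[0]
        other_serum = baseline + cohort_shift[cohort] + loadings @ f \
            + rng.normal(0.0, cfg.noise_sd, cfg.n_proteins)
        new = slope * other_serum + intercept \
            + rng.normal(0.0, cfg.noise_sd, cfg.n_proteins)
        if len(lod_idx):
            new[lod_idx] = lod_floor[lod_idx] + np.abs(
                rng.normal(0.0, cfg.lod_floor_noise_sd, len(lod_idx)))
        plasma_values.loc[key.plasma_sample_id] = new
        truth_pairs.loc[(key.patient_id, key.timepoint), "matched"] = False
    plasma = ProteomicMatrix(values=plasma_values, scale=Scale.LOG2,
                             metadata=data.plasma.metadata)
    truth = SyntheticTruth(proteins=data.truth.proteins,
                           samples=data.truth.samples, pairs=truth_pairs)
    return replace(data, plasma=plasma, truth=truth)


def inject_pair_mismatches(pd_: PairedDataset, k: int, seed: int):
    """Swap the plasma samples of ``k`` randomly chosen pairs among
    themselves (a seeded derangement of the chosen subset), returning the
    perturbed dataset and a boolean truth flag per pair (True = still
    genuinely matched). The overall sample multiset is preserved.
    """
    n = pd_.n_pairs
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of pairs ({n})")
    if k == 0:
        flags = pd.Series(True, index=range(n), name="matched")
        return pd_, flags
    if k == 1:
        raise ValueError("cannot mismatch a single pair by swapping; use k ≥ 2")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    while True:
        perm = rng.permutation(k)
        if not np.any(perm == np.arange(k)):
            break
    new_keys = list(pd_.pair_index)
    for pos, i in enumerate(chosen):
        donor = chosen[perm[pos]]
        old = new_keys[i]
        new_keys[i] = PairKey(old.patient_id, old.timepoint,
                              old.serum_sample_id,
                              pd_.pair_index[donor].plasma_sample_id)
    plasma = pd_.plasma.subset_samples([kk.plasma_sample_id for kk in new_keys])
    out = PairedDataset(serum=pd_.serum, plasma=plasma, pair_index=new_keys)
    flags = pd.Series(True, index=range(n), name="matched")
    flags.iloc[chosen] = False
    return out, flags
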