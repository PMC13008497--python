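"""Bridging QC: is downstream biological signal preserved after scaling?

Two complementary checks:

* **Prediction agreement** — a plug-in predictor (any deterministic map from
  a log2 matrix to one probability per sample) is applied to the plasma data
  and to the scaled serum data; agreement is quantified with the unity-line
  R² (coefficient of determination against the identity line — penalizes
  additive bias, may be negative), the fitted-line r² (squared Pearson
  correlation — blind to affine bias), and binary class agreement at a
  threshold with a two-sided Fisher exact p. A factor set that introduces a
  systematic bias shows up as r² ≈ 1 with R² collapsing.
* **Pair co-clustering** — after scaling, each serum sample's nearest plasma
  neighbour should be its own mate (mutual-nearest-neighbour fraction), and a
  2-cluster Ward cut should no longer split samples by specimen.

A seeded surrogate predictor (standardized linear score through a logistic
link) stands in for any proprietary downstream model so the whole bridge can
be exercised on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from .core import PairedDataset, ProteomicMatrix, Scale

__all__ = [
    "PredictionAgreement",
    "SurrogatePredictor",
    "surrogate_predictor",
    "prediction_agreement",
    "pair_coclustering",
    "CoclusteringResult",
]


@dataclass(frozen=True)
class PredictionAgreement:
    """Agreement between two probability vectors (plasma as the reference).

    ``r2_unity`` = 1 − Σ(y−x)²/Σ(y−ȳ)² against the identity line (can be
    negative); ``r2_fitted`` = squared Pearson r against the best-fit line
    (always ≥ ``r2_unity``); ``class_agreement_pct`` and its Fisher exact p
    summarize binary concordance at ``threshold``.
    """

    r2_unity: float
    r2_fitted: float
    class_agreement_pct: float
    threshold: float
    p_value: float
    n: int


def prediction_agreement(p_plasma, p_serum_scaled,
                         threshold: float = 0.5) -> PredictionAgreement:
    """Quantify agreement of scaled-serum-based predictions with plasma-based
    predictions.

    The plasma vector is the reference: the unity-line R² uses its variance
    in the denominator. Constant plasma predictions leave R² undefined and
    raise.
    """
    y = np.asarray(p_plasma, dtype=float).ravel()
    x = np.asarray(p_serum_scaled, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("prediction vectors must have equal length")
    if y.size < 5:
        raise ValueError("prediction_agreement requires ≥5 subjects")
    for name, v in (("plasma", y), ("serum", x)):
        if not np.isfinite(v).all() or (v < 0).any() or (v > 1).any():
            raise ValueError(f"{name} probabilities must be finite and in [0, 1]")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("plasma predictions are constant; unity-line R² "
                         "is undefined")
    r2_unity = 1.0 - float(np.sum((y - x) ** 2)) / sst
    if np.std(x) == 0:
        r2_fitted = float("nan")
    else:
        r2_fitted = float(np.corrcoef(x, y)[0, 1] ** 2)
    cls_y = y >= threshold
    cls_x = x >= threshold
    agreement = float(np.mean(cls_y == cls_x) * 100.0)
    table = [[int(np.sum(cls_y & cls_x)), int(np.sum(cls_y & ~cls_x))],
             [int(np.sum(~cls_y & cls_x)), int(np.sum(~cls_y & ~cls_x))]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return PredictionAgreement(r2_unity=r2_unity, r2_fitted=r2_fitted,
                               class_agreement_pct=agreement,
                               threshold=threshold, p_value=float(p),
                               n=int(y.size))


@dataclass(frozen=True)
class SurrogatePredictor:
    """A deterministic stand-in for a proprietary downstream model: a frozen
    linear score on standardized panel proteins through a logistic link.

    Weights are drawn once from ``weights_seed`` and frozen. Standardization
    uses fixed per-protein centers/scales (fitted on a reference matrix when
    one is provided, identity otherwise), so additive biases in the input
    propagate into the score instead of being silently re-normalized away.
    Weights have a positive mean by default, mimicking a risk panel of
    predominantly up-regulated markers; a uniform shift of the input
    therefore moves the score in a consistent direction.
    """

    panel: tuple
    weights: tuple
    center: tuple
    scale: tuple

    @property
    def required_proteins(self) -> set:
        return set(self.panel)

    def predict(self, m: ProteomicMatrix) -> pd.Series:
        """One probability in (0, 1) per sample; fails loudly on missing
        required proteins."""
        if m.scale is not Scale.LOG2:
            raise ValueError("predictor expects a log2 matrix")
        missing = [p for p in self.panel if p not in set(m.protein_ids)]
        if missing:
            raise KeyError(f"matrix lacks {len(missing)} required protein(s): "
                           f"{missing[:5]}")
        x = m.values[list(self.panel)].to_numpy(dtype=float)
        z = (x - np.asarray(self.center)) / np.asarray(self.scale)
        score = z @ np.asarray(self.weights) / np.sqrt(len(self.panel))
        with np.errstate(over="ignore"):
            prob = 1.0 / (1.0 + np.exp(-score))
        # keep the open-interval range of the logistic link in floats
        eps = 1e-12
        prob = np.clip(prob, eps, 1.0 - eps)
        return pd.Series(prob, index=m.values.index, name="probability")


def surrogate_predictor(weights_seed: int, panel,
                        reference: ProteomicMatrix | None = None,
                        weight_loc: float = 0.25,
                        weight_scale: float = 0.7) -> SurrogatePredictor:
    """Build a frozen surrogate predictor over ``panel`` proteins.

    ``reference`` (a log2 matrix) fixes the standardization centers/scales;
    without it, inputs are taken as already standardized. Weights are
    ``weight_loc`` plus a mean-centered N(0, weight_scale²) heterogeneity
    drawn once from ``weights_seed``: the per-panel weight *sum* is fixed at
    ``n·weight_loc`` by construction, so the score's sensitivity to a uniform
    input shift is a design property rather than a draw.
    """
    panel = tuple(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(weights_seed)
    het = rng.normal(0.0, weight_scale, size=len(panel))
    weights = weight_loc + (het - het.mean() if len(panel) > 1 else het)
    if reference is not None:
        missing = [p for p in panel if p not in set(reference.protein_ids)]
        if missing:
            raise KeyError(f"reference lacks panel protein(s): {missing[:5]}")
        vals = reference.values[list(panel)]
        center = vals.mean(axis=0).to_numpy()
        scale = vals.std(axis=0, ddof=1).to_numpy()
        if (scale == 0).any():
            raise ValueError("reference has zero-variance panel proteins")
    else:
        center = np.zeros(len(panel))
        scale = np.ones(len(panel))
    return SurrogatePredictor(panel=panel, weights=tuple(weights),
                              center=tuple(center), scale=tuple(scale))


@dataclass(frozen=True)
class CoclusteringResult:
    """Pair-level co-clustering after scaling: the mutual-nearest-neighbour
    fraction across specimens and the adjusted-Rand agreement between a
    2-cluster Ward cut and the specimen labels (high before scaling, low
    after successful scaling)."""

    mnn_fraction: float
    specimen_split_ari: float
    n_pairs: int


def pair_coclustering(pd_: PairedDataset, ddof: int = 1) -> CoclusteringResult:
    """Euclidean-distance diagnostics on per-protein z-scored profiles of the
    combined serum+plasma sample set.

    A pair is a mutual nearest neighbour when the serum sample's closest
    plasma sample is its own mate and vice versa. The specimen-split score is
    the adjusted Rand index between the 2-cluster Ward cut and specimen
    labels: ≈1 means the specimens still form separate clusters, ≈0 means
    pairs intermingle (the goal after scaling).
    """
    if pd_.n_pairs < 4:
        raise ValueError("pair_coclustering requires ≥4 pairs")
    x = pd_.serum_values()
    y = pd_.plasma_values()
    combined = np.vstack([x, y])
    mean = combined.mean(axis=0)
    sd = combined.std(axis=0, ddof=ddof)
    keep = sd > 0
    z = (combined[:, keep] - mean[keep]) / sd[keep]
    n = pd_.n_pairs
    zs, zp = z[:n], z[n:]
    d = cdist(zs, zp)
    nearest_plasma = d.argmin(axis=1)
    nearest_serum = d.argmin(axis=0)
    mutual = (nearest_plasma == np.arange(n)) & (nearest_serum == np.arange(n))
    ward = linkage(z, method="ward")
    cut = fcluster(ward, t=2, criterion="maxclust")
    specimen = np.array([0] * n + [1] * n)
    ari = float(adjusted_rand_score(specimen, cut))
    return CoclusteringResult(mnn_fraction=float(mutual.mean()),
                              specimen_split_ari=ari, n_pairs=n)
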