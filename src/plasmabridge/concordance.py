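"""Per-protein serum–plasma agreement statistics and selection.

The bridging method rests on the observation that for the vast majority of
proteins, serum and plasma levels are monotonically related across patients.
Rank (Spearman) correlation is the screening statistic of choice because
values compressed near the assay's limit of detection, plus a handful of
far-from-floor outliers, inflate Pearson correlations without implying a
usable protein-wise relationship. Proteins whose Spearman correlation is not
significant after Benjamini–Hochberg adjustment are excluded from bridging.

Also here: the raw-RFU plasma-to-serum ratio classification (coagulation
biology pushes a small minority of proteins to ratios near 100× or 0.01×),
Fisher-exact marker-panel enrichment, and the principal-component /
covariate association diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import PairedDataset, ProteomicMatrix, Scale
from .transform import iqr_bounds, zscore_per_protein

__all__ = [
    "protein_concordance",
    "select_proteins",
    "bh_adjust",
    "ratio_classification",
    "panel_enrichment",
    "pc_association",
    "lod_inflation_diagnostic",
    "rank_group_test",
    "EnrichmentRow",
]

RATIO_CENTRAL = "central"
RATIO_HIGH_PLASMA = "high_plasma"
RATIO_HIGH_SERUM = "high_serum"


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@lru_cache(maxsize=None)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Null distribution of Spearman's rho for untied samples of size n,
    by exhaustive enumeration of rank permutations."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = np.array([1.0 - 6.0 * np.sum((base - np.array(perm)) ** 2) / denom
                     for perm in permutations(base)])
    return rhos


def _spearman_p_exact(rho: float, n: int) -> float:
    null = _exact_spearman_null(n)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def _corr_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two equally shaped arrays."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    den = np.sqrt((xc * xc).sum(axis=0) * (yc * yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _t_approx_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a correlation coefficient via the t approximation."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return p


def protein_concordance(pd_: PairedDataset, exact_max_n: int = 9) -> pd.DataFrame:
    """Per-protein Pearson and Spearman correlation of serum vs plasma across
    pairs, with two-sided Spearman p and BH-adjusted q across all proteins.

    Spearman p-values come from the exact permutation null when n ≤
    ``exact_max_n`` and the ranks are untied, and from the t approximation
    otherwise. Zero-variance proteins get NaN statistics and a
    ``zero_variance`` flag; they are never selected downstream.

    Returns a DataFrame indexed by protein with columns ``pearson_r``,
    ``spearman_r``, ``spearman_p``, ``spearman_q``, ``n_pairs``, ``flag``.
    """
    if pd_.scale is not Scale.LOG2:
        raise ValueError("protein_concordance expects log2-scale data")
    n = pd_.n_pairs
    if n < 5:
        raise ValueError("protein_concordance requires ≥5 pairs")
    x = pd_.serum_values()
    y = pd_.plasma_values()
    pearson = _corr_columns(x, y)
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y, axis=0)
    spearman = _corr_columns(rx, ry)

    spearman_p = _t_approx_p(spearman, n)
    if n <= exact_max_n:
        # exact permutation p where ranks are untied in both specimens
        for j in range(x.shape[1]):
            if np.isnan(spearman[j]):
                continue
            if (np.unique(x[:, j]).size == n and np.unique(y[:, j]).size == n):
                spearman_p[j] = _spearman_p_exact(spearman[j], n)
    valid = ~np.isnan(spearman)
    q = np.full_like(spearman_p, np.nan)
    if valid.any():
        q[valid] = bh_adjust(spearman_p[valid])
    spearman_p = np.where(valid, spearman_p, np.nan)

    flag = np.where(valid, "", "zero_variance")
    return pd.DataFrame(
        {
            "pearson_r": pearson,
            "spearman_r": spearman,
            "spearman_p": spearman_p,
            "spearman_q": q,
            "n_pairs": n,
            "flag": flag,
        },
        index=pd.Index(pd_.protein_ids, name="protein_id"),
    )


def select_proteins(table: pd.DataFrame, q_threshold: float = 0.05,
                    r_floor: float = 0.0) -> set:
    """Proteins passing the concordance screen: BH q < ``q_threshold`` and
    Spearman r ≥ ``r_floor``.

    With many pairs the significance threshold corresponds to a weak
    correlation, so raising ``r_floor`` above 0 is advisable when downstream
    modelling demands tighter serum–plasma agreement.
    """
    q = table["spearman_q"]
    r = table["spearman_r"]
    keep = (q < q_threshold) & (r >= r_floor) & q.notna() & r.notna()
    return set(table.index[keep])


def ratio_classification(pd_: PairedDataset, multiplier: float = 1.5,
                         method: str = "linear") -> pd.DataFrame:
    """Median plasma-to-serum ratio per protein (raw RFU) and its outlier
    class.

    Ratios are computed pair-wise on the raw scale and summarized by the
    median; outlier thresholds are derived on log2 of the median ratios so
    that the two tails (plasma-retained vs serum-accumulated proteins, e.g.
    fibrinogen vs thrombin) are treated symmetrically. Above the upper
    threshold → ``high_plasma``; below the lower → ``high_serum``; otherwise
    ``central``.
    """
    if pd_.scale is not Scale.RAW_RFU:
        raise ValueError("ratio_classification expects raw-RFU data")
    ratios = pd_.plasma_values() / pd_.serum_values()
    med = np.median(ratios, axis=0)
    log2_med = np.log2(med)
    bounds = iqr_bounds(log2_med, multiplier=multiplier, method=method)
    cls = np.where(log2_med > bounds.upper, RATIO_HIGH_PLASMA,
                   np.where(log2_med < bounds.lower, RATIO_HIGH_SERUM,
                            RATIO_CENTRAL))
    return pd.DataFrame(
        {
            "median_plasma_serum_ratio": med,
            "log2_median_ratio": log2_med,
            "ratio_class": cls,
        },
        index=pd.Index(pd_.protein_ids, name="protein_id"),
    )


@dataclass(frozen=True)
class EnrichmentRow:
    panel_id: str
    overlap: int
    panel_size: int
    selection_size: int
    universe_size: int
    odds_ratio: float
    fisher_p: float
    fisher_q: float = math.nan
    enriched: bool = False


def panel_enrichment(selected, universe, panels, fdr: float = 0.1) -> list:
    """Two-sided Fisher exact enrichment of each marker panel in a protein
    selection, BH-adjusted across panels; enriched = q < ``fdr``.

    Panels with no measured member (empty intersection with the universe) are
    skipped with a warning.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected proteins must be a subset of the universe")
    rows = []
    for panel in panels:
        panel_in = panel.protein_ids & universe
        if not panel_in:
            warnings.warn(f"panel {panel.panel_id!r} disjoint from universe; "
                          "skipped", stacklevel=2)
            continue
        k = len(selected & panel_in)
        big_k = len(panel_in)
        n_sel = len(selected)
        big_n = len(universe)
        table = [[k, n_sel - k],
                 [big_k - k, big_n - big_k - (n_sel - k)]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(EnrichmentRow(panel_id=panel.panel_id, overlap=k,
                                  panel_size=big_k, selection_size=n_sel,
                                  universe_size=big_n, odds_ratio=float(odds),
                                  fisher_p=float(p)))
    if not rows:
        return []
    q = bh_adjust([r.fisher_p for r in rows])
    return [EnrichmentRow(**{**r.__dict__, "fisher_q": float(qi),
                             "enriched": bool(qi < fdr)})
            for r, qi in zip(rows, q)]


def lod_inflation_diagnostic(pd_: PairedDataset,
                             table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Diagnose Pearson-inflation by limit-of-detection compression.

    Proteins whose values pile up near the assay floor, with a few
    far-from-floor outliers, show Pearson ≫ Spearman. Per protein this
    reports the inflation gap ``pearson_r − spearman_r`` together with a
    distance-from-floor statistic: the median log2 value minus the
    1st-percentile value of that protein across all samples of both
    specimens. Floor-compressed proteins have small distances and tend to
    have large gaps (a negative rank correlation between the two columns).
    """
    if table is None:
        table = protein_concordance(pd_)
    combined = np.vstack([pd_.serum_values(), pd_.plasma_values()])
    floor = np.percentile(combined, 1.0, axis=0)
    distance = np.median(combined, axis=0) - floor
    out = pd.DataFrame(
        {
            "pearson_minus_spearman": (table["pearson_r"]
                                       - table["spearman_r"]),
            "distance_from_floor": pd.Series(distance, index=table.index),
        },
        index=table.index,
    )
    return out


def rank_group_test(values, labels) -> float:
    """Two-sided rank test of ``values`` across the levels of ``labels``:
    Mann–Whitney U for two levels, Kruskal–Wallis for more. Returns the
    p-value. Used for PC–covariate association and for comparing
    correlation populations (e.g. within-patient vs between-patient)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("rank_group_test needs at least 2 label levels")
    groups = [values[labels == lev] for lev in levels]
    if len(levels) == 2:
        _, p = stats.mannwhitneyu(groups[0], groups[1],
                                  alternative="two-sided")
    else:
        _, p = stats.kruskal(*groups)
    return float(p)


def pc_association(m: ProteomicMatrix, labels, n_components: int = 20,
                   normalize: str = "zscore", ddof: int = 1,
                   random_state: int = 0) -> pd.DataFrame:
    """Association of top principal components with a categorical covariate.

    The matrix is per-protein z-scored by default before the decomposition
    (``normalize="none"`` keeps raw log2). Each component's scores are
    compared across label levels with a rank test: Mann–Whitney U for two
    levels, Kruskal–Wallis for more. Returns a DataFrame with 1-based ``pc``,
    ``explained_variance_ratio`` and ``p_value``.
    """
    labels = pd.Series(np.asarray(labels), index=m.values.index)
    levels = labels.unique()
    if len(levels) < 2:
        raise ValueError("labels must have at least 2 levels")
    if normalize == "zscore":
        data = zscore_per_protein(m, ddof=ddof).values.to_numpy(dtype=float)
    elif normalize == "none":
        data = m.values.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown normalize option {normalize!r}")
    n_components = min(n_components, m.n_samples - 1, m.n_proteins)
    pca = PCA(n_components=n_components, random_state=random_state)
    scores = pca.fit_transform(data)
    pvals = [rank_group_test(scores[:, j], labels.to_numpy())
             for j in range(n_components)]
    return pd.DataFrame({
        "pc": np.arange(1, n_components + 1),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "p_value": pvals,
    })
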