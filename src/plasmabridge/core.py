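"""Core containers for paired serum/plasma proteomic data.

The central object is :class:`ProteomicMatrix`, a samples × proteins table of
relative fluorescence units (RFU, the aptamer assay's unit of relative protein
abundance) or their log2 transform, together with per-sample metadata
(patient, cohort, specimen type, timepoint, assay normalization scale factor).
:class:`PairedDataset` aligns a serum and a plasma matrix sample-by-sample on
the (patient, timepoint) key and is the substrate for concordance screening
and scaling-factor estimation.

Matrices must be complete: a missing cell is a hard error, never silently
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Specimen",
    "ProteomicMatrix",
    "PairKey",
    "PairedDataset",
    "MarkerPanel",
    "build_pairs",
    "REQUIRED_METADATA_COLUMNS",
]


class Scale(str, Enum):
    """Measurement scale of a matrix: raw RFU or log2(RFU)."""

    RAW_RFU = "raw_rfu"
    LOG2 = "log2"


class Specimen(str, Enum):
    SERUM = "serum"
    PLASMA = "plasma"


#: Metadata columns every sample must carry.
REQUIRED_METADATA_COLUMNS = ("patient_id", "cohort_id", "specimen", "timepoint")


def _format_offenders(items: Sequence, limit: int = 10) -> str:
    items = list(items)
    shown = ", ".join(str(x) for x in items[:limit])
    if len(items) > limit:
        shown += f", … ({len(items)} total)"
    return shown


@dataclass
class ProteomicMatrix:
    """A complete samples × proteins measurement table with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are protein (analyte) ids.
        No missing cells are allowed; raw-RFU values must be strictly
        positive.
    scale
        Whether ``values`` holds raw RFU or log2(RFU).
    metadata
        Per-sample table indexed by sample id. Must cover every sample and
        contain ``patient_id``, ``cohort_id``, ``specimen`` and ``timepoint``;
        ``norm_scale_factor`` (the assay's per-sample QC metric) and
        ``prep_protocol`` are optional.
    flags
        Per-protein processing flags (e.g. ``zero_variance``) accumulated by
        transforms; informational, never silently consumed.
    """

    values: pd.DataFrame
    scale: Scale
    metadata: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (samples × proteins)")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {_format_offenders(dups)}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {_format_offenders(dups)}")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))
            cells = [(v.index[i], v.columns[j]) for i, j in bad[:10]]
            raise ValueError(
                "matrix contains missing/non-finite cells (sample, protein): "
                f"{_format_offenders(cells)}; total {len(bad)}"
            )
        if self.scale is Scale.RAW_RFU and arr.size and (arr <= 0).any():
            bad = np.argwhere(arr <= 0)
            cells = [(v.index[i], v.columns[j]) for i, j in bad[:10]]
            raise ValueError(
                "raw RFU values must be strictly positive; offending cells: "
                f"{_format_offenders(cells)}; total {len(bad)}"
            )
        md = self.metadata
        if not isinstance(md, pd.DataFrame):
            raise TypeError("metadata must be a pandas DataFrame indexed by sample id")
        missing_meta = v.index.difference(md.index)
        if len(missing_meta):
            raise ValueError(
                f"samples without metadata: {_format_offenders(missing_meta.tolist())}"
            )
        missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
        if missing_cols:
            raise ValueError(f"metadata missing required columns: {missing_cols}")
        if "norm_scale_factor" in md.columns:
            nsf = pd.to_numeric(md.loc[v.index, "norm_scale_factor"], errors="coerce")
            bad = nsf.index[(nsf <= 0) & nsf.notna()].tolist()
            if bad:
                raise ValueError(
                    f"non-positive norm_scale_factor for samples: {_format_offenders(bad)}"
                )
        # keep metadata restricted & aligned to the matrix samples
        self.metadata = md.loc[v.index].copy()

    # ------------------------------------------------------------------ views
    @property
    def sample_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def protein_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: Scale | None = None,
                    extra_flags: dict | None = None) -> "ProteomicMatrix":
        """Return a new matrix sharing this one's metadata."""
        flags = dict(self.flags)
        if extra_flags:
            flags.update(extra_flags)
        return ProteomicMatrix(values=values, scale=scale or self.scale,
                               metadata=self.metadata, flags=flags)

    def subset_samples(self, sample_ids: Sequence) -> "ProteomicMatrix":
        return ProteomicMatrix(values=self.values.loc[list(sample_ids)],
                               scale=self.scale, metadata=self.metadata,
                               flags=dict(self.flags))

    def subset_proteins(self, protein_ids: Sequence) -> "ProteomicMatrix":
        return ProteomicMatrix(values=self.values.loc[:, list(protein_ids)],
                               scale=self.scale, metadata=self.metadata,
                               flags=dict(self.flags))

    def subset_cohort(self, cohort_id: str) -> "ProteomicMatrix":
        keep = self.metadata.index[self.metadata["cohort_id"] == cohort_id]
        if len(keep) == 0:
            raise KeyError(f"no samples with cohort_id={cohort_id!r}")
        return self.subset_samples(keep)

    def specimen_type(self) -> str | None:
        """The single specimen label of this matrix, or None if mixed."""
        levels = self.metadata["specimen"].unique()
        return str(levels[0]) if len(levels) == 1 else None


class PairKey(NamedTuple):
    patient_id: str
    timepoint: str
    serum_sample_id: str
    plasma_sample_id: str


@dataclass
class PairedDataset:
    """Two specimen-aligned matrices indexed by (patient, timepoint) pairs.

    Row *i* of ``serum.values`` and row *i* of ``plasma.values`` belong to the
    same (patient, timepoint) pair, recorded in ``pair_index[i]``. Protein
    columns are identical (same ids, same order) in both matrices.
    """

    serum: ProteomicMatrix
    plasma: ProteomicMatrix
    pair_index: list
    unpaired: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.serum.protein_ids != self.plasma.protein_ids:
            raise ValueError("serum and plasma matrices must share identical "
                             "protein ids in identical order")
        if self.serum.scale is not self.plasma.scale:
            raise ValueError("serum and plasma matrices must share the same scale")
        n = len(self.pair_index)
        if self.serum.n_samples != n or self.plasma.n_samples != n:
            raise ValueError("matrices must contain exactly the paired samples, "
                             "in pair order")
        self.pair_index = [PairKey(*k) for k in self.pair_index]
        for i, key in enumerate(self.pair_index):
            if (self.serum.sample_ids[i] != key.serum_sample_id
                    or self.plasma.sample_ids[i] != key.plasma_sample_id):
                raise ValueError("pair_index does not match matrix row order")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)

    @property
    def protein_ids(self) -> list:
        return self.serum.protein_ids

    @property
    def scale(self) -> Scale:
        return self.serum.scale

    def serum_values(self) -> np.ndarray:
        return self.serum.values.to_numpy(dtype=float)

    def plasma_values(self) -> np.ndarray:
        return self.plasma.values.to_numpy(dtype=float)

    def pair_cohorts(self) -> pd.Series:
        """Cohort of each pair (taken from the serum-side metadata)."""
        coh = self.serum.metadata["cohort_id"]
        return pd.Series([coh[k.serum_sample_id] for k in self.pair_index],
                         index=range(self.n_pairs), name="cohort_id")

    def subset_pairs(self, indices: Sequence[int]) -> "PairedDataset":
        indices = list(indices)
        keys = [self.pair_index[i] for i in indices]
        return PairedDataset(
            serum=self.serum.subset_samples([k.serum_sample_id for k in keys]),
            plasma=self.plasma.subset_samples([k.plasma_sample_id for k in keys]),
            pair_index=keys,
        )

    def subset_proteins(self, protein_ids: Sequence) -> "PairedDataset":
        return PairedDataset(
            serum=self.serum.subset_proteins(protein_ids),
            plasma=self.plasma.subset_proteins(protein_ids),
            pair_index=list(self.pair_index),
            unpaired=dict(self.unpaired),
        )

    def subset_cohort(self, cohort_id: str) -> "PairedDataset":
        keep = [i for i, c in self.pair_cohorts().items() if c == cohort_id]
        if not keep:
            raise KeyError(f"no pairs with cohort_id={cohort_id!r}")
        return self.subset_pairs(keep)

    def drop_pairs(self, keys: Sequence[PairKey]) -> "PairedDataset":
        drop = {PairKey(*k) for k in keys}
        keep = [i for i, k in enumerate(self.pair_index) if k not in drop]
        return self.subset_pairs(keep)


@dataclass(frozen=True)
class MarkerPanel:
    """A named set of marker proteins (e.g. platelet/erythrocyte contamination
    markers, plasma-retained or serum-accumulated coagulation factors)."""

    panel_id: str
    protein_ids: frozenset
    direction: str = "contamination"

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError(f"panel {self.panel_id!r} is empty")
        object.__setattr__(self, "protein_ids", frozenset(self.protein_ids))

    def intersect(self, universe: Sequence) -> "MarkerPanel":
        """Restrict the panel to measured proteins; warn about the rest."""
        universe = set(universe)
        kept = self.protein_ids & universe
        missing = self.protein_ids - universe
        if missing:
            warnings.warn(
                f"panel {self.panel_id!r}: {len(missing)} member(s) not measured: "
                f"{_format_offenders(sorted(missing))}", stacklevel=2)
        if not kept:
            raise ValueError(f"panel {self.panel_id!r} has no measured proteins")
        return MarkerPanel(self.panel_id, frozenset(kept), self.direction)


def build_pairs(serum: ProteomicMatrix, plasma: ProteomicMatrix) -> PairedDataset:
    """Join two matrices into serum–plasma pairs on the exact
    (patient_id, timepoint) key.

    Proteins are intersected and reordered identically (first argument's
    order). Unpaired samples are reported in ``PairedDataset.unpaired`` and via
    a warning, never silently dropped. Two samples with the same key on one
    side make the join ambiguous and raise.
    """

    def keyed(m: ProteomicMatrix, side: str) -> dict:
        md = m.metadata
        keys = list(zip(md["patient_id"].astype(str), md["timepoint"].astype(str)))
        seen: dict = {}
        for sid, key in zip(md.index, keys):
            if key in seen:
                raise ValueError(
                    f"ambiguous pairing key {key} on {side} side: samples "
                    f"{seen[key]!r} and {sid!r}")
            seen[key] = sid
        return seen

    serum_keys = keyed(serum, "serum")
    plasma_keys = keyed(plasma, "plasma")
    shared_keys = sorted(set(serum_keys) & set(plasma_keys))
    if not shared_keys:
        raise ValueError("no (patient_id, timepoint) keys shared between the "
                         "two matrices; zero pairs")
    shared_proteins = [p for p in serum.protein_ids if p in set(plasma.protein_ids)]
    if not shared_proteins:
        raise ValueError("the two matrices share no proteins")

    pair_index = [PairKey(pat, tp, serum_keys[(pat, tp)], plasma_keys[(pat, tp)])
                  for pat, tp in shared_keys]
    unpaired = {
        "serum": sorted(sid for key, sid in serum_keys.items()
                        if key not in plasma_keys),
        "plasma": sorted(sid for key, sid in plasma_keys.items()
                         if key not in serum_keys),
    }
    n_orphans = len(unpaired["serum"]) + len(unpaired["plasma"])
    if n_orphans:
        warnings.warn(
            f"{n_orphans} unpaired sample(s) dropped from the paired dataset: "
            f"serum {_format_offenders(unpaired['serum'])}; "
            f"plasma {_format_offenders(unpaired['plasma'])}", stacklevel=2)

    s = serum.subset_proteins(shared_proteins).subset_samples(
        [k.serum_sample_id for k in pair_index])
    p = plasma.subset_proteins(shared_proteins).subset_samples(
        [k.plasma_sample_id for k in pair_index])
    return PairedDataset(serum=s, plasma=p, pair_index=pair_index,
                         unpaired=unpaired)
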