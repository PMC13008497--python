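"""Readers and writers for the delimited-text interchange formats.

* Matrix: wide TSV/CSV, first column ``sample_id``, remaining columns protein
  ids. Metadata: TSV keyed by ``sample_id`` with required columns
  ``patient_id``, ``cohort_id``, ``specimen``, ``timepoint`` and optional
  ``norm_scale_factor``, ``prep_protocol``.
* Panels: plain text one protein id per line, or a two-column TSV
  ``protein_id<TAB>panel_id``.
* Factor tables: TSV with columns ``protein_id``, ``slope``, ``intercept``,
  ``n_pairs``, ``pearson_r``, ``residual_sd``, ``spearman_r``, ``spearman_p``,
  ``spearman_q``; floats written with 9 significant digits.

Matrices are written at full float precision so read∘write is the identity.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MarkerPanel, ProteomicMatrix, Scale
from .scaling import FACTOR_TABLE_COLUMNS, ScalingFactorSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_panels",
    "write_factor_table",
    "read_factor_table",
]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    if "sample_id" not in md.columns:
        raise ValueError(f"{path}: metadata must have a sample_id column")
    if md["sample_id"].duplicated().any():
        dups = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id rows: {dups[:10]}")
    return md.set_index("sample_id")


def read_matrix(path, metadata_path, value_scale: Scale | str,
                transpose: bool = False) -> ProteomicMatrix:
    """Read a wide measurement matrix plus its metadata table.

    The file is taken as samples-in-rows; set ``transpose=True`` explicitly
    for proteins-in-rows files (never auto-transposed silently). Missing
    cells, duplicate ids, non-positive raw RFUs and samples without metadata
    all raise with the offenders named.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if transpose:
        df = df.T
    df.index.name = "sample_id"
    metadata = read_metadata(metadata_path)
    return ProteomicMatrix(values=df, scale=Scale(value_scale),
                           metadata=metadata)


def write_matrix(m: ProteomicMatrix, path, metadata_path=None) -> None:
    m.values.to_csv(path, sep=_sep_for(path), float_format="%.17g",
                    index_label="sample_id")
    if metadata_path is not None:
        write_metadata(m.metadata, metadata_path)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_panels(path, direction: str = "contamination") -> list:
    """Read marker panels: either one protein id per line (a single panel
    named after the file stem) or a two-column TSV (protein_id, panel_id)."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty panel file")
    if any("\t" in ln for ln in lines):
        pairs = [ln.split("\t")[:2] for ln in lines]
        if pairs and pairs[0][0] in ("protein_id",):
            pairs = pairs[1:]
        by_panel: dict = {}
        for protein, panel in pairs:
            by_panel.setdefault(panel, set()).add(protein)
        return [MarkerPanel(panel_id=pid, protein_ids=frozenset(members),
                            direction=direction)
                for pid, members in sorted(by_panel.items())]
    return [MarkerPanel(panel_id=path.stem, protein_ids=frozenset(lines),
                        direction=direction)]


def write_factor_table(factors: ScalingFactorSet, path) -> None:
    """Write a factor set as TSV (floats at 9 significant digits). An empty
    set produces a header-only file plus a warning."""
    t = factors.table.copy()
    for col in FACTOR_TABLE_COLUMNS:
        if col not in t.columns:
            t[col] = np.nan
    t = t[list(FACTOR_TABLE_COLUMNS)]
    if len(t) == 0:
        warnings.warn(f"writing empty factor table to {path}", stacklevel=2)
    t.to_csv(path, sep=_sep_for(path), float_format="%.9g",
             index_label="protein_id")


def read_factor_table(path, provenance: str = "file") -> ScalingFactorSet:
    t = pd.read_csv(path, sep=_sep_for(path), index_col="protein_id")
    missing = [c for c in ("slope", "intercept", "n_pairs") if c not in t.columns]
    if missing:
        raise ValueError(f"{path}: factor table missing columns {missing}")
    if len(t):
        t["n_pairs"] = t["n_pairs"].astype(int)
    return ScalingFactorSet(table=t, provenance=provenance)
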