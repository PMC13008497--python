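"""Shared fixtures: small hand-built matrices and reusable synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from plasmabridge import ProteomicMatrix, Scale, SynthConfig, generate_cohorts


def make_matrix(values, scale=Scale.LOG2, specimen="serum", cohort="A",
                sample_prefix=None, protein_ids=None, patients=None,
                timepoints=None, nsf=None):
    """Build a small ProteomicMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    prefix = sample_prefix or specimen[0].upper()
    sample_ids = [f"{prefix}{i}" for i in range(n)]
    protein_ids = protein_ids or [f"PROT{j}" for j in range(p)]
    patients = patients or [f"pt{i}" for i in range(n)]
    timepoints = timepoints or ["T0"] * n
    md = pd.DataFrame(
        {
            "patient_id": patients,
            "cohort_id": cohort,
            "specimen": specimen,
            "timepoint": timepoints,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if nsf is not None:
        md["norm_scale_factor"] = nsf
    df = pd.DataFrame(values, index=md.index, columns=protein_ids)
    return ProteomicMatrix(values=df, scale=scale, metadata=md)


def make_pairs(serum_values, plasma_values, scale=Scale.LOG2, protein_ids=None):
    """Build a PairedDataset from two aligned arrays (row i pairs with row i)."""
    from plasmabridge import build_pairs

    n = np.asarray(serum_values).shape[0]
    patients = [f"pt{i}" for i in range(n)]
    s = make_matrix(serum_values, scale=scale, specimen="serum",
                    protein_ids=protein_ids, patients=patients)
    p = make_matrix(plasma_values, scale=scale, specimen="plasma",
                    protein_ids=protein_ids, patients=patients)
    return build_pairs(s, p)


@pytest.fixture(scope="session")
def clean_cohorts():
    """Three clean cohorts with references; reused by QC and pipeline tests."""
    cfg = SynthConfig(seed=101, n_cohorts=3, pairs_per_cohort=25, n_proteins=200,
                      contaminated_cohort=None, contamination_panel_size=0,
                      n_reference_serum=40, n_reference_plasma=40)
    return generate_cohorts(cfg)


@pytest.fixture(scope="session")
def contaminated_cohorts():
    """Three cohorts where cohort C's plasma carries a 1.5-sd marker spike."""
    cfg = SynthConfig(seed=202, n_cohorts=3, pairs_per_cohort=20, n_proteins=150,
                      contamination_panel_size=15, contamination_spike_sd=1.5,
                      contaminated_cohort="C", t1_fraction=0,
                      n_reference_serum=40, n_reference_plasma=50)
    return generate_cohorts(cfg)
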