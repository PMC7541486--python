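"""Shared fixtures: all data are generated programmatically at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import anndata as ad

from episcope.core import AnnotatedCounts
from episcope.syndata import CohortConfig, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def make_annotated(counts, samples, conditions, subtypes, classes=None, genes=None):
    """Hand-build a small AnnotatedCounts from per-cell vectors."""
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(g)]
    classes = classes or ["principal"] * n
    obs = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": conditions,
            "level1": ["root"] * n,
            "level2": ["fam"] * n,
            "level3": ["sub"] * n,
            "level4": subtypes,
            "class": classes,
        },
        index=pd.Index([f"cell{i}" for i in range(n)], name="cell_id"),
    )
    adata = ad.AnnData(
        X=sp.csr_matrix(counts), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    )
    return AnnotatedCounts(adata)


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects."""
    cfg = CohortConfig(
        n_control_samples=5, n_case_samples=4, n_subtypes=6,
        cells_per_sample_per_subtype=15, n_genes=250, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one DE-perturbed and composition-shifted subtype per class."""
    cfg = CohortConfig(
        n_control_samples=6, n_case_samples=5, n_subtypes=6,
        cells_per_sample_per_subtype=25, n_genes=400,
        affected_subtypes=[("Pvalb_Lamp5", 60, 2.0), ("L2_Cux2_Lamp5", 60, 2.0)],
        composition_shifts=[("Pvalb_Lamp5", 0.4)],
        seed=7,
    )
    return generate_cohort(cfg)
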