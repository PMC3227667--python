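"""Shared fixtures: small genotype tables built in memory or on tmp_path."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from miscore import PathwayModel


def make_samples(
    n_cases: int,
    n_controls: int,
    strata=None,
    prefix: str = "S",
) -> pd.DataFrame:
    """Sample sheet with deterministic ids; strata defaults to one group."""
    n = n_cases + n_controls
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    if strata is None:
        strata = ["Hispanic"] * n
    return pd.DataFrame(
        {
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "stratum": list(strata),
        },
        index=pd.Index(ids, name="sample_id"),
    )


def make_matrix(values, variant_ids=None, sample_ids=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return pd.DataFrame(
        values,
        index=pd.Index(
            sample_ids or [f"S{i:03d}" for i in range(n)], name="sample_id"
        ),
        columns=variant_ids or [f"GENE_{j + 1}" for j in range(m)],
    )


def make_variants(variant_ids, genes=None, classes=None) -> pd.DataFrame:
    m = len(variant_ids)
    return pd.DataFrame(
        {
            "gene": genes or [v.split("_")[0] for v in variant_ids],
            "functional_class": classes or ["nonsynonymous"] * m,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )


@pytest.fixture
def one_gene_model() -> PathwayModel:
    """A beneficial gene and a competing gene for one metabolite."""
    return PathwayModel(
        signs={"purine": {"GOODGENE": 1, "BADGENE": -1}},
        compartments={"GOODGENE": "cytoplasmic", "BADGENE": "cytoplasmic"},
    )


@pytest.fixture
def toy_cohort():
    """8 individuals × 4 variants across two signed genes, complete data."""
    variant_ids = ["GOODGENE_1", "GOODGENE_2", "BADGENE_1", "BADGENE_2"]
    values = [
        [2, 0, 0, 0],
        [1, 0, 0, 0],
        [0, 0, 1, 0],
        [0, 0, 2, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 1],
        [1, 0, 2, 0],
        [0, 0, 0, 0],
    ]
    matrix = make_matrix(values, variant_ids)
    variants = make_variants(variant_ids)
    samples = make_samples(4, 4)
    return matrix, variants, samples
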