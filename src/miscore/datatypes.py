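"""Core domain containers and vocabulary.

The package works on four aligned tables:

* a **genotype matrix** — a :class:`pandas.DataFrame` of minor-allele
  dosages, rows indexed by sample id, columns by variant id; entries are
  floats in ``{0.0, 1.0, 2.0}`` with :data:`numpy.nan` marking a missing
  genotype (missingness is an explicit state, never silently imputed);
* a **variant table** — one row per variant (gene, functional class,
  ref/alt alleles, coordinate);
* a **sample table** — one row per individual (case/control status,
  race-ethnicity stratum, optional covariates);
* a **pathway model** — per-metabolite gene signs (+1 beneficial,
  -1 detrimental/competing) plus a cytoplasmic/mitochondrial compartment
  tag per signed gene.

Validation helpers raise :class:`ValueError` with the offending ids so
callers can surface broken inputs directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FUNCTIONAL_CLASSES = (
    "non_coding",
    "nonsynonymous",
    "synonymous",
    "truncation",
    "frameshift",
)

METABOLITES = ("purine", "thymidylate", "homocysteine")

COMPARTMENTS = ("cytoplasmic", "mitochondrial")

#: Sentinel stratum label meaning "the whole cohort, unstratified".
ALL_STRATA = "all"

STATUS_VALUES = ("case", "control")


class DataValidationError(ValueError):
    """An input table violated a structural contract."""


def validate_genotype_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check dosage-matrix invariants and return the matrix as float.

    Every non-missing entry must be 0, 1 or 2; sample and variant ids
    must be unique.
    """
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate sample ids: {dups}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate variant ids: {dups}")
    values = matrix.to_numpy(dtype=float, copy=True)
    ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise DataValidationError(
            f"dosage out of {{0,1,2,missing}} at sample "
            f"{matrix.index[i]!r}, variant {matrix.columns[j]!r}: "
            f"{values[i, j]!r}"
        )
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)

def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Check the variant annotation table (indexed by variant id)."""
    required = {"gene", "functional_class"}
    missing = required - set(variants.columns)
    if missing:
        raise DataValidationError(f"variant table lacks columns: {sorted(missing)}")
    if variants.index.has_duplicates:
        dups = variants.index[variants.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate variant ids in annotation: {dups}")
    bad = variants.loc[~variants["functional_class"].isin(FUNCTIONAL_CLASSES)]
    if len(bad):
        row = bad.iloc[0]
        raise DataValidationError(
            f"unknown functional class {row['functional_class']!r} for "
            f"variant {bad.index[0]!r} (allowed: {FUNCTIONAL_CLASSES})"
        )
    return variants


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet (indexed by sample id)."""
    required = {"status", "stratum"}
    missing = required - set(samples.columns)
    if missing:
        raise DataValidationError(f"sample table lacks columns: {sorted(missing)}")
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate sample ids: {dups}")
    bad = samples.loc[~samples["status"].isin(STATUS_VALUES)]
    if len(bad):
        raise DataValidationError(
            f"status must be one of {STATUS_VALUES}; offending sample "
            f"{bad.index[0]!r}: {bad.iloc[0]['status']!r}"
        )
    empty = samples["stratum"].isna() | (samples["stratum"].astype(str) == "")
    if empty.any():
        raise DataValidationError(
            f"empty stratum for sample {samples.index[empty][0]!r}"
        )
    return samples


def stratum_mask(samples: pd.DataFrame, stratum: str) -> pd.Series:
    """Boolean mask over the sample table for one stratum (or ``"all"``)."""
    if stratum == ALL_STRATA:
        return pd.Series(True, index=samples.index)
    mask = samples["stratum"] == stratum
    if not mask.any():
        raise DataValidationError(f"stratum {stratum!r} absent from sample table")
    return mask


def case_mask(labels) -> np.ndarray:
    """Normalise case/control labels to a boolean case indicator array.

    Accepts ``"case"``/``"control"`` strings, booleans, or 0/1 integers.
    """
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        bad = ~np.isin(arr, STATUS_VALUES)
        if bad.any():
            raise DataValidationError(
                f"label {arr[bad][0]!r} is not 'case'/'control'"
            )
        return arr == "case"
    if arr.dtype.kind == "b":
        return arr.copy()
    if np.isin(arr, (0, 1)).all():
        return arr.astype(bool)
    raise DataValidationError("labels must be case/control, bool, or 0/1")


@dataclass(frozen=True)
class PathwayModel:
    """Signed gene sets per metabolite with compartment tags.

    ``signs[metabolite][gene]`` is +1 (variants in the gene push the
    metabolite's output up — "beneficial") or -1 (the gene competes with
    or drains the output — "detrimental").  Genes absent from a
    metabolite's mapping carry no sign and contribute nothing to that
    metabolite's Metabolic Index Score.  Every signed gene must carry a
    compartment tag (cytoplasmic or mitochondrial).
    """

    signs: Mapping[str, Mapping[str, int]]
    compartments: Mapping[str, str]

    def __post_init__(self) -> None:
        for metabolite, genes in self.signs.items():
            for gene, sign in genes.items():
                if sign not in (1, -1):
                    raise DataValidationError(
                        f"sign for ({metabolite}, {gene}) must be +1 or -1, "
                        f"got {sign!r}"
                    )
                if gene not in self.compartments:
                    raise DataValidationError(
                        f"signed gene {gene!r} has no compartment tag"
                    )
        for gene, comp in self.compartments.items():
            if comp not in COMPARTMENTS:
                raise DataValidationError(
                    f"compartment for {gene!r} must be one of {COMPARTMENTS}, "
                    f"got {comp!r}"
                )

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(self.signs)

    def sign(self, metabolite: str, gene: str) -> int | None:
        """Sign of *gene* for *metabolite*, or None if unsigned."""
        if metabolite not in self.signs:
            raise KeyError(f"metabolite {metabolite!r} absent from model")
        return self.signs[metabolite].get(gene)

    def signed_genes(
        self, metabolite: str, compartment: str = "all"
    ) -> dict[str, int]:
        """Gene → sign for one metabolite, optionally compartment-filtered."""
        if metabolite not in self.signs:
            raise KeyError(f"metabolite {metabolite!r} absent from model")
        genes = dict(self.signs[metabolite])
        if compartment != "all":
            if compartment not in COMPARTMENTS:
                raise DataValidationError(
                    f"compartment filter must be 'all' or one of {COMPARTMENTS}"
                )
            genes = {
                g: s for g, s in genes.items()
                if self.compartments[g] == compartment
            }
        return genes

    def negated(self) -> "PathwayModel":
        """A copy of the model with every sign flipped."""
        return PathwayModel(
            signs={m: {g: -s for g, s in gs.items()} for m, gs in self.signs.items()},
            compartments=dict(self.compartments),
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and analysis grid for a full pipeline run.

    Defaults mirror the analysis this package models: common/rare split
    at a within-stratum MAF of 2.5%, LD pruning at dosage R^2 > 0.8,
    QC exclusion of samples/variants with more than 25% missing data.
    """

    maf_threshold: float = 0.025
    ld_r2_threshold: float = 0.8
    missingness_threshold: float = 0.25
    n_permutations: int = 10_000
    rng_seed: int = 0
    variant_subsets: Sequence[tuple[str, str]] = (
        ("nonsynonymous", "common"),
        ("nonsynonymous", "rare"),
        ("non_coding", "common"),
        ("non_coding", "rare"),
    )
    strata_to_analyze: Sequence[str] | None = None  # None → all + pooled

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "ld_r2_threshold", "missingness_threshold"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise DataValidationError(f"{name} must be in (0, 1), got {value}")
        if self.n_permutations < 1:
            raise DataValidationError("n_permutations must be >= 1")
        for class_filter, maf_bin in self.variant_subsets:
            if maf_bin not in ("common", "rare", "all"):
                raise DataValidationError(f"unknown MAF bin {maf_bin!r}")
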