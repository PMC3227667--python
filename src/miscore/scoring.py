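"""Variant subsetting, unweighted burden sums, and the signed
Metabolic Index Score (MIS).

The burden of an individual is the plain count of minor alleles over a
variant subset: 1 per heterozygote, 2 per minor-allele homozygote.  The
MIS layers a pathway model on top: each variant's dosage enters with the
sign of its gene for the chosen metabolite (+1 for genes whose activity
is beneficial to the metabolic output, -1 for genes that compete with
it), so a minor-allele homozygote in a beneficial gene contributes +2
and a heterozygote in a competing gene contributes -1.  Every gene and
every variant within a gene carries identical weight; variants in genes
the model leaves unsigned for a metabolite contribute 0.

Subsets combine a functional-class filter with a within-stratum MAF bin:
``common`` means stratum MAF >= the threshold (default 2.5%, boundary
inclusive), ``rare`` means strictly below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ALL_STRATA,
    DataValidationError,
    FUNCTIONAL_CLASSES,
    PathwayModel,
)
from .io import compute_maf


@dataclass(frozen=True)
class VariantSubset:
    """A resolved variant selection with its provenance."""

    members: tuple[str, ...]
    class_filter: tuple[str, ...]
    maf_bin: str
    stratum: str
    maf_threshold: float = 0.025

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0

    def __len__(self) -> int:
        return len(self.members)


def _normalize_classes(class_filter) -> tuple[str, ...]:
    if class_filter in (None, "all"):
        return tuple(FUNCTIONAL_CLASSES)
    if isinstance(class_filter, str):
        class_filter = (class_filter,)
    unknown = set(class_filter) - set(FUNCTIONAL_CLASSES)
    if unknown:
        raise DataValidationError(f"unknown functional classes: {sorted(unknown)}")
    return tuple(class_filter)


def subset_variants(
    variants: pd.DataFrame,
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    class_filter="all",
    maf_bin: str = "all",
    stratum: str = ALL_STRATA,
    maf_threshold: float = 0.025,
) -> VariantSubset:
    """Select variants by functional class and within-stratum MAF bin.

    The matrix must already be oriented for *stratum*.  A variant whose
    stratum MAF equals the threshold exactly is classed common.  Variants
    with undefined MAF (no called genotype in the stratum) are excluded
    from both bins.  An empty subset is allowed; downstream statistics
    skip it.
    """
    if maf_bin not in ("common", "rare", "all"):
        raise DataValidationError(f"maf_bin must be common/rare/all, got {maf_bin!r}")
    classes = _normalize_classes(class_filter)
    variants = variants.loc[matrix.columns]
    keep = variants["functional_class"].isin(classes)
    if maf_bin != "all":
        maf = compute_maf(matrix, samples, stratum)
        if maf_bin == "common":
            keep &= maf >= maf_threshold
        else:
            keep &= maf < maf_threshold
    return VariantSubset(
        members=tuple(matrix.columns[keep.to_numpy()]),
        class_filter=classes,
        maf_bin=maf_bin,
        stratum=stratum,
        maf_threshold=maf_threshold,
    )


def _member_matrix(
    matrix: pd.DataFrame, subset, complete_case: bool
) -> pd.DataFrame:
    members = list(subset.members) if isinstance(subset, VariantSubset) else list(subset)
    missing = [v for v in members if v not in matrix.columns]
    if missing:
        raise DataValidationError(f"subset variants absent from matrix: {missing[:10]}")
    sub = matrix[members]
    if not complete_case and sub.isna().to_numpy().any():
        raise DataValidationError(
            "matrix has missing genotypes over the subset; impute first or "
            "pass complete_case=True to sum over called genotypes only"
        )
    return sub


def burden_sum(
    matrix: pd.DataFrame,
    subset,
    complete_case: bool = False,
) -> pd.Series:
    """Unweighted minor-allele sum per individual over a subset.

    ``score_i = sum_j dosage_ij`` — 1 per heterozygote, 2 per
    minor-allele homozygote.  Requires a complete matrix unless
    ``complete_case=True``, in which case missing cells contribute 0.
    """
    sub = _member_matrix(matrix, subset, complete_case)
    scores = sub.sum(axis=1, skipna=True).astype(float)
    scores.name = "burden"
    scores.attrs["provenance"] = {
        "kind": "burden",
        "subset": tuple(sub.columns),
    }
    return scores


def metabolic_index_score(
    matrix: pd.DataFrame,
    subset,
    variants,
    model: PathwayModel,
    metabolite: str,
    compartment_filter: str = "all",
    complete_case: bool = False,
) -> pd.Series:
    """Signed minor-allele sum per individual: the Metabolic Index Score.

    ``MIS_i = sum_j s(gene_j) * dosage_ij`` over subset variants whose
    gene is signed for *metabolite* (optionally restricted to one
    compartment); unsigned genes contribute nothing.  ``variants`` is the
    annotation table (or any variant id → gene mapping).
    """
    if metabolite not in model.metabolites:
        raise KeyError(f"metabolite {metabolite!r} absent from pathway model")
    sub = _member_matrix(matrix, subset, complete_case)
    gene_of = variants["gene"] if isinstance(variants, pd.DataFrame) else variants
    genes = pd.Series({v: gene_of[v] for v in sub.columns})
    signed = model.signed_genes(metabolite, compartment_filter)
    weights = genes.map(lambda g: signed.get(g, 0)).to_numpy(dtype=float)
    values = np.nan_to_num(sub.to_numpy(dtype=float), nan=0.0)
    scores = pd.Series(values @ weights, index=sub.index, name="mis")
    scores.attrs["provenance"] = {
        "kind": "mis",
        "metabolite": metabolite,
        "compartment_filter": compartment_filter,
        "subset": tuple(sub.columns),
        "signed_genes": dict(signed),
    }
    return scores


def distinct_genotype_combinations(
    matrix: pd.DataFrame,
    subset,
    sample_filter=None,
) -> int:
    """Number of unique dosage vectors over a subset among chosen samples.

    ``sample_filter`` may be a boolean mask or a list of sample ids;
    default is all samples.  Missing genotypes count as their own state.
    """
    members = list(subset.members) if isinstance(subset, VariantSubset) else list(subset)
    if not members:
        raise DataValidationError("subset is empty")
    sub = matrix[members]
    if sample_filter is not None:
        sub = sub.loc[sample_filter]
    rows = sub.to_numpy(dtype=float)
    seen = {tuple(-9.0 if np.isnan(v) else v for v in row) for row in rows}
    return len(seen)
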