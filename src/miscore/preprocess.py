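"""Missingness QC, genotype imputation, and LD pruning.

QC drops samples whose genotype missingness is strictly above the
threshold (default 25%), then variants by the same rule computed on the
retained samples.  Imputation draws each missing cell from the variant's
empirical genotype distribution within the sample's race-ethnicity
stratum (falling back to the cohort-wide distribution when the stratum
carries no call) — a deliberately simple, seeded stand-in for
haplotype-model imputation that preserves stratum allele frequencies in
expectation.

LD is measured as genotypic (dosage-correlation) R^2 on complete-case
pairs.  Pruning is greedy single linkage in variant-column order: each
unassigned variant seeds a group and absorbs every later unassigned
variant whose R^2 with the seed exceeds the threshold; the seed
represents the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ALL_STRATA, DataValidationError, stratum_mask


@dataclass
class QCReport:
    """Record of a missingness-filter pass."""

    dropped_samples: list[str]
    dropped_variants: list[str]
    pre_missing_fraction: float
    post_missing_fraction: float
    threshold: float

    @property
    def n_dropped_samples(self) -> int:
        return len(self.dropped_samples)

    @property
    def n_dropped_variants(self) -> int:
        return len(self.dropped_variants)


@dataclass
class LDGroup:
    """A group of variants in mutual LD with its representative (the seed)."""

    representative: str
    members: list[str]
    r2_to_representative: dict[str, float] = field(default_factory=dict)


def _missing_fraction(values: np.ndarray) -> float:
    return float(np.isnan(values).mean()) if values.size else 0.0


def filter_missing(
    matrix: pd.DataFrame,
    threshold: float = 0.25,
    order: str = "samples_first",
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples, then variants, with missingness strictly > threshold.

    A sample (or variant) missing *exactly* the threshold fraction is
    retained — the rule is "more than", not "at least".  Variant
    missingness is recomputed on the retained samples.  ``order`` may be
    ``"samples_first"`` (default) or ``"variants_first"``.
    """
    if not 0.0 < threshold < 1.0:
        raise DataValidationError("threshold must be in (0, 1)")
    if order not in ("samples_first", "variants_first"):
        raise DataValidationError(f"unknown filter order {order!r}")
    values = matrix.to_numpy(dtype=float)
    pre_missing = _missing_fraction(values)

    def drop_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        frac = df.isna().mean(axis=1)
        dropped = df.index[frac > threshold].tolist()
        return df.drop(index=dropped), dropped

    def drop_cols(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        frac = df.isna().mean(axis=0)
        dropped = df.columns[frac > threshold].tolist()
        return df.drop(columns=dropped), dropped

    if order == "samples_first":
        kept, dropped_samples = drop_rows(matrix)
        kept, dropped_variants = drop_cols(kept)
    else:
        kept, dropped_variants = drop_cols(matrix)
        kept, dropped_samples = drop_rows(kept)
    if kept.shape[0] == 0:
        raise DataValidationError(
            "missingness filter removed every sample; check the input matrix"
        )
    report = QCReport(
        dropped_samples=dropped_samples,
        dropped_variants=dropped_variants,
        pre_missing_fraction=pre_missing,
        post_missing_fraction=_missing_fraction(kept.to_numpy(dtype=float)),
        threshold=threshold,
    )
    return kept, report


def impute_missing(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Fill missing genotypes by sampling stratum genotype frequencies.

    For each variant and stratum, missing cells are drawn from the
    empirical distribution of the non-missing genotypes of that stratum
    at that variant; if the stratum has no call there, the cohort-wide
    distribution is used.  A variant with no call anywhere cannot be
    imputed and is rejected.  Non-missing cells are never touched, and
    the draw is reproducible under ``rng_seed``.
    """
    values = matrix.to_numpy(dtype=float, copy=True)
    if not np.isnan(values).any():
        return matrix.copy()
    all_missing = np.flatnonzero(np.isnan(values).all(axis=0))
    if all_missing.size:
        raise DataValidationError(
            "variants with no called genotype cannot be imputed: "
            f"{matrix.columns[all_missing].tolist()[:10]}"
        )
    samples = samples.loc[matrix.index]
    rng = np.random.default_rng(rng_seed)
    strata = samples["stratum"].to_numpy()
    levels = [0.0, 1.0, 2.0]
    for j in np.flatnonzero(np.isnan(values).any(axis=0)):
        col = values[:, j]
        cohort_counts = np.array([(col == g).sum() for g in levels], dtype=float)
        for label in pd.unique(strata):
            rows = strata == label
            holes = rows & np.isnan(col)
            if not holes.any():
                continue
            counts = np.array(
                [((col == g) & rows).sum() for g in levels], dtype=float
            )
            if counts.sum() == 0:
                counts = cohort_counts
            probs = counts / counts.sum()
            col[holes] = rng.choice(levels, size=int(holes.sum()), p=probs)
        values[:, j] = col
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


def pairwise_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on complete-case pairs (both values non-missing).  Returns
    :data:`numpy.nan` (flagged undefined) when either vector is constant
    over the complete cases or fewer than two pairs remain; pruning
    treats undefined as 0.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise DataValidationError("dosage vectors must be aligned")
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_one_vs_many(seed: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Complete-case R^2 of one dosage vector against many (columns)."""
    seed = seed[:, None]
    valid = ~np.isnan(seed) & ~np.isnan(others)
    n = valid.sum(axis=0).astype(float)
    a = np.where(valid, seed, 0.0)
    b = np.where(valid, others, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa, sb = a.sum(axis=0), b.sum(axis=0)
        saa, sbb = (a * a).sum(axis=0), (b * b).sum(axis=0)
        sab = (a * b).sum(axis=0)
        cov = sab - sa * sb / n
        var_a = saa - sa * sa / n
        var_b = sbb - sb * sb / n
        r2 = (cov * cov) / (var_a * var_b)
    r2[(n < 2) | (var_a <= 0) | (var_b <= 0)] = np.nan
    return r2


def ld_prune(
    matrix: pd.DataFrame,
    variants: pd.DataFrame | None = None,
    threshold: float = 0.8,
) -> tuple[list[str], list[LDGroup]]:
    """Greedy LD grouping; one representative retained per group.

    Variants are visited in column order (the variant table, when given,
    only validates alignment).  Each unassigned variant seeds a group and
    absorbs all later unassigned variants with seed-R^2 strictly above
    the threshold.  Returns the retained variant ids (group seeds, which
    includes all singleton groups) and the groups themselves.  Undefined
    R^2 (monomorphic over complete cases) never exceeds the threshold.
    """
    if variants is not None and not matrix.columns.isin(variants.index).all():
        missing = matrix.columns.difference(variants.index).tolist()
        raise DataValidationError(f"variants absent from annotation: {missing[:10]}")
    values = matrix.to_numpy(dtype=float)
    ids = list(matrix.columns)
    m = len(ids)
    unassigned = np.ones(m, dtype=bool)
    groups: list[LDGroup] = []
    retained: list[str] = []
    for j in range(m):
        if not unassigned[j]:
            continue
        unassigned[j] = False
        candidates = np.flatnonzero(unassigned)
        members = [ids[j]]
        r2_map: dict[str, float] = {ids[j]: 1.0}
        if candidates.size:
            r2 = _r2_one_vs_many(values[:, j], values[:, candidates])
            hits = candidates[np.nan_to_num(r2, nan=0.0) > threshold]
            for k in hits:
                unassigned[k] = False
                members.append(ids[k])
                r2_map[ids[k]] = float(
                    r2[np.searchsorted(candidates, k)]
                )
        retained.append(ids[j])
        groups.append(
            LDGroup(representative=ids[j], members=members, r2_to_representative=r2_map)
        )
    return retained, groups
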