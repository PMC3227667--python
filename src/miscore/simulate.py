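"""Synthetic case-control genotype cohorts.

The generator emulates the structure of a sequencing study of 31
folate/one-carbon pathway genes in ~480 newborns: race-ethnicity strata
(about 65% Hispanic, 21% non-Hispanic white), roughly 1,400 variants
dominated by rare alleles (≈43% singletons), a functional-class mix of
mostly non-coding plus nonsynonymous/synonymous and a handful of
truncations and frameshifts, linkage-disequilibrium blocks within genes,
and ~6% missing genotypes.

Genotypes are drawn per stratum from Balding-Nichols-perturbed allele
frequencies; LD is induced by an allele-copying model — within a block,
each allele slot of a member variant copies the block seed's allele with
probability ``ld_rho``, else is drawn fresh.  Singletons are placed
exactly (one heterozygous carrier) and stay outside LD blocks.

`plant_effect` turns a simulated cohort into a case-control study with a
known signed-pathway effect: case status is drawn per individual with
``Pr(case) = logistic(alpha + beta * MIS_i)``, the intercept calibrated
so the marginal prevalence matches the requested baseline.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import (
    ALL_STRATA,
    DataValidationError,
    FUNCTIONAL_CLASSES,
    PathwayModel,
)

#: Study-sized default gene roster: the 31 folate-pathway genes.
DEFAULT_GENES = (
    "ALDH1L1", "ALDH1L2", "AMT", "ATIC", "BHMT", "BHMT2", "CBS", "CTH",
    "DHFR", "DMGDH", "FOLH1", "FOLR1", "FOLR2", "FPGS", "GART", "GGH",
    "MAT1A", "MAT2A", "MTFMT", "MTHFD1", "MTHFD2", "MTHFR", "MTHFS",
    "MTR", "MTRR", "SARDH", "SHMT1", "SHMT2", "SLC19A1", "TCN2", "TYMS",
)

#: Functional-class mixture of the emulated variant catalogue
#: (1,441 variants: 1050 non-coding, 211 nonsynonymous, 171 synonymous,
#: 4 truncations, 5 frameshifts).
DEFAULT_CLASS_PROPORTIONS = {
    "non_coding": 1050 / 1441,
    "nonsynonymous": 211 / 1441,
    "synonymous": 171 / 1441,
    "truncation": 4 / 1441,
    "frameshift": 5 / 1441,
}

DEFAULT_STRATA = {"Hispanic": 0.65, "White": 0.21, "Other": 0.14}


def default_gene_variant_counts(total: int = 1441) -> dict[str, int]:
    """Spread *total* variants evenly over the default 31-gene roster."""
    base, extra = divmod(total, len(DEFAULT_GENES))
    return {
        gene: base + (1 if i < extra else 0)
        for i, gene in enumerate(DEFAULT_GENES)
    }


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture of target minor-allele frequencies.

    ``singleton_mass`` of variants are exact singletons (one carrier);
    ``rare_mass`` are rare but non-singleton, with MAF drawn from a Beta
    tail truncated to (1/2N, maf_threshold); the rest are common, with
    MAF drawn from a Beta truncated to [maf_threshold, 0.45].  Default
    masses follow the emulated catalogue: 614/1441 singletons and
    1096/1441 variants with MAF below 2.5%.
    """

    singleton_mass: float = 614 / 1441
    rare_mass: float = (1096 - 614) / 1441
    rare_beta: tuple[float, float] = (0.8, 80.0)
    common_beta: tuple[float, float] = (1.2, 5.0)
    maf_threshold: float = 0.025

    def __post_init__(self) -> None:
        if not 0 <= self.singleton_mass + self.rare_mass <= 1 + 1e-9:
            raise DataValidationError("MAF spectrum masses must sum to <= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; defaults are the emulated study's structure."""

    n_cases: int = 240
    n_controls: int = 240
    strata_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATA)
    )
    gene_variant_counts: Mapping[str, int] = field(
        default_factory=default_gene_variant_counts
    )
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    fst: float = 0.01  # Balding-Nichols stratum differentiation
    ld_block_size: int = 4
    ld_rho: float = 0.3  # within-block allele-copying probability
    missing_rate: float = 0.06
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise DataValidationError("case/control counts must be positive")
        for mapping, what in (
            (self.strata_proportions, "strata_proportions"),
            (self.class_proportions, "class_proportions"),
        ):
            total = float(sum(mapping.values()))
            if abs(total - 1.0) > 1e-9:
                raise DataValidationError(f"{what} must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(FUNCTIONAL_CLASSES)
        if unknown:
            raise DataValidationError(f"unknown functional classes {unknown}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DataValidationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise DataValidationError("ld_rho must be in [0, 1]")
        n = self.n_cases + self.n_controls
        if self.maf_spectrum.singleton_mass > 0 and n < 10:
            raise DataValidationError(
                "cohort too small to host singleton variants"
            )

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class EffectSpec:
    """A planted signed-pathway effect on case status."""

    metabolite: str
    class_filter: str | Sequence[str] = "nonsynonymous"
    maf_bin: str = "common"
    beta: float = 0.15  # log-odds of case status per MIS unit
    baseline_prevalence: float = 0.5
    compartment_filter: str = "all"

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise DataValidationError("beta must be finite")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise DataValidationError("baseline_prevalence must be in (0, 1)")


def _draw_target_mafs(
    spectrum: MafSpectrum, m: int, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Base MAF per variant plus a boolean singleton indicator."""
    u = rng.random(m)
    singleton = u < spectrum.singleton_mass
    rare = ~singleton & (u < spectrum.singleton_mass + spectrum.rare_mass)
    common = ~singleton & ~rare
    maf = np.empty(m)
    maf[singleton] = 1.0 / (2 * n_samples)
    floor = 1.0 / (2 * n_samples)
    a, b = spectrum.rare_beta
    draw = rng.beta(a, b, size=int(rare.sum()))
    maf[rare] = floor + (spectrum.maf_threshold - floor) * draw
    a, b = spectrum.common_beta
    draw = rng.beta(a, b, size=int(common.sum()))
    maf[common] = spectrum.maf_threshold + (0.45 - spectrum.maf_threshold) * draw
    return maf, singleton


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(genotype matrix, variant table, sample table)``.

    Reproducible under ``spec.rng_seed``.  The returned variant table
    carries the per-stratum target MAFs actually used (after LD blending)
    in ``target_maf_<stratum>`` columns, and the block id in
    ``ld_block``.  Dosages count the simulated minor allele; missing
    cells are injected completely at random at ``spec.missing_rate``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    status = np.array(
        ["case"] * spec.n_cases + ["control"] * spec.n_controls, dtype=object
    )
    strata_labels = list(spec.strata_proportions)
    strata = rng.choice(
        strata_labels, size=n, p=list(spec.strata_proportions.values())
    )
    samples = pd.DataFrame(
        {"status": status, "stratum": strata},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- variant catalogue -------------------------------------------------
    genes = []
    coords = []
    for gene, count in spec.gene_variant_counts.items():
        if count < 0:
            raise DataValidationError(f"negative variant count for {gene}")
        genes.extend([gene] * count)
        # coordinate 1 sits 1 kb upstream of the transcription start
        coords.extend(1 + 137 * np.arange(count))
    m = len(genes)
    classes = rng.choice(
        list(spec.class_proportions),
        size=m,
        p=list(spec.class_proportions.values()),
    )
    variant_ids = [f"{g}_{c}" for g, c in zip(genes, coords)]
    base_maf, singleton = _draw_target_mafs(spec.maf_spectrum, m, n, rng)

    # stratum-specific frequencies via Balding-Nichols (skipped for
    # singletons, which are placed exactly rather than drawn)
    f = spec.fst
    strat_maf = {}
    for label in strata_labels:
        if f > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = rng.beta(
                    base_maf * (1 - f) / f, (1 - base_maf) * (1 - f) / f
                )
        else:
            p = base_maf.copy()
        p[singleton] = base_maf[singleton]
        strat_maf[label] = np.clip(p, 0.0, 0.5)

    # per-individual target frequency
    p_ind = np.empty((n, m))
    for label in strata_labels:
        p_ind[strata == label] = strat_maf[label]

    # --- LD blocks (allele-copying within consecutive non-singleton runs) --
    block_id = np.full(m, -1, dtype=int)
    next_block = 0
    gene_arr = np.asarray(genes)
    j = 0
    while j < m:
        if singleton[j]:
            j += 1
            continue
        block = [j]
        k = j + 1
        while (
            k < m
            and len(block) < spec.ld_block_size
            and gene_arr[k] == gene_arr[j]
        ):
            if not singleton[k]:
                block.append(k)
            k += 1
        block_id[block] = next_block
        next_block += 1
        j = block[-1] + 1

    alleles = np.zeros((n, m, 2), dtype=np.int8)
    target = p_ind.copy()  # blended marginal target per individual
    for b in range(next_block):
        members = np.flatnonzero(block_id == b)
        seed = members[0]
        seed_alleles = (rng.random((n, 2)) < p_ind[:, seed, None]).astype(np.int8)
        alleles[:, seed, :] = seed_alleles
        for v in members[1:]:
            fresh = (rng.random((n, 2)) < p_ind[:, v, None]).astype(np.int8)
            copy = rng.random((n, 2)) < spec.ld_rho
            alleles[:, v, :] = np.where(copy, seed_alleles, fresh)
            target[:, v] = (
                spec.ld_rho * p_ind[:, seed] + (1 - spec.ld_rho) * p_ind[:, v]
            )
    dosage = alleles.sum(axis=2).astype(float)

    # exact singletons: one heterozygous carrier each
    for v in np.flatnonzero(singleton):
        dosage[:, v] = 0.0
        dosage[rng.integers(n), v] = 1.0

    # --- missingness (MCAR) ------------------------------------------------
    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        dosage[mask] = np.nan

    matrix = pd.DataFrame(
        dosage,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=variant_ids,
    )
    variants = pd.DataFrame(
        {
            "gene": genes,
            "functional_class": classes,
            "ref": "A",
            "alt": "G",
            "coordinate": coords,
            "ld_block": block_id,
            "is_singleton": singleton,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    # record blended per-stratum marginal target MAFs
    for label in strata_labels:
        rows = strata == label
        variants[f"target_maf_{label}"] = target[rows].mean(axis=0)
    return matrix, variants, samples


def plant_effect(
    matrix: pd.DataFrame,
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    model: PathwayModel,
    effect: EffectSpec,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Resample case/control status with a planted MIS effect.

    The Metabolic Index Score is computed for the requested metabolite
    over the requested variant subset (missing genotypes contribute 0);
    status is then drawn independently per individual from
    ``Bernoulli(logistic(alpha + beta * MIS_i))`` with ``alpha`` solved
    so the marginal prevalence matches ``effect.baseline_prevalence``.
    Returns a sample table with the new ``status`` and the ``true_score``
    used.
    """
    from .scoring import metabolic_index_score, subset_variants

    subset = subset_variants(
        variants,
        matrix,
        samples,
        class_filter=effect.class_filter,
        maf_bin=effect.maf_bin,
        stratum=ALL_STRATA,
    )
    mis = metabolic_index_score(
        matrix,
        subset,
        variants,
        model,
        effect.metabolite,
        compartment_filter=effect.compartment_filter,
        complete_case=True,
    )
    scores = mis.to_numpy(dtype=float)
    beta = effect.beta
    prevalence = effect.baseline_prevalence

    def marginal(alpha: float) -> float:
        return float(expit(alpha + beta * scores).mean()) - prevalence

    lo, hi = -50.0, 50.0
    alpha = brentq(marginal, lo, hi)
    rng = np.random.default_rng(rng_seed)
    p_case = expit(alpha + beta * scores)
    status = np.where(rng.random(len(scores)) < p_case, "case", "control")
    out = samples.copy()
    out["status"] = status
    out["true_score"] = scores
    out.attrs["planted_alpha"] = float(alpha)
    out.attrs["planted_beta"] = float(beta)
    return out


def write_ground_truth(
    path: str | os.PathLike,
    spec: CohortSpec,
    effect: EffectSpec | None = None,
    planted: pd.DataFrame | None = None,
) -> None:
    """Dump the generator's ground truth (spec, effect, true scores) as JSON."""
    payload: dict = {"cohort_spec": asdict(spec)}
    if effect is not None:
        payload["effect_spec"] = asdict(effect)
    if planted is not None:
        payload["planted_alpha"] = planted.attrs.get("planted_alpha")
        payload["planted_beta"] = planted.attrs.get("planted_beta")
        payload["true_score"] = {
            str(k): float(v) for k, v in planted["true_score"].items()
        }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, default=float)
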