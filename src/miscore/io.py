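"""Readers and writers for genotype, annotation, sample and pathway files,
plus minor-allele orientation and stratified MAF computation.

File dialects
-------------
* VCF v4.x with GT fields (parsed with :mod:`cyvcf2`); multi-allelic
  sites are split into one biallelic record per alt allele.
* Dosage TSV: header row of variant ids, first column ``sample_id``,
  cells in ``{0, 1, 2, NA}``.
* Annotation TSV: ``variant_id, gene, functional_class, ref, alt``.
* Sample sheet TSV: ``sample_id, status, stratum`` plus free covariate
  columns.
* Pathway model as YAML (``metabolites: {name: {gene: "+"|"-"}}`` plus
  ``compartments``) or TSV (``metabolite, gene, sign, compartment``).

Dosages are loaded in raw alt-allele counts; `orient_to_minor_allele`
flips each variant to count the allele that is minor *within the chosen
analysis stratum* (cases and controls pooled), since the identity of the
minor allele can differ between race-ethnicity groups.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ALL_STRATA,
    COMPARTMENTS,
    DataValidationError,
    METABOLITES,
    PathwayModel,
    stratum_mask,
    validate_genotype_matrix,
    validate_sample_table,
    validate_variant_table,
)

MISSING_TOKENS = ("NA", "", ".", "NaN", "nan")


# ---------------------------------------------------------------------------
# genotype + annotation loading


def read_dosage_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the TSV dosage dialect into a genotype matrix."""
    table = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False, dtype=str,
    )
    matrix = table.apply(pd.to_numeric).astype(float)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "sample_id"
    return validate_genotype_matrix(matrix)


def write_dosage_table(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a genotype matrix in the TSV dosage dialect (missing → NA)."""
    out = matrix.copy()
    out.index.name = "sample_id"
    # keep integer look for dosages
    formatted = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep="\t")


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read GT dosages from a VCF into a samples × variants matrix.

    Multi-allelic records are split per alt allele; the dosage of a cell
    is the count of that alt allele in the genotype.  A genotype with any
    uncalled allele is treated as missing.  Variant ids use the VCF ID
    field when present, else ``CHROM_POS_REF_ALT``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[str] = []
    dosage_rows: list[np.ndarray] = []
    for record in vcf:
        genotypes = np.array([g[:2] for g in record.genotypes], dtype=int)
        for alt_index, alt in enumerate(record.ALT, start=1):
            if record.ID and record.ID != ".":
                vid = record.ID if len(record.ALT) == 1 else f"{record.ID}_{alt}"
            else:
                vid = f"{record.CHROM}_{record.POS}_{record.REF}_{alt}"
            dosage = (genotypes == alt_index).sum(axis=1).astype(float)
            dosage[(genotypes < 0).any(axis=1)] = np.nan
            columns.append(vid)
            dosage_rows.append(dosage)
    matrix = pd.DataFrame(
        np.column_stack(dosage_rows) if dosage_rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=columns,
    )
    return validate_genotype_matrix(matrix)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Read the variant annotation TSV, indexed by variant id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "variant_id" not in table.columns:
        raise DataValidationError("annotation table lacks a variant_id column")
    table = table.set_index("variant_id")
    table.index = table.index.astype(str)
    if "ref" in table.columns and "alt" in table.columns:
        table["is_indel"] = table["ref"].str.len() != table["alt"].str.len()
    return validate_variant_table(table)


def read_genotypes(
    genotype_source: str | os.PathLike,
    annotation_source: str | os.PathLike,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load genotypes (VCF or dosage TSV) with their annotation table.

    Every genotype column must map to an annotation row; unknown variants
    are rejected by id.  Returns ``(matrix, variants)`` with the variant
    table aligned to the matrix columns.
    """
    source = str(genotype_source)
    if source.endswith((".vcf", ".vcf.gz", ".bcf")):
        matrix = read_vcf(genotype_source)
    else:
        matrix = read_dosage_table(genotype_source)
    variants = read_annotations(annotation_source)
    unknown = matrix.columns.difference(variants.index)
    if len(unknown):
        raise DataValidationError(
            f"variants absent from annotation table: {unknown.tolist()[:10]}"
        )
    return matrix, variants.loc[matrix.columns]


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample sheet TSV, indexed by sample id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table.columns:
        raise DataValidationError("sample sheet lacks a sample_id column")
    table = table.set_index("sample_id")
    table.index = table.index.astype(str)
    return validate_sample_table(table)


def write_samples(samples: pd.DataFrame, path: str | os.PathLike) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_variants(variants: pd.DataFrame, path: str | os.PathLike) -> None:
    out = variants.copy()
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# minor-allele orientation and MAF


@dataclass(frozen=True)
class OrientationResult:
    """Oriented matrix plus the per-variant orientation record."""

    matrix: pd.DataFrame
    flipped: pd.Series  # bool per variant: dosages replaced by 2 - g
    undefined: pd.Series  # bool per variant: all genotypes missing in stratum
    stratum: str


def orient_to_minor_allele(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    stratum: str = ALL_STRATA,
) -> OrientationResult:
    """Flip variants so dosages count the stratum's minor allele.

    For each variant, if the counted allele's frequency among non-missing
    genotypes of the chosen stratum (cases + controls pooled) exceeds
    0.5, dosages are flipped ``g -> 2 - g``.  A frequency of exactly 0.5
    is left unflipped (the alt allele stays "minor").  Variants with no
    non-missing genotype in the stratum have undefined orientation; they
    are flagged and left unflipped.

    Idempotent: orienting an already-oriented matrix changes nothing.
    """
    samples = samples.loc[matrix.index]
    mask = stratum_mask(samples, stratum).to_numpy()
    sub = matrix.to_numpy(dtype=float)[mask]
    n_called = np.sum(~np.isnan(sub), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(sub, axis=0) / (2.0 * n_called)
    undefined = n_called == 0
    flip = ~undefined & (freq > 0.5)
    oriented = matrix.to_numpy(dtype=float, copy=True)
    oriented[:, flip] = 2.0 - oriented[:, flip]
    return OrientationResult(
        matrix=pd.DataFrame(oriented, index=matrix.index, columns=matrix.columns),
        flipped=pd.Series(flip, index=matrix.columns, name="flipped"),
        undefined=pd.Series(undefined, index=matrix.columns, name="undefined"),
        stratum=stratum,
    )


def compute_maf(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    stratum: str = ALL_STRATA,
) -> pd.Series:
    """Per-variant minor-allele frequency within a stratum.

    ``MAF_j = sum(dosages) / (2 * n_non_missing)`` over the stratum's
    samples.  Assumes the matrix is already oriented for this stratum, so
    values fall in [0, 0.5].  Variants with no non-missing genotype get
    :data:`numpy.nan` (undefined).
    """
    samples = samples.loc[matrix.index]
    mask = stratum_mask(samples, stratum).to_numpy()
    sub = matrix.to_numpy(dtype=float)[mask]
    n_called = np.sum(~np.isnan(sub), axis=0)
    with np.errstate(invalid="ignore"):
        maf = np.nansum(sub, axis=0) / (2.0 * n_called)
    maf[n_called == 0] = np.nan
    return pd.Series(maf, index=matrix.columns, name=f"maf_{stratum}")


# ---------------------------------------------------------------------------
# pathway model


_SIGN_TOKENS = {"+": 1, "-": -1, "−": -1, "+1": 1, "-1": -1, "1": 1}
_COMPARTMENT_ALIASES = {
    "cyto": "cytoplasmic",
    "cytoplasmic": "cytoplasmic",
    "mito": "mitochondrial",
    "mitochondrial": "mitochondrial",
}


def _parse_sign(token, metabolite: str, gene: str) -> int:
    key = str(token).strip()
    if key not in _SIGN_TOKENS:
        raise DataValidationError(
            f"sign for ({metabolite}, {gene}) must be '+' or '-', got {token!r}"
        )
    return _SIGN_TOKENS[key]


def _parse_compartment(token, gene: str) -> str:
    key = str(token).strip().lower()
    if key not in _COMPARTMENT_ALIASES:
        raise DataValidationError(
            f"compartment for {gene!r} must be one of {COMPARTMENTS} "
            f"(or cyto/mito), got {token!r}"
        )
    return _COMPARTMENT_ALIASES[key]


def read_pathway_model(path: str | os.PathLike) -> PathwayModel:
    """Read a pathway model from YAML or TSV.

    YAML layout::

        metabolites:
          purine: {MTHFD1: "+", ALDH1L1: "-"}
        compartments:
          MTHFD1: cytoplasmic
          ALDH1L1: cytoplasmic

    TSV layout: columns ``metabolite, gene, sign, compartment``.
    Duplicate (metabolite, gene) rows and sign tokens other than +/- are
    rejected.
    """
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        signs: dict[str, dict[str, int]] = {}
        compartments: dict[str, str] = {}
        for metabolite, genes in (raw.get("metabolites") or {}).items():
            signs[metabolite] = {
                gene: _parse_sign(tok, metabolite, gene)
                for gene, tok in (genes or {}).items()
            }
        for gene, comp in (raw.get("compartments") or {}).items():
            compartments[gene] = _parse_compartment(comp, gene)
        return PathwayModel(signs=signs, compartments=compartments)

    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"metabolite", "gene", "sign", "compartment"}
    if not required <= set(table.columns):
        raise DataValidationError(
            f"pathway TSV needs columns {sorted(required)}"
        )
    if table.duplicated(["metabolite", "gene"]).any():
        dup = table[table.duplicated(["metabolite", "gene"])].iloc[0]
        raise DataValidationError(
            f"duplicate pathway row for ({dup['metabolite']}, {dup['gene']})"
        )
    signs = {}
    compartments = {}
    for _, row in table.iterrows():
        metabolite, gene = row["metabolite"], row["gene"]
        signs.setdefault(metabolite, {})[gene] = _parse_sign(
            row["sign"], metabolite, gene
        )
        compartments[gene] = _parse_compartment(row["compartment"], gene)
    return PathwayModel(signs=signs, compartments=compartments)


def write_pathway_model(model: PathwayModel, path: str | os.PathLike) -> None:
    rows = [
        {
            "metabolite": metabolite,
            "gene": gene,
            "sign": "+" if sign > 0 else "-",
            "compartment": model.compartments[gene],
        }
        for metabolite, genes in model.signs.items()
        for gene, sign in genes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_pathway_model() -> PathwayModel:
    """The shipped folate/one-carbon pathway model.

    Signs encode how each gene's activity is expected to push three
    metabolic outputs — purine synthesis, thymidylate (dTMP) synthesis,
    and homocysteine abundance:

    * purine: genes feeding one-carbon units toward cytoplasmic
      10-formyl-THF (MTHFD1, ATIC, GART cytoplasmic; MTHFD2, SHMT2, AMT,
      SARDH, DMGDH mitochondrial) are beneficial (+); genes competing for
      those units or for THF (MTFMT, ALDH1L2 mitochondrial; ALDH1L1,
      SHMT1 cytoplasmic) are detrimental (-).
    * homocysteine: the purine genes carry the opposite sign (reduced
      flux toward methionine regeneration raises homocysteine), and the
      methionine-cycle and trans-sulfuration genes (BHMT, BHMT2, MTHFR,
      MTR, MTRR, CBS, CTH) are signed -, since their activity drains
      homocysteine.  MAT1A/MAT2A are excluded: AdoMet synthesis does not
      materially change homocysteine levels.
    * thymidylate: the nuclear dTMP module SHMT1-TYMS-DHFR is +;
      MTHFR competes with TYMS for 5,10-methylene-THF, hence -; the
      AdoMet-producing arm (MTR, MTRR, MAT1A, MAT2A) is + through
      AdoMet-mediated inhibition of MTHFR.
    """
    purine_plus_cyto = ("MTHFD1", "ATIC", "GART")
    purine_plus_mito = ("MTHFD2", "SHMT2", "AMT", "SARDH", "DMGDH")
    purine_minus_cyto = ("ALDH1L1", "SHMT1")
    purine_minus_mito = ("MTFMT", "ALDH1L2")
    homocysteine_extra_minus = ("BHMT", "BHMT2", "MTHFR", "MTR", "MTRR", "CBS", "CTH")

    purine = {g: 1 for g in purine_plus_cyto + purine_plus_mito}
    purine.update({g: -1 for g in purine_minus_cyto + purine_minus_mito})
    homocysteine = {g: -s for g, s in purine.items()}
    homocysteine.update({g: -1 for g in homocysteine_extra_minus})
    thymidylate = {"SHMT1": 1, "TYMS": 1, "DHFR": 1, "MTHFR": -1,
                   "MTR": 1, "MTRR": 1, "MAT1A": 1, "MAT2A": 1}

    compartments = {g: "cytoplasmic" for g in (
        *purine_plus_cyto, *purine_minus_cyto, *homocysteine_extra_minus,
        "TYMS", "DHFR", "MAT1A", "MAT2A",
    )}
    compartments.update({g: "mitochondrial" for g in (
        *purine_plus_mito, *purine_minus_mito,
    )})
    return PathwayModel(
        signs={
            "purine": purine,
            "thymidylate": thymidylate,
            "homocysteine": homocysteine,
        },
        compartments=compartments,
    )
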