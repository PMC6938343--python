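"""Core domain types shared by every pipeline stage.

The central objects are :class:`GenotypeMatrix` (sample x variant additive
dosages of a coded allele), per-study phenotype and covariate tables, and
:class:`AssociationRecord`, the atomic unit every downstream filter operates
on (one study x SNP x phenotype test result).

Dosages are stored as floats with ``NaN`` marking a missing genotype, so a
missing call is always distinct from a homozygous-reference 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "PhenotypeTable",
    "CovariateTable",
    "StudyCohort",
    "AssociationRecord",
    "RECORD_COLUMNS",
    "coded_allele_frequency",
    "records_to_frame",
    "frame_to_records",
]

#: Canonical column order for association-record tables (files and frames).
RECORD_COLUMNS = [
    "study",
    "variant_id",
    "chrom",
    "pos",
    "phenotype",
    "transform",
    "model",
    "beta",
    "se",
    "p",
    "n",
    "coded_allele",
    "caf",
]

PHENOTYPE_KINDS = ("continuous", "binary", "categorical")


@dataclass(frozen=True)
class Variant:
    """A biallelic site with a designated coded allele.

    ``dosage`` entries downstream count copies of ``coded_allele`` (0, 1, 2).
    Coordinates are 1-based; strand is ignored (alleles stored as given).
    """

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, str]
    coded_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.coded_allele not in self.alleles:
            raise ValueError(
                f"variant {self.id}: coded allele {self.coded_allele!r} "
                f"not among alleles {self.alleles}"
            )


class GenotypeMatrix:
    """Sample x variant additive dosage matrix with variant metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows).
    variants
        Ordered :class:`Variant` metadata (columns).
    dosage
        ``(n_samples, n_variants)`` float array with entries in
        ``{0, 1, 2, NaN}``; ``NaN`` is a missing genotype call.
    """

    def __init__(
        self,
        samples: Sequence[str],
        variants: Sequence[Variant],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2 or dosage.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        finite = dosage[np.isfinite(dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing (NaN)")
        if dosage.shape[1] and np.isnan(dosage).all(axis=0).any():
            bad = [v.id for v, allnan in zip(variants, np.isnan(dosage).all(axis=0)) if allnan]
            raise ValueError(f"all-missing dosage column(s): {bad}")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant id(s): {dupes}")
        self.samples = list(samples)
        self.variants = list(variants)
        self.dosage = dosage
        self._index = {vid: j for j, vid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant id."""
        return self.dosage[:, self._index[variant_id]]

    def caf(self) -> np.ndarray:
        """Coded-allele frequency per variant over non-missing samples."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.dosage, axis=0) / (
                2.0 * np.isfinite(self.dosage).sum(axis=0)
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


def coded_allele_frequency(dosages: np.ndarray) -> float:
    """Frequency of the coded allele from a single dosage column.

    Sum of non-missing dosages divided by twice their count.
    """
    d = np.asarray(dosages, dtype=float)
    mask = np.isfinite(d)
    if not mask.any():
        raise ValueError("all-missing dosage column has no allele frequency")
    return float(d[mask].sum() / (2.0 * mask.sum()))


class PhenotypeTable:
    """Per-study phenotype measurements with declared kinds.

    ``values`` is a ``DataFrame`` indexed by sample id, one column per
    phenotype (missing allowed); ``kinds`` maps each phenotype name to
    ``continuous``, ``binary`` or ``categorical``.
    """

    def __init__(self, study: str, values: pd.DataFrame, kinds: dict[str, str]) -> None:
        unknown = set(kinds.values()) - set(PHENOTYPE_KINDS)
        if unknown:
            raise ValueError(f"unknown phenotype kind(s): {sorted(unknown)}")
        missing = set(values.columns) - set(kinds)
        if missing:
            raise ValueError(f"phenotype(s) without a declared kind: {sorted(missing)}")
        for name, kind in kinds.items():
            if name not in values.columns:
                raise ValueError(f"kind declared for absent phenotype {name!r}")
            if kind == "binary":
                col = pd.to_numeric(values[name], errors="coerce").dropna()
                if not col.isin([0, 1]).all():
                    raise ValueError(f"binary phenotype {name!r} has values outside {{0,1}}")
        self.study = study
        self.values = values
        self.kinds = dict(kinds)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


@dataclass
class CovariateTable:
    """Principal-component and sex covariates aligned to a sample list.

    In a female-only study the sex column is constant ``F`` and is excluded
    from every model matrix.
    """

    samples: list[str]
    pc1: np.ndarray
    pc2: np.ndarray
    sex: np.ndarray  # array of "F" / "M" / "" (missing)
    female_only_study: bool = False

    def __post_init__(self) -> None:
        n = len(self.samples)
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.pc2 = np.asarray(self.pc2, dtype=float)
        self.sex = np.asarray(self.sex, dtype=object)
        for name, arr in (("pc1", self.pc1), ("pc2", self.pc2), ("sex", self.sex)):
            if arr.shape != (n,):
                raise ValueError(f"covariate {name} length {arr.shape} != {n} samples")
        if self.female_only_study:
            nonf = set(self.sex) - {"F"}
            if nonf:
                raise ValueError(f"female-only study has non-F sex values: {sorted(map(str, nonf))}")

    def model_columns(self) -> tuple[np.ndarray, list[str]]:
        """Numeric covariate block used in regressions (PC1, PC2 [, sex])."""
        cols = [self.pc1, self.pc2]
        names = ["pc1", "pc2"]
        if not self.female_only_study:
            sex_num = np.where(
                self.sex == "F", 0.0, np.where(self.sex == "M", 1.0, np.nan)
            )
            cols.append(sex_num)
            names.append("sex")
        return np.column_stack(cols), names


@dataclass
class StudyCohort:
    """One study's genotypes, phenotypes, covariates and optional local ancestry.

    All components share a single sample ordering; ``local_ancestry`` counts
    copies of the African-derived allele (0/1/2, NaN missing) per sample per
    variant.
    """

    study: str
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    covariates: CovariateTable
    local_ancestry: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        s = self.genotypes.samples
        if self.phenotypes.samples != s:
            raise ValueError(f"{self.study}: phenotype sample order differs from genotypes")
        if self.covariates.samples != s:
            raise ValueError(f"{self.study}: covariate sample order differs from genotypes")
        if self.local_ancestry is not None:
            la = np.asarray(self.local_ancestry, dtype=float)
            if la.shape != self.genotypes.dosage.shape:
                raise ValueError(f"{self.study}: local-ancestry shape {la.shape} mismatch")
            self.local_ancestry = la


@dataclass
class AssociationRecord:
    """One study x SNP x phenotype test result."""

    study: str
    variant_id: str
    chrom: str
    pos: int
    phenotype: str
    transform: str  # raw | log1p | onevsrest:<label>
    model: str  # linear | logistic
    beta: float
    se: float
    p: float
    n: int
    coded_allele: str
    caf: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}/{self.phenotype}: se must be > 0")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant_id}/{self.phenotype}: p must be in (0,1]")
        if not (0.0 <= self.caf <= 1.0):
            raise ValueError(f"{self.variant_id}/{self.phenotype}: caf must be in [0,1]")


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Association records as a DataFrame in canonical column order."""
    if len(records) == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    df = pd.DataFrame([vars(r) for r in records])
    return df[RECORD_COLUMNS]


def frame_to_records(frame: pd.DataFrame) -> list[AssociationRecord]:
    """Inverse of :func:`records_to_frame`."""
    extra = set(frame.columns) - set(RECORD_COLUMNS)
    if extra:
        raise ValueError(f"unknown column(s): {sorted(extra)}")
    return [
        AssociationRecord(
            study=row.study,
            variant_id=row.variant_id,
            chrom=str(row.chrom),
            pos=int(row.pos),
            phenotype=row.phenotype,
            transform=row.transform,
            model=row.model,
            beta=float(row.beta),
            se=float(row.se),
            p=float(row.p),
            n=int(row.n),
            coded_allele=row.coded_allele,
            caf=float(row.caf),
        )
        for row in frame.itertuples(index=False)
    ]
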