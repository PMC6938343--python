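"""Readers and writers for the pipeline's on-disk formats.

Genotypes come in as VCF 4.x (via cyvcf2) or whitespace-delimited PLINK
PED/MAP text; association results, phenotype, covariate and local-ancestry
tables are tab-delimited with fixed documented headers.  Every writer/reader
pair round-trips losslessly on valid data.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    RECORD_COLUMNS,
    CovariateTable,
    GenotypeMatrix,
    PhenotypeTable,
    Variant,
    frame_to_records,
    records_to_frame,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_association_records",
    "write_association_records",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_covariate_table",
    "write_covariate_table",
    "read_ancestry_matrix",
    "write_ancestry_matrix",
]

_MISSING_GT_TOKENS = {"./.", ".|.", ".", "./", ".|"}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    coded_alleles: Optional[dict[str, str]] = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or PLINK PED/MAP file pair.

    Dosages count copies of the coded allele: by default the VCF ALT allele,
    or the in-sample minor allele for PED/MAP.  ``coded_alleles`` overrides
    the coded allele per variant id.  Missing genotype tokens become NaN.

    For ``format="ped_map"``, ``path`` is the ``.ped`` file; the companion
    ``.map`` is found by swapping the extension.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path, coded_alleles)
    if format == "ped_map":
        return _read_ped_map(path, coded_alleles)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, coded_alleles: Optional[dict[str, str]]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    _prevalidate_vcf(path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path}: variant {rec.ID or rec.POS} is not biallelic "
                f"(ALT = {rec.ALT})"
            )
        ref, alt = rec.REF, rec.ALT[0]
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        coded = (coded_alleles or {}).get(vid, alt)
        if coded not in (ref, alt):
            raise ParseError(f"{path}: coded allele {coded!r} not in ({ref},{alt}) for {vid}")
        # gts012: 0/1/2 = ALT copies, 3 = missing
        alt_copies = rec.gt_types.astype(float)
        alt_copies[alt_copies == 3] = np.nan
        dose = alt_copies if coded == alt else 2.0 - alt_copies
        variants.append(Variant(vid, str(rec.CHROM), int(rec.POS), (ref, alt), coded))
        columns.append(dose)
    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, variants, dosage)


def _prevalidate_vcf(path: Path) -> None:
    """Cheap structural check so malformed records fail with a line number."""
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise ParseError(f"{path}:{lineno}: VCF header has no sample columns")
                n_fields = len(fields)
                continue
            if n_fields is None:
                raise ParseError(f"{path}:{lineno}: data before #CHROM header")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} fields, found {len(fields)}"
                )


def _read_ped_map(ped_path: Path, coded_alleles: Optional[dict[str, str]]) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    meta: list[tuple[str, str, int]] = []  # (chrom, id, pos)
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 fields, found {len(fields)}")
            chrom, vid, _cm, pos = fields
            meta.append((chrom, vid, int(pos)))
    m = len(meta)
    samples: list[str] = []
    geno_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, found {len(fields)}"
                )
            samples.append(fields[1])
            alleles = fields[6:]
            geno_rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)])

    variants: list[Variant] = []
    dosage = np.full((len(samples), m), np.nan)
    for j, (chrom, vid, pos) in enumerate(meta):
        observed = sorted(
            {a for row in geno_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise ParseError(f"{ped_path}: variant {vid} has >2 alleles: {observed}")
        if not observed:
            raise ParseError(f"{ped_path}: variant {vid} has no called genotypes")
        if len(observed) == 1:
            observed = observed * 2  # monomorphic; both slots the same allele
        counts = {a: 0 for a in observed}
        for row in geno_rows:
            a1, a2 = row[j]
            if a1 != "0":
                counts[a1] += 1
            if a2 != "0":
                counts[a2] += 1
        # default coded allele: in-sample minor (ties broken alphabetically)
        minor = min(observed, key=lambda a: (counts[a], a))
        coded = (coded_alleles or {}).get(vid, minor)
        if coded not in observed:
            raise ParseError(f"{ped_path}: coded allele {coded!r} unseen for {vid}")
        for i, row in enumerate(geno_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == coded) + (a2 == coded)
        pair = (observed[0], observed[1]) if observed[0] != observed[1] else (observed[0], observed[0])
        variants.append(Variant(vid, chrom, pos, pair, coded))
    return GenotypeMatrix(samples, variants, dosage)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    """Write a genotype matrix as VCF text or a PED/MAP pair.

    The VCF writer places the coded allele as ALT, so a default
    ``read_genotypes`` round-trips the dosage matrix exactly.
    """
    path = Path(path)
    if format == "vcf":
        _write_vcf(matrix, path)
    elif format == "ped_map":
        _write_ped_map(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, v in enumerate(matrix.variants):
            other = v.alleles[0] if v.alleles[1] == v.coded_allele else v.alleles[1]
            gts = [
                gt_for[d] if np.isfinite(d) else "./."
                for d in matrix.dosage[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{other}\t{v.coded_allele}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _write_ped_map(matrix: GenotypeMatrix, ped_path: Path) -> None:
    map_path = ped_path.with_suffix(".map")
    with open(map_path, "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(matrix.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, v in enumerate(matrix.variants):
                other = v.alleles[0] if v.alleles[1] == v.coded_allele else v.alleles[1]
                d = matrix.dosage[i, j]
                if not np.isfinite(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [other, other]
                elif d == 1:
                    fields += [other, v.coded_allele]
                else:
                    fields += [v.coded_allele, v.coded_allele]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# association records

_FLOAT_COLUMNS = ("beta", "se", "p", "caf")


def write_association_records(records, path: str | Path) -> None:
    """Write association records (list or DataFrame) as TSV.

    Column order is fixed; floats are serialized with 12 significant digits
    so values like ``8.01e-44`` survive a round trip.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    extra = set(frame.columns) - set(RECORD_COLUMNS)
    if extra:
        raise ValueError(f"unknown column(s): {sorted(extra)}")
    frame = frame.reindex(columns=RECORD_COLUMNS)
    out = frame.copy()
    for col in _FLOAT_COLUMNS:
        out[col] = [f"{float(x):.12g}" for x in frame[col]]
    out.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_association_records(path: str | Path, as_frame: bool = True):
    """Read an association-record TSV; returns a DataFrame (default) or list."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "study": str, "phenotype": str},
        keep_default_na=False,
        na_values=[],
    )
    extra = set(df.columns) - set(RECORD_COLUMNS)
    if extra:
        raise ValueError(f"{path}: unknown column(s): {sorted(extra)}")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    df = df[RECORD_COLUMNS]
    for col in _FLOAT_COLUMNS:
        df[col] = df[col].astype(float)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)
    if as_frame:
        return df
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# phenotype / covariate / ancestry tables


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    """Long-format TSV: sample_id, phenotype, value, kind."""
    rows = []
    for name in table.phenotypes:
        kind = table.kinds[name]
        for sample, value in table.values[name].items():
            if pd.isna(value):
                continue
            rows.append((sample, name, value, kind))
    pd.DataFrame(rows, columns=["sample_id", "phenotype", "value", "kind"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype_table(
    path: str | Path, study: str, samples: Sequence[str]
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "phenotype": str, "kind": str})
    kinds = {}
    for name, grp in df.groupby("phenotype", sort=False):
        uniq = grp["kind"].unique()
        if len(uniq) != 1:
            raise ParseError(f"{path}: phenotype {name!r} declares multiple kinds {list(uniq)}")
        kinds[name] = uniq[0]
    wide = df.pivot_table(
        index="sample_id", columns="phenotype", values="value", aggfunc="first"
    )
    wide = wide.reindex(index=list(samples))
    wide = wide.reindex(columns=list(kinds))
    for name, kind in kinds.items():
        if kind in ("continuous", "binary"):
            wide[name] = pd.to_numeric(wide[name])
    return PhenotypeTable(study, wide, kinds)


def write_covariate_table(cov: CovariateTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": cov.samples,
            "pc1": cov.pc1,
            "pc2": cov.pc2,
            "sex": cov.sex,
        }
    ).to_csv(path, sep="\t", index=False)


def read_covariate_table(
    path: str | Path, female_only_study: bool = False
) -> CovariateTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str}, keep_default_na=False)
    return CovariateTable(
        samples=list(df["sample_id"]),
        pc1=df["pc1"].astype(float).to_numpy(),
        pc2=df["pc2"].astype(float).to_numpy(),
        sex=df["sex"].to_numpy(dtype=object),
        female_only_study=female_only_study,
    )


def write_ancestry_matrix(
    matrix: np.ndarray, samples: Sequence[str], variant_ids: Sequence[str], path: str | Path
) -> None:
    """Samples x variants TSV of African-derived allele copies (0/1/2)."""
    pd.DataFrame(matrix, index=list(samples), columns=list(variant_ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_ancestry_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    arr = df.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        raise ParseError(f"{path}: local-ancestry entries must be 0/1/2 or missing")
    return arr, [str(s) for s in df.index], [str(c) for c in df.columns]
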