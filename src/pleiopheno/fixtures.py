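"""Packaged in-study reference tables.

Three small tab-delimited tables ship with the package:

``table4_records.tsv``
    The published concomitant cross-phenotype association records for
    African Americans: one row per (study, SNP, phenotype) test with
    p-value, beta, SE, sample size, coded allele and allele frequency.
    Phenotype labels are kept verbatim (including their ``LN+1``
    transform prefixes) so the curated class map can be certified against
    the published rows.  A handful of rows where the source's extraction
    duplicated a label were emended by restoring the obvious ``LN+1``
    prefix; the affected record is otherwise unchanged.

``table4_rows.tsv``
    Row-level expectations: each variant's phenotype-class set and its
    opposite-direction-between-classes flag, used to certify the
    replication/pleiotropy pipeline.

``table5_ancestry.tsv``
    Local-ancestry summaries at the called loci: the percentage of
    individuals carrying 0, 1 or 2 African-derived allele copies.  One row
    (the SPARC locus) carries a note flagging internally inconsistent
    column semantics in the source and is excluded from certification;
    one RBKS row has no printed ancestry columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_association_records

__all__ = [
    "load_table4_fixture",
    "load_table4_expected",
    "load_table5_ancestry",
    "TABLE4_CONTEXT",
]

#: Published headline counts surrounding the concomitant-association table:
#: 133 multi-class SNPs before reductions, of which 53 were the
#: LDL/total-cholesterol co-membership and 37 the chromosome-1 white blood
#: count couplings; the remaining table rows collapse to 38 independent
#: signals at r^2 >= 0.80 of which 7 are opposite-direction between classes.
TABLE4_CONTEXT = {
    "multiclass_snps": 133,
    "ldl_tc_excluded": 53,
    "wbc_chr1_excluded": 37,
    "independent_signals": 38,
    "opposite_direction_independent": 7,
}


def _data_path(name: str):
    return resources.files("pleiopheno.data").joinpath(name)


def load_table4_fixture(as_frame: bool = True):
    """Association records of the packaged concomitant-results table."""
    with resources.as_file(_data_path("table4_records.tsv")) as path:
        return read_association_records(path, as_frame=as_frame)


def load_table4_expected() -> pd.DataFrame:
    """Row-level expectations (variant, class set, opposite-direction flag)."""
    with resources.as_file(_data_path("table4_rows.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    df["caf"] = df["caf"].astype(float)
    return df


def certify_table4(p_max: float = 0.01):
    """Run the replication/pleiotropy pipeline on the packaged records.

    Returns ``(calls, expected)``: the pleiotropy calls produced by
    ``replicate_class`` + ``detect_pleiotropy`` under the default class map,
    and the row-level expectations they are certified against.
    """
    from .classes import default_class_map
    from .pipeline import detect_pleiotropy, filter_significant, replicate_class

    records = filter_significant(load_table4_fixture(), p_max=p_max)
    hits = replicate_class(records, default_class_map(), p_max=p_max)
    calls = detect_pleiotropy(hits)
    return calls, load_table4_expected()


def load_table5_ancestry(include_flagged: bool = True) -> pd.DataFrame:
    """Local-ancestry percentage rows (0/1/2 African-derived allele copies).

    Rows without printed ancestry columns are dropped; with
    ``include_flagged=False`` the row noted as internally inconsistent in
    the source is dropped too.
    """
    with resources.as_file(_data_path("table5_ancestry.tsv")) as path:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in ("pct0", "pct1", "pct2"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["pct0", "pct1", "pct2"]).reset_index(drop=True)
    if not include_flagged:
        df = df[df["note"] == ""].reset_index(drop=True)
    return df
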