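"""Curated phenotype -> phenotype-class mapping with coding polarity.

Epidemiologic studies label the same underlying trait many ways ("Diabetes
ever (Y/N)", "treated diabetes (Y/N)", ...), and some labels are inversely
coded ("Never hypertensive", "Number of years since quit smoking").  The
class map bins each per-study phenotype label into one of 30 curated
phenotype classes and records a polarity (+1/-1) so that effect directions
can be harmonized within a class: an inversely coded phenotype with a
negative beta supports the same direction as a directly coded one with a
positive beta.

Polarity is curation, not statistics: the packaged default map was built by
reading every phenotype label, and users can edit the TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["PhenotypeClassMap", "load_class_map", "default_class_map", "assign_class"]

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeClassMap:
    """Mapping (study, phenotype label) -> (class, polarity in {+1, -1})."""

    entries: dict[tuple[str, str], tuple[str, int]]

    def __post_init__(self) -> None:
        for key, (cls, pol) in self.entries.items():
            if pol not in (1, -1):
                raise ValueError(f"{key}: polarity must be +1 or -1, got {pol}")
            if not cls:
                raise ValueError(f"{key}: empty class name")

    @property
    def classes(self) -> list[str]:
        return sorted({cls for cls, _ in self.entries.values()})

    def lookup(self, study: str, phenotype: str) -> tuple[str, int] | None:
        return self.entries.get((study, phenotype))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (study, phen, cls, pol)
            for (study, phen), (cls, pol) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["study", "phenotype", "class", "polarity"])


def load_class_map(path: str | Path) -> PhenotypeClassMap:
    """Load a class map from a TSV with columns study, phenotype, class, polarity.

    A missing polarity column defaults every entry to +1 with a warning.
    Duplicate (study, phenotype) rows and unrecognized polarity tokens are
    errors.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, comment="#"
    )
    required = {"study", "phenotype", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: class map missing column(s) {sorted(missing)}")
    if "polarity" not in df.columns:
        warnings.warn(f"{path}: no polarity column; defaulting every entry to +1")
        df["polarity"] = "1"
    entries: dict[tuple[str, str], tuple[str, int]] = {}
    for study, phenotype, cls, polarity in zip(
        df["study"], df["phenotype"], df["class"], df["polarity"]
    ):
        token = str(polarity).strip()
        if token in ("1", "+1"):
            pol = 1
        elif token == "-1":
            pol = -1
        else:
            raise ValueError(
                f"{path}: unknown polarity token {token!r} for ({study}, {phenotype})"
            )
        key = (study, phenotype)
        if key in entries:
            raise ValueError(f"{path}: duplicate class-map entry {key}")
        entries[key] = (cls, pol)
    return PhenotypeClassMap(entries)


def default_class_map() -> PhenotypeClassMap:
    """The packaged default map: 30 phenotype classes covering the bundled
    concomitant-association fixture plus representative labels for classes
    the fixture does not touch."""
    ref = resources.files("pleiopheno.data").joinpath("class_map_default.tsv")
    with resources.as_file(ref) as path:
        return load_class_map(path)


def assign_class(record, class_map: PhenotypeClassMap) -> tuple[str, str] | None:
    """Class and harmonized direction for one association record.

    Returns ``(class, direction)`` with direction ``"+"``, ``"-"`` or
    ``"0"`` (zero beta never supports replication), or ``None`` when the
    record's (study, phenotype) is not in the map (the record is then
    excluded from class-level analyses).
    """
    hit = class_map.lookup(record.study, record.phenotype)
    if hit is None:
        logger.warning(
            "unmapped phenotype (%s, %s); excluded from class analyses",
            record.study,
            record.phenotype,
        )
        return None
    cls, pol = hit
    signed = record.beta * pol
    direction = "+" if signed > 0 else "-" if signed < 0 else "0"
    return cls, direction


def assign_classes_frame(frame: pd.DataFrame, class_map: PhenotypeClassMap) -> pd.DataFrame:
    """Vectorized class/direction assignment for a record DataFrame.

    Adds ``class``, ``polarity`` and ``direction`` columns; rows whose
    (study, phenotype) is unmapped are dropped (with a summary log line).
    """
    map_df = class_map.to_frame()
    out = frame.merge(map_df, on=["study", "phenotype"], how="left")
    unmapped = out["class"].isna()
    if unmapped.any():
        pairs = (
            out.loc[unmapped, ["study", "phenotype"]].drop_duplicates().itertuples(index=False)
        )
        logger.warning(
            "dropping %d record(s) with unmapped phenotypes: %s",
            int(unmapped.sum()),
            "; ".join(f"({s}, {p})" for s, p in pairs),
        )
        out = out[~unmapped].copy()
    out["polarity"] = out["polarity"].astype(int)
    signed = out["beta"] * out["polarity"]
    out["direction"] = pd.Series(
        pd.Categorical([""] * len(out)), index=out.index, dtype=object
    )
    out["direction"] = "0"
    out.loc[signed > 0, "direction"] = "+"
    out.loc[signed < 0, "direction"] = "-"
    return out
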