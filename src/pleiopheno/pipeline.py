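"""Replication filtering, pleiotropy calling and LD collapsing.

The detection procedure is filter-based: keep association records below a
significance threshold, bin them into phenotype classes with harmonized
directions, require class-level support from at least two studies in a
common direction, call a variant pleiotropic when two or more distinct
classes replicate, and finally collapse called variants into independent
signals by greedy r-squared clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classes import PhenotypeClassMap, assign_classes_frame
from .model import GenotypeMatrix, records_to_frame

__all__ = [
    "ClassHit",
    "PleiotropyCall",
    "IndependentSignal",
    "filter_significant",
    "replicate_same_phenotype",
    "replicate_class",
    "detect_pleiotropy",
    "pairwise_r2",
    "collapse_independent",
    "class_hits_frame",
    "calls_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class ClassHit:
    """A (variant, phenotype class) pair replicated across studies.

    ``records`` holds the supporting sub-threshold records whose harmonized
    direction equals ``direction``; they span at least two distinct studies.
    """

    variant_id: str
    phenotype_class: str
    direction: str  # "+" or "-"
    studies: frozenset[str]
    records: pd.DataFrame = field(repr=False)

    @property
    def min_p(self) -> float:
        return float(self.records["p"].min())


@dataclass
class PleiotropyCall:
    """A variant with two or more replicated phenotype classes."""

    variant_id: str
    classes: list[ClassHit]

    @property
    def class_names(self) -> set[str]:
        return {h.phenotype_class for h in self.classes}

    @property
    def opposite_between_classes(self) -> bool:
        return len({h.direction for h in self.classes}) > 1

    @property
    def min_p(self) -> float:
        return min(h.min_p for h in self.classes)


@dataclass
class IndependentSignal:
    """A cluster of called variants in mutual LD with its representative."""

    representative: str
    members: list[str]
    min_p: float


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(list(records))


def filter_significant(records, p_max: float = 0.01) -> pd.DataFrame:
    """Keep records with p strictly below ``p_max``."""
    frame = _as_frame(records)
    return frame[frame["p"] < p_max].copy()


def replicate_same_phenotype(records, p_max: float = 0.01) -> pd.DataFrame:
    """Per-phenotype replication before any class binning.

    Groups sub-threshold records by (variant, phenotype name) — transform
    variants of one phenotype count as that phenotype — and keeps groups
    supported by >= 2 distinct studies with the same raw beta sign.
    Returns one row per (variant_id, phenotype, direction) with the
    supporting study set.
    """
    frame = filter_significant(records, p_max)
    if frame.empty:
        return pd.DataFrame(columns=["variant_id", "phenotype", "direction", "studies"])
    frame = frame[frame["beta"] != 0].copy()
    frame["direction"] = np.where(frame["beta"] > 0, "+", "-")
    grouped = (
        frame.groupby(["variant_id", "phenotype", "direction"])["study"]
        .agg(lambda s: frozenset(s))
        .reset_index(name="studies")
    )
    grouped = grouped[grouped["studies"].map(len) >= 2]
    return grouped.reset_index(drop=True)


def replicate_class(
    records,
    class_map: PhenotypeClassMap,
    p_max: float = 0.01,
    direction_rule: str = "concordant",
) -> list[ClassHit]:
    """Class-level replication: >= 2 studies, one harmonized direction.

    For each (variant, class), sub-threshold records are grouped by their
    harmonized direction.  Under the default ``"concordant"`` rule the class
    replicates when some direction is supported by records from at least two
    distinct studies; the hit's direction is the best-supported one (most
    studies, then most records, then smallest p).  Under ``"unanimous"``
    every sub-threshold record of the pair must share one direction.
    """
    if direction_rule not in ("concordant", "unanimous"):
        raise ValueError(f"unknown direction_rule {direction_rule!r}")
    frame = filter_significant(_as_frame(records), p_max)
    frame = assign_classes_frame(frame, class_map)
    frame = frame[frame["direction"] != "0"]
    hits: list[ClassHit] = []
    for (vid, cls), grp in frame.groupby(["variant_id", "class"], sort=True):
        per_dir = {}
        for d, sub in grp.groupby("direction"):
            per_dir[d] = (sub["study"].nunique(), len(sub), -sub["p"].min(), sub)
        valid = {d: v for d, v in per_dir.items() if v[0] >= 2}
        if not valid:
            continue
        if direction_rule == "unanimous" and len(per_dir) > 1:
            continue
        best = max(valid, key=lambda d: (valid[d][0], valid[d][1], valid[d][2], d))
        sub = valid[best][3]
        hits.append(
            ClassHit(
                variant_id=vid,
                phenotype_class=cls,
                direction=best,
                studies=frozenset(sub["study"]),
                records=sub.reset_index(drop=True),
            )
        )
    return hits


def detect_pleiotropy(
    class_hits: Sequence[ClassHit],
    exclusions: Optional[Iterable[dict]] = None,
) -> list[PleiotropyCall]:
    """Variants whose replicated classes number two or more.

    ``exclusions`` optionally removes calls matching configured patterns,
    each a dict with a ``classes`` set (the call is removed when that set is
    a subset of its class names) and optional ``chrom`` restricting the rule
    to variants whose supporting records sit on that chromosome.  This
    mirrors reductions like dropping LDL/total-cholesterol co-membership or
    chromosome-1 white-blood-count couplings.
    """
    by_variant: dict[str, list[ClassHit]] = {}
    for hit in class_hits:
        by_variant.setdefault(hit.variant_id, []).append(hit)
    calls = []
    for vid in sorted(by_variant):
        hits = sorted(by_variant[vid], key=lambda h: h.phenotype_class)
        if len({h.phenotype_class for h in hits}) < 2:
            continue
        call = PleiotropyCall(variant_id=vid, classes=hits)
        if exclusions and _excluded(call, exclusions):
            continue
        calls.append(call)
    return calls


def _excluded(call: PleiotropyCall, exclusions: Iterable[dict]) -> bool:
    for rule in exclusions:
        classes = set(rule["classes"])
        if not classes <= call.class_names:
            continue
        chrom = rule.get("chrom")
        if chrom is not None:
            chroms = {
                str(c)
                for h in call.classes
                for c in h.records.get("chrom", pd.Series(dtype=str))
            }
            if str(chrom) not in chroms:
                continue
        return True
    return False


def pairwise_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of two dosage vectors.

    Complete-case pairwise; a constant vector has undefined correlation and
    is treated as r^2 = 0 for clustering (logged).
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        raise ValueError("pairwise_r2 needs >= 3 jointly non-missing samples")
    a, b = a[mask], b[mask]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        logger.warning("constant dosage vector in r^2; treating as 0")
        return 0.0
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def collapse_independent(
    calls: Sequence[PleiotropyCall],
    genotypes: GenotypeMatrix,
    r2_min: float = 0.80,
) -> list[IndependentSignal]:
    """Greedy clustering of pleiotropy calls into independent signals.

    Calls are sorted by their minimum supporting p (ties broken by variant
    id); the best unassigned variant seeds a cluster and absorbs every
    unassigned variant with r^2 >= ``r2_min`` to the seed.  The seed is the
    cluster's representative.
    """
    order = sorted(calls, key=lambda c: (c.min_p, c.variant_id))
    unassigned = [c.variant_id for c in order]
    signals: list[IndependentSignal] = []
    minp = {c.variant_id: c.min_p for c in order}
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        rest = []
        g_seed = genotypes.column(seed)
        for vid in unassigned:
            if pairwise_r2(g_seed, genotypes.column(vid)) >= r2_min:
                members.append(vid)
            else:
                rest.append(vid)
        unassigned = rest
        signals.append(
            IndependentSignal(representative=seed, members=members, min_p=minp[seed])
        )
    return signals


# ---------------------------------------------------------------------------
# tabular views (used by the CLI writers)


def class_hits_frame(hits: Sequence[ClassHit]) -> pd.DataFrame:
    rows = [
        (
            h.variant_id,
            h.phenotype_class,
            h.direction,
            ",".join(sorted(h.studies)),
            len(h.records),
            h.min_p,
        )
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["variant_id", "class", "direction", "studies", "n_records", "min_p"],
    )


def calls_frame(calls: Sequence[PleiotropyCall]) -> pd.DataFrame:
    rows = [
        (
            c.variant_id,
            ", ".join(sorted(c.class_names)),
            "*" if c.opposite_between_classes else "",
            c.min_p,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["variant_id", "classes", "opposite_direction", "min_p"]
    )
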