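"""Permutation-derived empirical significance thresholds.

Because tests across correlated phenotypes and linked SNPs are far from
independent, a Bonferroni bound is miscalibrated for this design; the
empirical alternative re-runs the entire scan on label-permuted data.
Within each study the whole phenotype block (all phenotype columns
together, and by default the sex covariate with them) is permuted against
the genotype matrix, preserving both the genotype-genotype and the
phenotype-phenotype correlation structure.  Genotype-derived principal
components stay with the genotypes.

For each permuted dataset and each candidate p-value threshold the
procedure counts (a) replicated (variant, class) pairs — sub-threshold in
two or more studies with a common harmonized direction — and (b) variants
with two or more such classes.  Comparing observed to permuted counts
yields an add-one empirical p-value ``(1 + #{permuted >= observed}) /
(B + 1)`` per threshold and count type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import run_study_phewas
from .classes import PhenotypeClassMap
from .model import CovariateTable, PhenotypeTable, StudyCohort

__all__ = [
    "PermutationSummary",
    "permute_study",
    "count_replication",
    "permutation_phewas",
    "empirical_summary",
]

DEFAULT_THRESHOLDS = (1e-2, 1e-3, 1e-4, 1e-5)


@dataclass
class PermutationSummary:
    """Observed vs permuted replication counts across thresholds.

    ``observed`` has shape ``(T, 2)`` and ``permuted`` ``(B, T, 2)`` where
    the last axis is (n_replicated, n_multiclass).
    """

    B: int
    thresholds: tuple[float, ...]
    observed: np.ndarray
    permuted: np.ndarray

    @property
    def empirical_p(self) -> np.ndarray:
        """Add-one estimator per (threshold, count type); always in (0, 1]."""
        exceed = (self.permuted >= self.observed[None, :, :]).sum(axis=0)
        return (1.0 + exceed) / (self.B + 1.0)


def permute_study(
    cohort: StudyCohort,
    rng: np.random.Generator | None = None,
    permutation: np.ndarray | None = None,
    permute_sex: bool = True,
) -> StudyCohort:
    """Randomize genotype-phenotype pairing within one study.

    One uniform permutation of sample labels is applied jointly to every
    phenotype column (and, by default, to sex, which belongs to the
    phenotype side of the pairing); genotypes, local ancestry and the
    genotype-derived PCs are untouched.  An explicit ``permutation`` array
    overrides the random draw (useful for exhaustive enumeration).
    """
    n = len(cohort.genotypes.samples)
    if permutation is None:
        if rng is None:
            raise ValueError("provide rng or an explicit permutation")
        permutation = rng.permutation(n)
    else:
        permutation = np.asarray(permutation)
        if sorted(permutation.tolist()) != list(range(n)):
            raise ValueError("not a permutation of range(n)")
    values = cohort.phenotypes.values
    new_values = pd.DataFrame(
        values.to_numpy()[permutation],
        index=values.index,
        columns=values.columns,
    )
    for col, kind in cohort.phenotypes.kinds.items():
        if kind in ("continuous", "binary"):
            new_values[col] = pd.to_numeric(new_values[col])
    new_table = PhenotypeTable(cohort.study, new_values, cohort.phenotypes.kinds)
    cov = cohort.covariates
    new_cov = CovariateTable(
        samples=cov.samples,
        pc1=cov.pc1,
        pc2=cov.pc2,
        sex=cov.sex[permutation] if permute_sex else cov.sex,
        female_only_study=cov.female_only_study,
    )
    return StudyCohort(
        study=cohort.study,
        genotypes=cohort.genotypes,
        phenotypes=new_table,
        covariates=new_cov,
        local_ancestry=cohort.local_ancestry,
    )


def count_replication(
    records: pd.DataFrame,
    class_map: PhenotypeClassMap,
    thresholds: tuple[float, ...],
) -> np.ndarray:
    """(n_replicated, n_multiclass) per threshold for a pooled record frame.

    A (variant, class) pair counts as replicated at threshold t when some
    harmonized direction is supported by sub-threshold records from >= 2
    distinct studies; a variant counts as multi-class when >= 2 of its
    classes replicate.
    """
    out = np.zeros((len(thresholds), 2), dtype=int)
    if records.empty:
        return out
    ps = records["p"].to_numpy(dtype=float)
    pre = ps < max(thresholds)
    if not pre.any():
        return out
    studies = records["study"].to_numpy()[pre]
    phens = records["phenotype"].to_numpy()[pre]
    betas = records["beta"].to_numpy(dtype=float)[pre]
    vids = records["variant_id"].to_numpy()[pre]
    ps = ps[pre]

    # integer-code (class, polarity), study and variant per record
    cls_code = np.empty(ps.size, dtype=np.int64)
    pol = np.empty(ps.size, dtype=np.int64)
    cls_ids: dict[str, int] = {}
    cache: dict[tuple[str, str], tuple[int, int]] = {}
    for i, key in enumerate(zip(studies, phens)):
        hit = cache.get(key)
        if hit is None:
            ent = class_map.lookup(*key)
            if ent is None:
                hit = (-1, 0)
            else:
                hit = (cls_ids.setdefault(ent[0], len(cls_ids)), ent[1])
            cache[key] = hit
        cls_code[i], pol[i] = hit
    scode = pd.factorize(studies)[0]
    vcode = pd.factorize(vids)[0]
    n_cls = max(len(cls_ids), 1)
    n_st = scode.max() + 1

    sign = np.sign(betas) * pol
    valid = (cls_code >= 0) & (sign != 0)
    dircode = (sign > 0).astype(np.int64)
    key_pair = (vcode * n_cls + cls_code) * 2 + dircode  # (variant, class, direction)
    key_full = key_pair * n_st + scode

    for i, t in enumerate(thresholds):
        mask = valid & (ps < t)
        if not mask.any():
            continue
        uniq_full = np.unique(key_full[mask])
        pair_dir, support = np.unique(uniq_full // n_st, return_counts=True)
        replicated = pair_dir[support >= 2]
        if replicated.size == 0:
            continue
        vc_pairs = np.unique(replicated // 2)
        out[i, 0] = vc_pairs.size
        _, classes_per_variant = np.unique(vc_pairs // n_cls, return_counts=True)
        out[i, 1] = int((classes_per_variant >= 2).sum())
    return out


def permutation_phewas(
    cohorts: list[StudyCohort],
    B: int,
    class_map: PhenotypeClassMap,
    rng: np.random.Generator,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    permute_sex: bool = True,
    **scan_kwargs,
) -> PermutationSummary:
    """Observed and permuted replication counts over B permuted datasets.

    Each replicate permutes every study independently and re-runs the full
    scan with the same code path used for the observed data.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    thresholds = tuple(thresholds)
    observed_frames = [run_study_phewas(c, **scan_kwargs) for c in cohorts]
    observed = count_replication(
        pd.concat(observed_frames, ignore_index=True), class_map, thresholds
    )
    permuted = np.zeros((B, len(thresholds), 2), dtype=int)
    for b in range(B):
        frames = [
            run_study_phewas(permute_study(c, rng, permute_sex=permute_sex), **scan_kwargs)
            for c in cohorts
        ]
        permuted[b] = count_replication(
            pd.concat(frames, ignore_index=True), class_map, thresholds
        )
    return PermutationSummary(
        B=B, thresholds=thresholds, observed=observed, permuted=permuted
    )


def empirical_summary(summary: PermutationSummary, alpha: float = 0.05) -> dict:
    """Threshold recommendation report.

    Per threshold: observed counts, permuted mean and max, and empirical p
    for both count types.  The recommended threshold is the largest one
    whose multi-class empirical p is <= ``alpha`` — loose enough to explore
    the data, stringent enough that chance alone rarely matches it.
    """
    emp = summary.empirical_p
    rows = []
    for i, t in enumerate(summary.thresholds):
        rows.append(
            {
                "threshold": t,
                "observed_replicated": int(summary.observed[i, 0]),
                "observed_multiclass": int(summary.observed[i, 1]),
                "permuted_mean_replicated": float(summary.permuted[:, i, 0].mean()),
                "permuted_max_replicated": int(summary.permuted[:, i, 0].max()),
                "permuted_mean_multiclass": float(summary.permuted[:, i, 1].mean()),
                "permuted_max_multiclass": int(summary.permuted[:, i, 1].max()),
                "empirical_p_replicated": float(emp[i, 0]),
                "empirical_p_multiclass": float(emp[i, 1]),
            }
        )
    eligible = [
        r["threshold"] for r in rows if r["empirical_p_multiclass"] <= alpha
    ]
    return {
        "B": summary.B,
        "alpha": alpha,
        "per_threshold": rows,
        "recommended_threshold": max(eligible) if eligible else None,
    }
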