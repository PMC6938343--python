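"""Local-ancestry summaries at called loci.

African American genomes are admixed: at any locus an individual carries
0, 1 or 2 allele copies inherited from the African ancestral population.
Given externally estimated local-ancestry calls (e.g. LAMP-LD output as a
samples x variants 0/1/2 matrix), this module profiles each locus — the
fraction of individuals with 0/1/2 African-derived copies and the implied
proportion of African-derived alleles — and classifies it relative to the
genome-wide average: "admixed" when consistent with the global proportion,
otherwise "african_derived" or "european_derived" depending on the sign of
the deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AncestryLocusProfile",
    "locus_profile",
    "global_ancestry",
    "classify_locus",
    "profile_loci",
]

#: Default half-width of the "consistent with global ancestry" band.
DEFAULT_TOL = 0.10


@dataclass
class AncestryLocusProfile:
    """Fractions of individuals carrying 0/1/2 African-derived alleles."""

    variant_id: str
    f0: float
    f1: float
    f2: float
    classification: Optional[str] = None

    def __post_init__(self) -> None:
        total = self.f0 + self.f1 + self.f2
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.variant_id}: fractions sum to {total}, not 1")

    @property
    def prop_african(self) -> float:
        """Proportion of African-derived alleles at the locus."""
        return (self.f1 + 2.0 * self.f2) / 2.0


def locus_profile(ancestry_column, variant_id: str = "") -> AncestryLocusProfile:
    """Profile one locus from a 0/1/2 African-copy column (NaN = missing)."""
    col = np.asarray(ancestry_column, dtype=float)
    mask = np.isfinite(col)
    if not mask.any():
        raise ValueError(f"{variant_id or 'locus'}: all ancestry calls missing")
    col = col[mask]
    if not np.isin(col, (0.0, 1.0, 2.0)).all():
        raise ValueError(f"{variant_id or 'locus'}: entries must be 0, 1 or 2")
    n = col.size
    return AncestryLocusProfile(
        variant_id=variant_id,
        f0=float((col == 0).sum() / n),
        f1=float((col == 1).sum() / n),
        f2=float((col == 2).sum() / n),
    )


def global_ancestry(local_ancestry: np.ndarray) -> float:
    """Genome-wide African ancestry proportion from a 0/1/2 call matrix.

    The mean African-copy count over all non-missing entries, divided
    by 2.
    """
    arr = np.asarray(local_ancestry, dtype=float)
    mask = np.isfinite(arr)
    if not mask.any():
        raise ValueError("empty local-ancestry matrix")
    return float(arr[mask].mean() / 2.0)


def classify_locus(
    profile: AncestryLocusProfile, global_prop: float, tol: float = DEFAULT_TOL
) -> str:
    """Classify a locus against the genome-wide African proportion.

    ``admixed`` when |prop_african - global| <= tol, else ``african_derived``
    above the global proportion and ``european_derived`` below it.
    """
    if not (0.0 <= global_prop <= 1.0):
        raise ValueError("global_prop must be in [0,1]")
    delta = profile.prop_african - global_prop
    if abs(delta) <= tol:
        return "admixed"
    return "african_derived" if delta > 0 else "european_derived"


def profile_loci(
    local_ancestry: np.ndarray,
    variant_ids,
    global_prop: Optional[float] = None,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Per-locus ancestry report for a samples x variants call matrix.

    When ``global_prop`` is None it is estimated from the matrix itself.
    Returns percentages of individuals with 0/1/2 African copies (matching
    the published report layout), the African-allele proportion and the
    classification per variant.
    """
    arr = np.asarray(local_ancestry, dtype=float)
    if global_prop is None:
        global_prop = global_ancestry(arr)
    rows = []
    for j, vid in enumerate(variant_ids):
        prof = locus_profile(arr[:, j], vid)
        rows.append(
            {
                "variant_id": vid,
                "pct0": 100.0 * prof.f0,
                "pct1": 100.0 * prof.f1,
                "pct2": 100.0 * prof.f2,
                "prop_african": prof.prop_african,
                "classification": classify_locus(prof, global_prop, tol),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["global_prop_african"] = global_prop
    return out
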