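"""Synthetic multi-study admixed cohorts with known pleiotropic architecture.

The generator emulates the study conditions the pipeline targets: three
unequal-size epidemiologic cohorts (one female-only) sharing a variant
panel but not samples, two-way admixed genotypes whose per-haplotype
ancestry follows a Markov chain along the chromosome (stationary African
probability 0.788 by default), allele frequencies drawn per ancestral
origin, and phenotypes generated from latent per-class scores so that one
SNP can drive several correlated phenotypes in a class — the structure the
class-level replication filter aggregates over.

Genotype effects are specified in standardized-dosage units via a
variant x class effect matrix; a phenotype inherits its class score scaled
by a loading and a coding polarity, plus independent Gaussian noise.
Binary phenotypes threshold a latent logistic draw at a configured
prevalence; categorical phenotypes bin a continuous latent into tertiles.
Fixing the seed fixes every downstream number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .association import compute_pcs
from .model import CovariateTable, GenotypeMatrix, PhenotypeTable, StudyCohort, Variant

__all__ = [
    "PhenotypeSpec",
    "SimulationConfig",
    "simulate_local_ancestry",
    "simulate_genotypes",
    "simulate_phenotypes",
    "build_multistudy_dataset",
    "null_config",
    "signal_config",
]


@dataclass
class PhenotypeSpec:
    """One simulated phenotype: its class membership and generative knobs."""

    name: str
    phenotype_class: str
    kind: str = "continuous"
    loading: float = 1.0
    polarity: int = 1
    prevalence: float = 0.5  # binary only
    n_categories: int = 3  # categorical only

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.polarity not in (1, -1):
            raise ValueError(f"{self.name}: polarity must be +1/-1")
        if self.kind == "binary" and not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-study dataset.

    Defaults mirror the emulated design: study sizes 3430/549/2186 with the
    third study female-only, 78.8% stationary African ancestry, and an
    ancestry switch rate of 1e-7 per basepair (per-interval switch
    probability ``1 - exp(-rate * distance)``).
    """

    n_per_study: tuple[int, ...] = (3430, 549, 2186)
    study_names: tuple[str, ...] = ("cohort1", "cohort2", "cohort3")
    female_only: tuple[str, ...] = ("cohort3",)
    m_variants: int = 100
    spacing_bp: int = 4000
    global_african: float = 0.788
    ancestry_switch_rate: float = 1e-7
    maf_afr: Optional[np.ndarray] = None  # per-variant; default U(0.05, 0.5)
    maf_eur: Optional[np.ndarray] = None
    classes: tuple[str, ...] = ()
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    effect_matrix: Optional[np.ndarray] = None  # m_variants x len(classes)
    class_noise_sd: float = 0.5
    noise_sd: float = 1.0
    availability: Optional[dict[str, frozenset[str]]] = None  # study -> phenotype names
    n_duplicate_pairs: int = 0  # last k variants duplicate the first k (LD blocks)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_study) != len(self.study_names):
            raise ValueError("n_per_study and study_names lengths differ")
        if any(n < 2 for n in self.n_per_study):
            raise ValueError("every study needs n >= 2")
        if not (0.0 <= self.global_african <= 1.0):
            raise ValueError("global_african must be in [0,1]")
        if self.ancestry_switch_rate < 0:
            raise ValueError("ancestry_switch_rate must be >= 0")
        for name in ("maf_afr", "maf_eur"):
            maf = getattr(self, name)
            if maf is not None:
                maf = np.asarray(maf, float)
                if maf.shape != (self.m_variants,):
                    raise ValueError(f"{name} must have length m_variants")
                if ((maf <= 0) | (maf > 0.5)).any():
                    raise ValueError(f"{name} values must be in (0, 0.5]")
                setattr(self, name, maf)
        if self.effect_matrix is not None:
            eff = np.asarray(self.effect_matrix, float)
            if eff.shape != (self.m_variants, len(self.classes)):
                raise ValueError(
                    f"effect_matrix shape {eff.shape} != "
                    f"({self.m_variants}, {len(self.classes)})"
                )
            self.effect_matrix = eff
        declared = {p.phenotype_class for p in self.phenotypes}
        undeclared = declared - set(self.classes)
        if undeclared:
            raise ValueError(f"phenotype classes not declared: {sorted(undeclared)}")
        if self.availability is not None:
            names = {p.name for p in self.phenotypes}
            covered = set().union(*self.availability.values()) if self.availability else set()
            orphans = names - covered
            if orphans:
                raise ValueError(f"availability mask leaves phenotypes in no study: {sorted(orphans)}")
        if not (0 <= self.n_duplicate_pairs <= self.m_variants // 2):
            raise ValueError("n_duplicate_pairs out of range")

    @property
    def positions(self) -> np.ndarray:
        return (np.arange(self.m_variants) + 1) * self.spacing_bp


def simulate_local_ancestry(
    config: SimulationConfig, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-haplotype ancestry tracks and the per-genotype African-copy matrix.

    Each of the ``2 * n_samples`` haplotypes is a two-state Markov chain
    along position: the initial state is African with the stationary
    probability, and on each inter-variant interval a switch event occurs
    with probability ``1 - exp(-switch_rate * distance)``, after which the
    state is redrawn from the stationary distribution (so the chain stays
    stationary at ``global_african``).

    Returns ``(tracks, copies)``: ``tracks`` is ``(2n, m)`` of 0/1 African
    indicators, ``copies`` is ``(n, m)`` summing each sample's two
    haplotypes.
    """
    m = config.m_variants
    pi = config.global_african
    h = 2 * n_samples
    tracks = np.empty((h, m), dtype=np.int8)
    tracks[:, 0] = rng.random(h) < pi
    if m > 1:
        dist = np.diff(config.positions)
        s = 1.0 - np.exp(-config.ancestry_switch_rate * dist)
        switch = rng.random((h, m - 1)) < s[None, :]
        redraw = rng.random((h, m - 1)) < pi
        for j in range(1, m):
            prev = tracks[:, j - 1]
            sw = switch[:, j - 1]
            tracks[:, j] = np.where(sw, redraw[:, j - 1], prev)
    copies = tracks[0::2] + tracks[1::2]
    return tracks, copies.astype(float)


def simulate_genotypes(
    tracks: np.ndarray,
    maf_afr: np.ndarray,
    maf_eur: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dosage matrix from haplotype ancestry tracks and per-origin frequencies.

    Each haplotype's allele is Bernoulli with the frequency matched to its
    ancestral origin at that variant; a sample's dosage sums its two
    haplotypes.
    """
    maf_afr = np.asarray(maf_afr, float)
    maf_eur = np.asarray(maf_eur, float)
    for name, maf in (("maf_afr", maf_afr), ("maf_eur", maf_eur)):
        if ((maf < 0) | (maf > 1)).any():
            raise ValueError(f"{name} outside [0,1]")
    freq = np.where(tracks == 1, maf_afr[None, :], maf_eur[None, :])
    alleles = (rng.random(tracks.shape) < freq).astype(np.int8)
    dosage = alleles[0::2] + alleles[1::2]
    return dosage.astype(float)


def _class_scores(
    Z: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n = Z.shape[0]
    eff = (
        config.effect_matrix
        if config.effect_matrix is not None
        else np.zeros((config.m_variants, len(config.classes)))
    )
    scores = {}
    for c_idx, cls in enumerate(config.classes):
        genetic = Z @ eff[:, c_idx]
        shared = config.class_noise_sd * rng.standard_normal(n)
        scores[cls] = genetic + shared
    return scores


def simulate_phenotypes(
    study: str,
    dosage: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: Sequence[str],
    female_only: bool,
) -> tuple[PhenotypeTable, CovariateTable]:
    """Phenotype and covariate tables for one study's dosage matrix.

    Dosages are standardized within the study (constant columns contribute
    zero), class scores combine genetic effects with shared class noise,
    and each phenotype applies its polarity, loading and independent noise.
    Covariates: PC1/PC2 from the study genotypes, sex Bernoulli(0.5)
    except in a female-only study.
    """
    n = dosage.shape[0]
    mean = np.nanmean(dosage, axis=0)
    sd = np.nanstd(dosage, axis=0)
    sd[sd == 0] = 1.0
    Z = (np.nan_to_num(dosage, nan=0.0) - mean) / sd
    scores = _class_scores(Z, config, rng)

    available = None
    if config.availability is not None:
        available = config.availability.get(study, frozenset())

    values = {}
    kinds = {}
    for spec in config.phenotypes:
        # draw this phenotype's noise regardless of availability so that the
        # random stream (and hence other studies' data) is mask-invariant
        signal = spec.polarity * spec.loading * scores[spec.phenotype_class]
        if spec.kind == "continuous":
            y = signal + config.noise_sd * rng.standard_normal(n)
        elif spec.kind == "binary":
            eta = logit(spec.prevalence) + signal
            y = (rng.random(n) < expit(eta)).astype(float)
        else:
            latent = signal + config.noise_sd * rng.standard_normal(n)
            edges = np.quantile(latent, np.linspace(0, 1, spec.n_categories + 1)[1:-1])
            bins = np.digitize(latent, edges)
            y = np.array([f"cat{b}" for b in bins], dtype=object)
        if available is not None and spec.name not in available:
            continue
        values[spec.name] = y
        kinds[spec.name] = spec.kind

    frame = pd.DataFrame(values, index=list(sample_ids))
    table = PhenotypeTable(study, frame, kinds)

    pcs = compute_pcs(dosage, k=2)
    if female_only:
        sex = np.array(["F"] * n, dtype=object)
    else:
        sex = np.where(rng.random(n) < 0.5, "F", "M").astype(object)
    cov = CovariateTable(
        samples=list(sample_ids),
        pc1=pcs[:, 0],
        pc2=pcs[:, 1],
        sex=sex,
        female_only_study=female_only,
    )
    return table, cov


def build_multistudy_dataset(config: SimulationConfig) -> list[StudyCohort]:
    """Simulate every study cohort of the configured design.

    Studies share the variant panel but have disjoint samples; the same
    seed reproduces the identical dataset byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_variants
    maf_afr = (
        config.maf_afr
        if config.maf_afr is not None
        else rng.uniform(0.05, 0.5, size=m)
    )
    maf_eur = (
        config.maf_eur
        if config.maf_eur is not None
        else rng.uniform(0.05, 0.5, size=m)
    )

    positions = config.positions
    ndup = config.n_duplicate_pairs
    variants = []
    for j in range(m):
        if ndup and j >= m - ndup:
            twin = j - (m - ndup)
            vid = f"snp{twin:05d}_dup"
        else:
            vid = f"snp{j:05d}"
        variants.append(Variant(vid, "1", int(positions[j]), ("A", "G"), "G"))

    cohorts = []
    offset = 0
    for study, n in zip(config.study_names, config.n_per_study):
        sample_ids = [f"{study}_s{offset + i:06d}" for i in range(n)]
        offset += n
        tracks, copies = simulate_local_ancestry(config, n, rng)
        dosage = simulate_genotypes(tracks, maf_afr, maf_eur, rng)
        if ndup:
            dosage[:, m - ndup:] = dosage[:, : ndup]
            copies[:, m - ndup:] = copies[:, : ndup]
        female = study in config.female_only
        table, cov = simulate_phenotypes(study, dosage, config, rng, sample_ids, female)
        gm = GenotypeMatrix(sample_ids, variants, dosage)
        cohorts.append(
            StudyCohort(
                study=study,
                genotypes=gm,
                phenotypes=table,
                covariates=cov,
                local_ancestry=copies,
            )
        )
    return cohorts


def class_map_from_config(config: SimulationConfig):
    """The phenotype-class map implied by a simulation design.

    Every (study, phenotype) pair maps to the phenotype's generating class
    with the generating polarity, so harmonized directions undo any
    inverse coding the generator applied.
    """
    from .classes import PhenotypeClassMap

    entries = {}
    for study in config.study_names:
        for spec in config.phenotypes:
            if config.availability is not None and spec.name not in config.availability.get(
                study, frozenset()
            ):
                continue
            entries[(study, spec.name)] = (spec.phenotype_class, spec.polarity)
    return PhenotypeClassMap(entries)


# ---------------------------------------------------------------------------
# ready-made configurations


def null_config(
    n_per_study=(300, 120, 200),
    m_variants=50,
    n_phenotypes=12,
    n_classes=4,
    seed=0,
    **overrides,
) -> SimulationConfig:
    """A no-effect design: phenotypes spread round-robin over classes."""
    classes = tuple(f"class{k}" for k in range(n_classes))
    phenos = tuple(
        PhenotypeSpec(name=f"pheno{i:03d}", phenotype_class=classes[i % n_classes])
        for i in range(n_phenotypes)
    )
    return SimulationConfig(
        n_per_study=tuple(n_per_study),
        study_names=tuple(f"cohort{i+1}" for i in range(len(n_per_study))),
        female_only=(f"cohort{len(n_per_study)}",),
        m_variants=m_variants,
        classes=classes,
        phenotypes=phenos,
        seed=seed,
        **overrides,
    )


def signal_config(
    effect: float = 0.15,
    signal_variant: int = 0,
    signal_classes: tuple[int, int] = (0, 1),
    **kwargs,
) -> SimulationConfig:
    """A null design plus one pleiotropic SNP acting on two classes.

    ``effect`` is the standardized per-allele effect on each target class's
    latent score.
    """
    cfg = null_config(**kwargs)
    eff = np.zeros((cfg.m_variants, len(cfg.classes)))
    for c in signal_classes:
        eff[signal_variant, c] = effect
    return SimulationConfig(
        **{
            **{k: getattr(cfg, k) for k in (
                "n_per_study", "study_names", "female_only", "m_variants",
                "spacing_bp", "global_african", "ancestry_switch_rate",
                "maf_afr", "maf_eur", "classes", "phenotypes",
                "class_noise_sd", "noise_sd", "availability",
                "n_duplicate_pairs", "seed",
            )},
            "effect_matrix": eff,
        }
    )
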