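"""Synthetic multi-study cohort generator."""

import numpy as np
import pytest
from scipy import stats

from pleiopheno import simulate as sim


class TestConfigValidation:
    def test_tiny_study_is_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            sim.null_config(n_per_study=(1, 50))

    def test_negative_switch_rate_is_rejected(self):
        with pytest.raises(ValueError, match="switch_rate"):
            sim.null_config(ancestry_switch_rate=-1e-8)

    def test_bad_prevalence_is_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            sim.PhenotypeSpec("x", "c", kind="binary", prevalence=1.5)

    def test_orphaned_phenotype_in_availability_mask_is_rejected(self):
        cfg_kwargs = dict(n_per_study=(10, 10), n_phenotypes=2, n_classes=1)
        with pytest.raises(ValueError, match="no study"):
            sim.null_config(
                availability={"cohort1": frozenset({"pheno000"}), "cohort2": frozenset()},
                **cfg_kwargs,
            )

    def test_maf_outside_range_is_rejected(self):
        with pytest.raises(ValueError, match="maf_afr"):
            sim.null_config(m_variants=2, maf_afr=np.array([0.0, 0.3]))


class TestLocalAncestry:
    def test_zero_switch_rate_gives_constant_haplotypes(self, rng):
        cfg = sim.null_config(m_variants=40, ancestry_switch_rate=0.0)
        tracks, copies = sim.simulate_local_ancestry(cfg, 2000, rng)
        assert (tracks == tracks[:, [0]]).all()
        frac = tracks[:, 0].mean()
        se = np.sqrt(0.788 * 0.212 / tracks.shape[0])
        assert abs(frac - 0.788) < 4 * se

    def test_all_african_gives_all_two_copies(self, rng):
        cfg = sim.null_config(global_african=1.0, m_variants=10)
        _, copies = sim.simulate_local_ancestry(cfg, 50, rng)
        assert (copies == 2).all()

    def test_empirical_transition_frequency_matches_the_formula(self, rng):
        rate, spacing = 2e-6, 5000
        cfg = sim.null_config(
            m_variants=2, ancestry_switch_rate=rate, spacing_bp=spacing
        )
        tracks, _ = sim.simulate_local_ancestry(cfg, 5000, rng)  # 10^4 haplotypes
        s = 1.0 - np.exp(-rate * spacing)
        pi = cfg.global_african
        # African -> European requires a switch event and a European redraw
        start_afr = tracks[:, 0] == 1
        p_change = s * (1 - pi)
        observed = (tracks[start_afr, 1] == 0).mean()
        se = np.sqrt(p_change * (1 - p_change) / start_afr.sum())
        assert abs(observed - p_change) < 3 * se


class TestGenotypes:
    def test_caf_matches_balanced_frequencies(self, rng):
        cfg = sim.null_config(m_variants=1)
        tracks, _ = sim.simulate_local_ancestry(cfg, 5000, rng)
        dosage = sim.simulate_genotypes(tracks, np.array([0.5]), np.array([0.5]), rng)
        caf = dosage.mean() / 2.0
        assert 0.48 <= caf <= 0.52

    def test_zero_frequency_gives_all_zero_dosages(self, rng):
        cfg = sim.null_config(m_variants=3)
        tracks, _ = sim.simulate_local_ancestry(cfg, 100, rng)
        dosage = sim.simulate_genotypes(tracks, np.zeros(3), np.zeros(3), rng)
        assert (dosage == 0).all()

    def test_frequency_outside_unit_interval_is_an_error(self, rng):
        cfg = sim.null_config(m_variants=1)
        tracks, _ = sim.simulate_local_ancestry(cfg, 10, rng)
        with pytest.raises(ValueError, match="outside"):
            sim.simulate_genotypes(tracks, np.array([1.2]), np.array([0.5]), rng)

    def test_within_origin_genotypes_are_in_hardy_weinberg(self, rng):
        # single-origin population so every haplotype draws one frequency
        m = 1000
        cfg = sim.null_config(
            m_variants=m, global_african=1.0, maf_afr=np.full(m, 0.3),
            maf_eur=np.full(m, 0.3),
        )
        tracks, _ = sim.simulate_local_ancestry(cfg, 1000, rng)
        dosage = sim.simulate_genotypes(tracks, cfg.maf_afr, cfg.maf_eur, rng)
        fails = 0
        for j in range(m):
            col = dosage[:, j]
            n = col.size
            q = col.mean() / 2.0
            expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            observed = np.array([(col == k).sum() for k in (0, 1, 2)])
            chi2 = ((observed - expected) ** 2 / expected).sum()
            if stats.chi2.sf(chi2, df=1) < 0.001:
                fails += 1
        assert fails <= 10  # >= 99% pass at alpha 0.001


class TestPhenotypes:
    def test_opposite_polarity_classmates_have_opposite_betas(self):
        classes = ("c0",)
        phenos = (
            sim.PhenotypeSpec("plus", "c0", polarity=1),
            sim.PhenotypeSpec("minus", "c0", polarity=-1),
        )
        eff = np.zeros((20, 1))
        eff[0, 0] = 0.5
        cfg = sim.SimulationConfig(
            n_per_study=(2000,), study_names=("S1",), female_only=(),
            m_variants=20, classes=classes, phenotypes=phenos, effect_matrix=eff,
            seed=5,
        )
        (cohort,) = sim.build_multistudy_dataset(cfg)
        g = cohort.genotypes.dosage[:, 0]
        z = (g - g.mean()) / g.std()
        b_plus = np.polyfit(z, cohort.phenotypes.values["plus"], 1)[0]
        b_minus = np.polyfit(z, cohort.phenotypes.values["minus"], 1)[0]
        assert b_plus > 0 > b_minus
        assert b_plus == pytest.approx(-b_minus, abs=0.1)

    def test_classmates_share_noise_hence_correlate(self):
        # two unit-loading phenotypes of one class: corr = s^2/(s^2 + n^2)
        cfg = sim.null_config(
            n_per_study=(4000,), n_phenotypes=2, n_classes=1, seed=9,
            class_noise_sd=1.0, noise_sd=1.0,
        )
        (cohort,) = sim.build_multistudy_dataset(
            sim.SimulationConfig(
                **{**cfg.__dict__, "study_names": ("S1",), "n_per_study": (4000,),
                   "female_only": ()}
            )
        )
        vals = cohort.phenotypes.values
        r = np.corrcoef(vals["pheno000"], vals["pheno001"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.06)

    def test_binary_prevalence_is_respected(self):
        phenos = (sim.PhenotypeSpec("d", "c0", kind="binary", prevalence=0.2),)
        cfg = sim.SimulationConfig(
            n_per_study=(5000,), study_names=("S1",), female_only=(),
            m_variants=5, classes=("c0",), phenotypes=phenos, seed=2,
        )
        (cohort,) = sim.build_multistudy_dataset(cfg)
        assert cohort.phenotypes.values["d"].mean() == pytest.approx(0.2, abs=0.03)

    def test_categorical_bins_into_requested_labels(self):
        phenos = (sim.PhenotypeSpec("cat", "c0", kind="categorical", n_categories=3),)
        cfg = sim.SimulationConfig(
            n_per_study=(300,), study_names=("S1",), female_only=(),
            m_variants=5, classes=("c0",), phenotypes=phenos, seed=2,
        )
        (cohort,) = sim.build_multistudy_dataset(cfg)
        assert set(cohort.phenotypes.values["cat"]) == {"cat0", "cat1", "cat2"}


class TestMultistudyDataset:
    def test_default_design_echoes_configured_sizes(self):
        cfg = sim.null_config(n_per_study=(40, 15, 25), m_variants=8, seed=1)
        cohorts = sim.build_multistudy_dataset(cfg)
        assert [c.genotypes.n_samples for c in cohorts] == [40, 15, 25]
        assert len({s for c in cohorts for s in c.genotypes.samples}) == 80  # disjoint
        assert [c.genotypes.variant_ids for c in cohorts][0] == cohorts[1].genotypes.variant_ids

    def test_same_seed_reproduces_the_dataset_exactly(self):
        cfg = sim.null_config(n_per_study=(30, 20), m_variants=6, seed=11)
        a = sim.build_multistudy_dataset(cfg)
        b = sim.build_multistudy_dataset(cfg)
        for ca, cb in zip(a, b):
            assert ca.genotypes == cb.genotypes
            assert ca.phenotypes.values.equals(cb.phenotypes.values)
            np.testing.assert_array_equal(ca.covariates.sex, cb.covariates.sex)
            np.testing.assert_array_equal(ca.local_ancestry, cb.local_ancestry)

    def test_last_study_is_female_only(self):
        cfg = sim.null_config(n_per_study=(20, 20, 20), m_variants=5, seed=3)
        cohorts = sim.build_multistudy_dataset(cfg)
        assert cohorts[2].covariates.female_only_study
        assert set(cohorts[2].covariates.sex) == {"F"}
        assert not cohorts[0].covariates.female_only_study

    def test_availability_mask_limits_study_phenotypes(self):
        cfg = sim.null_config(
            n_per_study=(20, 20), n_phenotypes=3, n_classes=1, m_variants=5,
            availability={
                "cohort1": frozenset({"pheno000", "pheno001"}),
                "cohort2": frozenset({"pheno001", "pheno002"}),
            },
        )
        cohorts = sim.build_multistudy_dataset(cfg)
        assert cohorts[0].phenotypes.phenotypes == ["pheno000", "pheno001"]
        assert cohorts[1].phenotypes.phenotypes == ["pheno001", "pheno002"]

    def test_duplicate_pairs_create_perfect_ld_blocks(self):
        cfg = sim.null_config(m_variants=10, n_duplicate_pairs=2, seed=4)
        cohorts = sim.build_multistudy_dataset(cfg)
        gm = cohorts[0].genotypes
        np.testing.assert_array_equal(gm.dosage[:, 8], gm.dosage[:, 0])
        assert gm.variant_ids[8] == "snp00000_dup"
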