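"""Single-SNP test machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiopheno.association import (
    AssociationSkipped,
    compute_pcs,
    expand_phenotype,
    linear_association,
    logistic_association,
    run_study_phewas,
)
from pleiopheno.model import CovariateTable, PhenotypeTable, StudyCohort

from conftest import make_matrix


# ---------------------------------------------------------------------------
# oracles


def ols_oracle(y, g, C=None):
    """Normal equations + t distribution, independent of the implementation."""
    X = [np.ones_like(y), g]
    if C is not None:
        X.extend(np.atleast_2d(C.T))
    X = np.column_stack(X)
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ y
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = coef[1] / se
    return coef[1], se, 2 * stats.t.sf(abs(t), df)


def logit_oracle(y, g, C=None):
    """Newton iteration on the logit log-likelihood, written independently."""
    X = [np.ones_like(y), g]
    if C is not None:
        X.extend(np.atleast_2d(C.T))
    X = np.column_stack(X)
    b = np.zeros(X.shape[1])
    for _ in range(200):
        mu = 1.0 / (1.0 + np.exp(-(X @ b)))
        grad = X.T @ (y - mu)
        H = X.T @ (X * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = 1.0 / (1.0 + np.exp(-(X @ b)))
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    se = np.sqrt(cov[1, 1])
    return b[1], se, 2 * stats.norm.sf(abs(b[1] / se))


# ---------------------------------------------------------------------------
# principal components


class TestComputePCs:
    def test_scores_of_distinct_components_are_orthogonal(self, rng):
        X = rng.integers(0, 3, size=(40, 20)).astype(float)
        scores = compute_pcs(make_matrix(X), k=3)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * 40

    def test_matches_independent_eigendecomposition(self, rng):
        for _ in range(20):
            X = rng.normal(size=(50, 30))
            Z = (X - X.mean(0)) / X.std(0)
            # oracle: eigenvectors of the sample covariance
            cov = Z.T @ Z / 50
            w, V = np.linalg.eigh(cov)
            order = np.argsort(w)[::-1]
            oracle = Z @ V[:, order[:2]]
            got = compute_pcs(X, k=2)
            for j in range(2):
                s = np.sign(oracle[:, j] @ got[:, j])
                np.testing.assert_allclose(got[:, j], s * oracle[:, j], atol=1e-8)

    def test_pc1_separates_two_ancestry_groups(self, rng):
        # two groups with very different allele frequencies at every SNP
        a = rng.binomial(2, 0.9, size=(30, 40)).astype(float)
        b = rng.binomial(2, 0.1, size=(30, 40)).astype(float)
        scores = compute_pcs(np.vstack([a, b]), k=2)
        pc1 = scores[:, 0]
        assert pc1[:30].min() > pc1[30:].max() or pc1[:30].max() < pc1[30:].min()

    def test_k_beyond_rank_is_an_error(self):
        X = np.tile([[0.0], [1.0], [2.0]], (1, 4))  # rank 1 after standardizing
        with pytest.raises(ValueError, match="rank"):
            compute_pcs(X, k=2)

    def test_missing_dosages_are_mean_imputed(self, rng):
        X = rng.integers(0, 3, size=(30, 10)).astype(float)
        X[3, 2] = np.nan
        scores = compute_pcs(X, k=2)
        assert np.isfinite(scores).all()


# ---------------------------------------------------------------------------
# phenotype expansion


class TestExpandPhenotype:
    def test_continuous_gets_raw_and_natural_log_plus_one(self):
        y = np.array([0.0, 1.0, np.e - 1])
        resp = expand_phenotype(y, "continuous", "x")
        assert [r.transform for r in resp] == ["raw", "log1p"]
        assert all(r.model == "linear" for r in resp)
        np.testing.assert_allclose(resp[1].values, [0.0, np.log(2.0), 1.0])

    def test_negative_values_skip_the_log_transform(self, caplog):
        resp = expand_phenotype(np.array([-1.0, 2.0]), "continuous", "x")
        assert [r.transform for r in resp] == ["raw"]

    def test_binary_passes_through_once_as_logistic(self):
        resp = expand_phenotype(np.array([0.0, 1.0, np.nan]), "binary", "x")
        assert len(resp) == 1
        assert resp[0].model == "logistic" and resp[0].transform == "raw"

    def test_three_label_categorical_becomes_three_binary_responses(self):
        values = pd.Series(["a", "b", "c", "a", None])
        resp = expand_phenotype(values, "categorical", "x")
        assert [r.transform for r in resp] == [
            "onevsrest:a",
            "onevsrest:b",
            "onevsrest:c",
        ]
        np.testing.assert_array_equal(resp[0].values[:4], [1, 0, 0, 1])
        assert np.isnan(resp[0].values[4])


# ---------------------------------------------------------------------------
# linear model


class TestLinearAssociation:
    # a fixed 8-row dataset: dosages, two covariates, a continuous response
    G8 = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
    C8 = np.array(
        [
            [0.1, -0.3], [0.5, 0.2], [-0.2, 0.4], [0.3, -0.1],
            [-0.5, 0.3], [0.2, -0.2], [0.4, 0.1], [-0.1, -0.4],
        ]
    )
    Y8 = np.array([1.2, 2.3, 3.1, 0.8, 2.9, 3.5, 1.7, 1.1])

    def test_fixed_dataset_matches_normal_equations_oracle(self):
        beta, se, p, n = linear_association(self.Y8, self.G8, self.C8, min_n=5)
        ob, ose, op = ols_oracle(self.Y8, self.G8, self.C8)
        assert n == 8
        assert beta == pytest.approx(ob, abs=1e-10)
        assert se == pytest.approx(ose, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_exact_fit_raises_degenerate(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        with pytest.raises(AssociationSkipped, match="degenerate"):
            linear_association(2 * g + 1, g, min_n=3)

    def test_monomorphic_genotype_is_skipped(self):
        with pytest.raises(AssociationSkipped, match="monomorphic"):
            linear_association(self.Y8, np.ones(8), min_n=3)

    def test_row_permutation_leaves_statistics_unchanged(self, rng):
        perm = rng.permutation(8)
        a = linear_association(self.Y8, self.G8, self.C8, min_n=5)
        b = linear_association(self.Y8[perm], self.G8[perm], self.C8[perm], min_n=5)
        np.testing.assert_allclose(a[:3], b[:3], atol=1e-12)

    def test_missing_values_are_dropped_pairwise(self):
        y = self.Y8.copy()
        y[2] = np.nan
        beta, se, p, n = linear_association(y, self.G8, self.C8, min_n=5)
        keep = np.arange(8) != 2
        ob, ose, op = ols_oracle(self.Y8[keep], self.G8[keep], self.C8[keep])
        assert n == 7 and beta == pytest.approx(ob, abs=1e-10)


class TestLogisticAssociation:
    def test_constant_outcome_is_skipped(self):
        with pytest.raises(AssociationSkipped, match="one_class"):
            logistic_association(np.ones(20), np.arange(20) % 3.0, min_n=5)

    def test_perfect_separation_is_flagged(self):
        g = np.array([0.0] * 10 + [2.0] * 10)
        y = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(AssociationSkipped, match="separation|nonconverged"):
            logistic_association(y, g, min_n=5, min_cases=2)

    def test_genotype_by_outcome_counts_match_mle_oracle(self):
        # 2x3 count table: outcome x genotype {0,1,2}
        counts = {(0, 0): 30, (0, 1): 20, (0, 2): 8, (1, 0): 12, (1, 1): 18, (1, 2): 14}
        y = np.concatenate([np.full(c, out, float) for (out, _), c in counts.items()])
        g = np.concatenate([np.full(c, dose, float) for (_, dose), c in counts.items()])
        beta, se, p, n = logistic_association(y, g, min_n=10, min_cases=5)
        ob, ose, op = logit_oracle(y, g)
        assert beta == pytest.approx(ob, abs=1e-6)
        assert se == pytest.approx(ose, abs=1e-6)
        assert p == pytest.approx(op, abs=1e-6)


class TestCodedAlleleFlip:
    def test_flip_negates_beta_and_preserves_se_and_p(self, rng):
        n = 60
        g = rng.integers(0, 3, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = 0.3 * g + rng.normal(size=n)
        b1, s1, p1, _ = linear_association(y, g, C, min_n=10)
        b2, s2, p2, _ = linear_association(y, 2.0 - g, C, min_n=10)
        assert b2 == pytest.approx(-b1, abs=1e-12)
        assert s2 == pytest.approx(s1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

        yb = (rng.random(n) < 1 / (1 + np.exp(-(g - 1)))).astype(float)
        b1, s1, p1, _ = logistic_association(yb, g, C, min_n=10, min_cases=5)
        b2, s2, p2, _ = logistic_association(yb, 2.0 - g, C, min_n=10, min_cases=5)
        assert b2 == pytest.approx(-b1, abs=1e-6)
        assert s2 == pytest.approx(s1, abs=1e-6)


# ---------------------------------------------------------------------------
# study-level scan


def _cohort(dosage, phen_values, kinds, female_only=False, rng=None):
    gm = make_matrix(dosage)
    n = len(gm.samples)
    rng = rng or np.random.default_rng(0)
    table = PhenotypeTable("S1", pd.DataFrame(phen_values, index=gm.samples), kinds)
    sex = np.array(["F"] * n, dtype=object) if female_only else np.where(
        rng.random(n) < 0.5, "F", "M"
    ).astype(object)
    cov = CovariateTable(
        samples=gm.samples,
        pc1=rng.normal(size=n),
        pc2=rng.normal(size=n),
        sex=sex,
        female_only_study=female_only,
    )
    return StudyCohort("S1", gm, table, cov)


class TestRunStudyPhewas:
    def test_enumerates_the_full_test_grid(self, rng):
        # 10 variants, 2 with minor frequency at/below 1%; 3 non-negative
        # continuous phenotypes -> 8 x (3 x 2 transforms) = 48 records
        n = 400
        dosage = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        dosage[:, 0] = 0.0
        dosage[0, 0] = 1.0  # caf 1/(2n) < 1%
        dosage[:, 1] = 0.0
        dosage[: int(0.01 * n * 2) // 1, 1] = 1.0  # caf exactly 1% -> excluded
        phen = {f"p{i}": rng.uniform(0, 5, n) for i in range(3)}
        cohort = _cohort(dosage, phen, {f"p{i}": "continuous" for i in range(3)}, rng=rng)
        records = run_study_phewas(cohort, maf_min=0.01, min_n=10)
        assert len(records) == 48
        assert records.attrs["manifest"]["maf_filtered"] == 2
        assert set(records["transform"]) == {"raw", "log1p"}

    def test_empty_phenotype_table_yields_no_records(self, rng):
        dosage = rng.integers(0, 3, size=(30, 4)).astype(float)
        cohort = _cohort(dosage, {}, {}, rng=rng)
        records = run_study_phewas(cohort)
        assert records.empty

    def test_female_only_study_omits_sex_from_the_model(self, rng):
        n = 200
        dosage = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        phen = {"p0": rng.uniform(0, 2, n)}
        cohort = _cohort(dosage, phen, {"p0": "continuous"}, female_only=True, rng=rng)
        records = run_study_phewas(cohort)
        # oracle fit without sex must match exactly
        row = records.iloc[0]
        C = np.column_stack([cohort.covariates.pc1, cohort.covariates.pc2])
        ob, ose, op = ols_oracle(
            np.asarray(phen["p0"], float), dosage[:, 0], C
        )
        assert row["beta"] == pytest.approx(ob, abs=1e-10)
        assert row["p"] == pytest.approx(op, abs=1e-10)
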