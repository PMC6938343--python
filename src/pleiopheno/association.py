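"""Per-study comprehensive single-SNP association tests.

Every (variant, phenotype response) pair is tested with an additive genetic
model — dosage 0/1/2 of the coded allele — adjusted for the first two
genotype-derived principal components and sex (omitted in a female-only
study).  Continuous responses are fit twice, raw and after a natural-log
``log(y+1)`` transform; binary responses use logistic regression; a
categorical phenotype is expanded into one "A versus not A" logistic
response per label.

Linear fits are exact OLS (the genotype coefficient is obtained by
residualizing genotype and response on the covariate block, which equals
the full normal-equations solution); p-values are two-sided t-tests.
Logistic fits are maximum likelihood via iteratively reweighted least
squares with Wald p-values.  Tests that cannot be fit (monomorphic SNP,
one-class outcome, too few observations, separation) are skipped and
counted in a per-study manifest rather than emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .model import RECORD_COLUMNS, GenotypeMatrix, StudyCohort, coded_allele_frequency

__all__ = [
    "ExpandedResponse",
    "AssociationSkipped",
    "compute_pcs",
    "expand_phenotype",
    "linear_association",
    "logistic_association",
    "run_study_phewas",
]

logger = logging.getLogger(__name__)

SEPARATION_BETA = 15.0
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50


class AssociationSkipped(Exception):
    """A single test that cannot be fit; ``reason`` is a short tag."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class ExpandedResponse:
    """One regression response derived from a phenotype column."""

    source_phenotype: str
    transform: str  # raw | log1p | onevsrest:<label>
    values: np.ndarray  # floats; NaN = missing
    model: str  # linear | logistic


# ---------------------------------------------------------------------------
# principal components


def compute_pcs(genotypes, k: int = 2) -> np.ndarray:
    """Scores of the k leading principal components of the dosage matrix.

    Columns are mean-imputed (for the PCA only), standardized to mean 0 and
    unit variance, and constant columns dropped.  Scores are projections
    onto the leading eigenvectors of the sample covariance; each
    component's sign is fixed so its largest-magnitude variant loading is
    positive.
    """
    X = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    X = X.astype(float).copy()
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} samples for {k} components, got {n}")
    mean = np.nanmean(X, axis=0)
    nanmask = np.isnan(X)
    if nanmask.any():
        X[nanmask] = np.take(mean, np.nonzero(nanmask)[1])
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * s[:k]
    for j in range(k):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


# ---------------------------------------------------------------------------
# phenotype expansion


_log1p_warned: set[str] = set()


def _as_float(values) -> np.ndarray:
    if isinstance(values, np.ndarray) and values.dtype == float:
        return values
    return np.asarray(pd.to_numeric(pd.Series(values)), dtype=float)


def expand_phenotype(values, kind: str, name: str = "") -> list[ExpandedResponse]:
    """Expand a phenotype column into regression responses.

    continuous -> raw linear plus natural-log ``log(y+1)`` linear (skipped
    with a warning when any value is negative); binary -> one logistic
    response; categorical -> one 0/1 "A versus not A" logistic response per
    label (a two-label categorical collapses to a single binary response).
    """
    if kind == "continuous":
        y = _as_float(values)
        out = [ExpandedResponse(name, "raw", y, "linear")]
        finite = y[np.isfinite(y)]
        if finite.size and finite.min() < 0:
            if name not in _log1p_warned:  # warn once per phenotype per process
                _log1p_warned.add(name)
                logger.warning(
                    "phenotype %s has negative values; log(y+1) response skipped", name
                )
        else:
            out.append(ExpandedResponse(name, "log1p", np.log1p(y), "linear"))
        return out
    if kind == "binary":
        return [ExpandedResponse(name, "raw", _as_float(values), "logistic")]
    if kind == "categorical":
        ser = pd.Series(values, dtype=object)
        labels = sorted({v for v in ser.dropna()})
        if len(labels) < 2:
            raise ValueError(f"categorical phenotype {name!r} has <2 labels")
        if len(labels) == 2:
            y = np.where(ser.isna(), np.nan, (ser == labels[1]).astype(float))
            logger.warning(
                "two-label categorical %s treated as binary (%s=1)", name, labels[1]
            )
            return [ExpandedResponse(name, "raw", y.astype(float), "logistic")]
        out = []
        for lab in labels:
            y = np.where(ser.isna(), np.nan, (ser == lab).astype(float))
            out.append(
                ExpandedResponse(name, f"onevsrest:{lab}", y.astype(float), "logistic")
            )
        return out
    raise ValueError(f"unknown phenotype kind {kind!r}")


# ---------------------------------------------------------------------------
# single-test fits


def _complete_rows(y, g, covariates):
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    mask = np.isfinite(y) & np.isfinite(g)
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        mask &= np.isfinite(C).all(axis=1)
        return y[mask], g[mask], C[mask], mask
    return y[mask], g[mask], None, mask


def linear_association(y, g, covariates=None, min_n: int = 10):
    """OLS of y on (1, g, covariates); returns (beta, se, p, n) for g.

    Complete-case rows only; two-sided t-test with n - k degrees of
    freedom.  Raises :class:`AssociationSkipped` for monomorphic g, n below
    ``min_n``, or a degenerate (zero residual variance) fit.
    """
    y, g, C, _ = _complete_rows(y, g, covariates)
    n = y.size
    if n < min_n:
        raise AssociationSkipped("low_n")
    if np.ptp(g) == 0:
        raise AssociationSkipped("monomorphic")
    X = np.column_stack([np.ones(n), g] + ([C] if C is not None else []))
    k = X.shape[1]
    if n <= k:
        raise AssociationSkipped("low_n")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise AssociationSkipped("collinear")
    resid = y - X @ coef
    rss = float(resid @ resid)
    df = n - k
    tss = float(((y - y.mean()) ** 2).sum())
    if rss <= max(tss, 1.0) * 1e-12:
        raise AssociationSkipped("degenerate")
    sigma2 = rss / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[1, 1])
    beta = float(coef[1])
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, float(p), n


def logistic_association(
    y,
    g,
    covariates=None,
    min_n: int = 10,
    min_cases: int = 5,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
):
    """Maximum-likelihood logit of y on (1, g, covariates) via IRLS.

    Returns (beta, se, p, n) for g: beta is the log odds per coded-allele
    copy, p the two-sided Wald test.  Raises :class:`AssociationSkipped`
    for a one-class outcome, outcome groups below ``min_cases``, apparent
    separation (|beta| > 15), or non-convergence.
    """
    y, g, C, _ = _complete_rows(y, g, covariates)
    n = y.size
    if n < min_n:
        raise AssociationSkipped("low_n")
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        raise AssociationSkipped("one_class")
    if min(n1, n - n1) < min_cases:
        raise AssociationSkipped("low_cases")
    if np.ptp(g) == 0:
        raise AssociationSkipped("monomorphic")
    X = np.column_stack([np.ones(n), g] + ([C] if C is not None else []))
    k = X.shape[1]
    beta = np.zeros(k)
    beta[0] = math.log(n1 / (n - n1))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            raise AssociationSkipped("singular")
        step = np.max(np.abs(new - beta))
        beta = new
        if abs(beta[1]) > SEPARATION_BETA:
            raise AssociationSkipped("separation")
        if step < tol:
            converged = True
            break
    if not converged:
        raise AssociationSkipped("nonconverged")
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = math.sqrt(cov[1, 1])
    b = float(beta[1])
    p = 2.0 * stats.norm.sf(abs(b / se))
    return b, se, float(p), n


# ---------------------------------------------------------------------------
# vectorized linear scan (one response, many SNPs)


def _linear_scan(G, y, C, min_n):
    """Per-SNP OLS of one response on (1, g, C) across a dosage block.

    Returns (beta, se, p, n, ok, reason) arrays.  SNP columns without
    missing genotypes on the response's complete rows are solved in one
    residualized pass; columns with genotype missingness fall back to the
    single-test path (identical math).
    """
    m = G.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    nn = np.zeros(m, dtype=int)
    reason = np.array([""] * m, dtype=object)

    y = np.asarray(y, float)
    base = np.isfinite(y)
    if C is not None:
        base &= np.isfinite(C).all(axis=1)
    Gb = G[base]
    yb = y[base]
    Cb = C[base] if C is not None else None
    nb = yb.size
    q = 1 + (0 if Cb is None else Cb.shape[1])  # intercept + covariates
    k = q + 1
    if nb <= k or nb < min_n:
        reason[:] = "low_n"
        return beta, se, p, nn, np.zeros(m, bool), reason

    nomiss = np.isfinite(Gb).all(axis=0)
    idx = np.nonzero(nomiss)[0]
    if idx.size:
        X = np.column_stack(
            [np.ones(nb)] + ([Cb] if Cb is not None else [])
        )
        Q, _ = np.linalg.qr(X)
        yt = yb - Q @ (Q.T @ yb)
        Gsub = Gb[:, idx]
        Gt = Gsub - Q @ (Q.T @ Gsub)
        sgg = np.einsum("ij,ij->j", Gt, Gt)
        sgy = Gt.T @ yt
        yy = float(yt @ yt)
        span = np.ptp(Gsub, axis=0)
        ok = (span > 0) & (sgg > 1e-10 * nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(ok, sgy / np.where(sgg > 0, sgg, 1.0), np.nan)
            rss = yy - b * sgy
        df = nb - k
        tss = float(((yb - yb.mean()) ** 2).sum())
        degen = ok & (rss <= max(tss, 1.0) * 1e-12)
        ok &= ~degen
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(np.clip(rss, 0, None) / df / np.where(sgg > 0, sgg, 1.0))
            tstat = b / s
            pv = 2.0 * stats.t.sf(np.abs(tstat), df)
        beta[idx] = b
        se[idx] = s
        p[idx] = pv
        nn[idx] = nb
        reason[idx[span == 0]] = "monomorphic"
        reason[idx[(span > 0) & (sgg <= 1e-10 * nb)]] = "collinear"
        reason[idx[degen]] = "degenerate"
        okmask = np.zeros(m, bool)
        okmask[idx] = ok
    else:
        okmask = np.zeros(m, bool)

    for j in np.nonzero(~nomiss)[0]:
        try:
            bj, sj, pj, nj = linear_association(y, G[:, j], C, min_n=min_n)
        except AssociationSkipped as exc:
            reason[j] = exc.reason
            continue
        beta[j], se[j], p[j], nn[j] = bj, sj, pj, nj
        okmask[j] = True
    return beta, se, p, nn, okmask, reason


# ---------------------------------------------------------------------------
# study-level scan


def run_study_phewas(
    cohort: StudyCohort,
    maf_min: float = 0.01,
    min_n: int = 10,
    min_cases: int = 5,
) -> pd.DataFrame:
    """All single-SNP tests for one study cohort.

    Variants must have minor coded-allele frequency strictly above
    ``maf_min`` (computed on this study's non-missing calls).  Covariates
    are PC1, PC2 and sex (sex omitted for a female-only study).  Returns an
    association-record DataFrame; a manifest of skip counts by reason is
    attached as ``frame.attrs["manifest"]``.
    """
    gm = cohort.genotypes
    C, _ = cohort.covariates.model_columns()
    manifest: dict[str, int] = {}

    caf = gm.caf()
    keep = np.minimum(caf, 1.0 - caf) > maf_min
    manifest["maf_filtered"] = int((~keep).sum())
    cols = np.nonzero(keep)[0]
    G = gm.dosage[:, cols]
    vid = np.array([gm.variants[j].id for j in cols], dtype=object)
    vchrom = np.array([gm.variants[j].chrom for j in cols], dtype=object)
    vpos = np.array([gm.variants[j].pos for j in cols], dtype=int)
    vallele = np.array([gm.variants[j].coded_allele for j in cols], dtype=object)
    vcaf = caf[cols]

    chunks: list[dict] = []
    for name in cohort.phenotypes.phenotypes:
        kind = cohort.phenotypes.kinds[name]
        values = cohort.phenotypes.values[name]
        if kind in ("continuous", "binary"):
            values = values.to_numpy(dtype=float)
        responses = expand_phenotype(values, kind, name)
        if kind == "continuous" and len(responses) == 1:
            manifest["log1p_skipped"] = manifest.get("log1p_skipped", 0) + 1
        for resp in responses:
            if resp.model == "linear":
                b, s, p, nn, ok, reason = _linear_scan(G, resp.values, C, min_n)
            else:
                m = G.shape[1]
                b = np.full(m, np.nan)
                s = np.full(m, np.nan)
                p = np.full(m, np.nan)
                nn = np.zeros(m, int)
                ok = np.zeros(m, bool)
                reason = np.array([""] * m, dtype=object)
                for j in range(m):
                    try:
                        b[j], s[j], p[j], nn[j] = logistic_association(
                            resp.values, G[:, j], C, min_n=min_n, min_cases=min_cases
                        )
                        ok[j] = True
                    except AssociationSkipped as exc:
                        reason[j] = exc.reason
            for r in reason[~ok]:
                if r:
                    manifest[r] = manifest.get(r, 0) + 1
            if not ok.any():
                continue
            sel = np.nonzero(ok)[0]
            chunks.append(
                {
                    "sel": sel,
                    "phenotype": resp.source_phenotype,
                    "transform": resp.transform,
                    "model": resp.model,
                    "beta": b[sel],
                    "se": s[sel],
                    "p": p[sel],
                    "n": nn[sel],
                }
            )

    if not chunks:
        out = pd.DataFrame(columns=RECORD_COLUMNS)
        manifest["tests_run"] = 0
        out.attrs["manifest"] = manifest
        return out

    sel_all = np.concatenate([c["sel"] for c in chunks])
    counts = [len(c["sel"]) for c in chunks]
    out = pd.DataFrame(
        {
            "study": np.repeat(cohort.study, len(sel_all)),
            "variant_id": vid[sel_all],
            "chrom": vchrom[sel_all],
            "pos": vpos[sel_all],
            "phenotype": np.repeat([c["phenotype"] for c in chunks], counts),
            "transform": np.repeat([c["transform"] for c in chunks], counts),
            "model": np.repeat([c["model"] for c in chunks], counts),
            "beta": np.concatenate([c["beta"] for c in chunks]),
            "se": np.concatenate([c["se"] for c in chunks]),
            "p": np.concatenate([c["p"] for c in chunks]),
            "n": np.concatenate([c["n"] for c in chunks]),
            "coded_allele": vallele[sel_all],
            "caf": vcaf[sel_all],
        },
        columns=RECORD_COLUMNS,
    )
    manifest["tests_run"] = int(len(out))
    out.attrs["manifest"] = manifest
    return out
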