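"""Per-SNP statistics: genotype summaries, HWE exact test, association tests.

These are the "type 1" computations — each SNP (or SNP/trait pair) is
processed independently of all others, so the work partitions trivially
over SNP ranges and every statistic here is a pure function of a single
genotype column plus, for association, the trait and covariates.

Statistical definitions fixed by this package:

* HWE exact test: conditional on the observed allele counts, sum the
  probabilities of all heterozygote counts whose conditional probability
  is less than or equal to that of the observed count (two-sided, no
  mid-p correction; ties included in the sum).
* score test: ``chi2 = n * r^2`` with ``r`` the Pearson correlation of
  genotype code and trait over the complete pairs — for a 0/1 trait this
  is exactly the Cochran-Armitage trend statistic.
* regression: per-SNP ``trait ~ genotype + covariates`` with a Wald
  ``chi2 = (beta/se)^2`` for the genotype term; linear models are solved
  in closed form, logistic by Newton iterations.

Missing data are handled per SNP by complete-case analysis, never by
imputation. P-values from the 1-df chi-square survival function are
floored at the smallest positive normal float so downstream log
transforms stay finite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist

from .errors import ParameterError
from .genotype_io import GenotypeMatrix, PhenotypeTable

_P_FLOOR = float(np.finfo(np.float64).tiny)

#: Diagnostic codes used in the ``status`` column of association tables.
STATUS_OK = "ok"
STATUS_TOO_FEW = "too_few_complete_pairs"
STATUS_DEGENERATE = "zero_variance"
STATUS_RANK_DEFICIENT = "rank_deficient"
STATUS_NOT_CONVERGED = "not_converged"
STATUS_SINGULAR = "singular_information"
STATUS_EXACT_FIT = "exact_fit"


def _chi2_sf(chi2: np.ndarray | float) -> np.ndarray | float:
    p = chi2_dist.sf(chi2, df=1)
    return np.maximum(p, _P_FLOOR)


def alt_allele_freqs(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP sample alt-allele frequency (NaN where no calls exist)."""
    called = G.codes >= 0
    n_called = called.sum(axis=0)
    alt = np.where(called, G.codes, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditional on the allele counts implied by the three genotype counts,
    the heterozygote count follows a known discrete distribution; the
    returned p-value sums the probabilities of all heterozygote counts at
    most as probable as the observed one. Always in (0, 1].
    """
    counts = (n_AA, n_AB, n_BB)
    if any(c < 0 for c in counts):
        raise ParameterError(f"genotype counts must be >= 0, got {counts}")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ParameterError("all genotype counts are zero")
    n_alt = n_AB + 2 * n_BB
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0  # allele counts admit a single genotype configuration

    # heterozygote counts share the parity of the rare-allele count
    het = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - het) // 2
    hom_common = n - het - hom_rare
    # conditional pmf: P(h) ∝ n! / (hom_r! h! hom_c!) * 2^h
    logw = (
        het * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(het + 1)
        - gammaln(hom_common + 1)
    )
    logp = logw - logsumexp(logw)
    obs_het = n_AB
    (obs_idx,) = np.nonzero(het == obs_het)
    if obs_idx.size != 1:  # pragma: no cover - parity guaranteed by construction
        raise ParameterError("observed heterozygote count inconsistent with allele counts")
    log_obs = logp[obs_idx[0]]
    # include ties (equality up to representation noise) in the tail sum
    p = float(np.exp(logp[logp <= log_obs + 1e-12]).sum())
    return min(max(p, _P_FLOOR), 1.0)


def snp_summary(G: GenotypeMatrix) -> pd.DataFrame:
    """One row per SNP: genotype counts, call rate, alt-allele frequency, HWE p.

    An all-missing SNP gets call_rate 0 with NaN frequency and HWE p.
    Monomorphic SNPs get hwe_p = 1 (no heterozygote deficit is possible).
    """
    codes = G.codes
    n = G.n_samples
    n_aa = (codes == 0).sum(axis=0)
    n_ab = (codes == 1).sum(axis=0)
    n_bb = (codes == 2).sum(axis=0)
    n_missing = (codes < 0).sum(axis=0)
    n_called = n - n_missing
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_called > 0, (n_ab + 2 * n_bb) / (2.0 * n_called), np.nan)
    hwe_p = np.array(
        [
            hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
            if n_called[j] > 0
            else np.nan
            for j in range(G.n_snps)
        ]
    )
    return pd.DataFrame(
        {
            "snp": G.snp_names,
            "chrom": [s.chrom for s in G.snps],
            "pos": [s.pos for s in G.snps],
            "n_AA": n_aa.astype(np.int64),
            "n_AB": n_ab.astype(np.int64),
            "n_BB": n_bb.astype(np.int64),
            "n_missing": n_missing.astype(np.int64),
            "call_rate": n_called / float(n),
            "q": q,
            "hwe_p": hwe_p,
        }
    )


def _assoc_frame(G: GenotypeMatrix, n, beta, se, chi2, p, status) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": G.snp_names,
            "chrom": [s.chrom for s in G.snps],
            "pos": [s.pos for s in G.snps],
            "n": np.asarray(n, dtype=np.int64),
            "beta": beta,
            "se": se,
            "chi2": chi2,
            "p": p,
            "status": status,
        }
    )


def score_test(G: GenotypeMatrix, y: Sequence[float]) -> pd.DataFrame:
    """Score test of trait-genotype association, one row per SNP.

    ``chi2 = n * r^2`` over the per-SNP complete pairs. SNPs with zero
    genotype or trait variance give chi2 = 0, p = 1; SNPs with fewer than
    two complete pairs are flagged. ``beta``/``se`` are NaN (score tests
    do not estimate an effect size).

    All reductions run column-by-column, so results are bit-identical
    whether computed on the full matrix or on any column partition of it.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (G.n_samples,):
        raise ParameterError(f"trait vector must have length {G.n_samples}")
    X = G.dosage()
    valid = ~np.isnan(X) & ~np.isnan(y)[:, None]
    n = valid.sum(axis=0)
    Xv = np.where(valid, X, 0.0)
    Yv = np.where(valid, y[:, None], 0.0)
    sx = Xv.sum(axis=0)
    sy = Yv.sum(axis=0)
    sxx = (Xv * Xv).sum(axis=0)
    syy = (Yv * Yv).sum(axis=0)
    sxy = (Xv * Yv).sum(axis=0)

    m = G.n_snps
    chi2 = np.zeros(m)
    p = np.ones(m)
    status = np.full(m, STATUS_OK, dtype=object)

    enough = n >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.where(enough, n, 1)
        varx = sxx - sx * sx / np.where(enough, n, 1)
        vary = syy - sy * sy / np.where(enough, n, 1)
    informative = enough & (varx > 0) & (vary > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(informative, cov**2 / np.where(informative, varx * vary, 1.0), 0.0)
    chi2[informative] = n[informative] * r2[informative]
    p[informative] = _chi2_sf(chi2[informative])
    # degenerate but computable: zero variance -> chi2 0, p 1 (already set)
    too_few = ~enough
    chi2[too_few] = np.nan
    p[too_few] = np.nan
    status[too_few] = STATUS_TOO_FEW

    nan = np.full(m, np.nan)
    return _assoc_frame(G, n, nan, nan, chi2, p, status)


def _fit_linear(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS; returns (beta_g, se_g, status)."""
    n, k = X.shape
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < k:
        return np.nan, np.nan, STATUS_RANK_DEFICIENT
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        return np.nan, np.nan, STATUS_TOO_FEW
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se == 0.0:
        return float(beta[1]), 0.0, STATUS_EXACT_FIT
    return float(beta[1]), se, STATUS_OK


def _fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8):
    """Newton-Raphson logistic fit; returns (beta_g, se_g, status)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X.T @ X) < k:
        return np.nan, np.nan, STATUS_RANK_DEFICIENT
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, STATUS_SINGULAR
        beta = beta + step
    if not converged:
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) > tol:
            return np.nan, np.nan, STATUS_NOT_CONVERGED
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, STATUS_SINGULAR
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se == 0.0:
        return float(beta[1]), 0.0, STATUS_EXACT_FIT
    return float(beta[1]), se, STATUS_OK


def ml_regression(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    covariates: Sequence[str] = (),
    model: str = "linear",
) -> pd.DataFrame:
    """Per-SNP regression ``trait ~ genotype + covariates`` (linear or logistic).

    Complete-case per SNP. Rows that cannot be estimated (zero genotype
    variance, rank deficiency, separation/non-convergence) are flagged via
    the ``status`` column rather than raising.
    """
    if model not in ("linear", "logistic"):
        raise ParameterError(f"model must be 'linear' or 'logistic', got {model!r}")
    cols = [trait, *covariates]
    ph = pheno.aligned(G.sample_ids, cols)
    y_all = ph[:, 0]
    C_all = ph[:, 1:]
    if model == "logistic":
        seen = set(np.unique(y_all[~np.isnan(y_all)]))
        if not seen.issubset({0.0, 1.0}):
            raise ParameterError(
                f"logistic model requires a 0/1 trait, found values {sorted(seen)[:5]}"
            )
    X_all = G.dosage()

    m = G.n_snps
    n_used = np.zeros(m, dtype=np.int64)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    status = np.full(m, STATUS_OK, dtype=object)

    base_ok = ~np.isnan(y_all) & ~np.isnan(C_all).any(axis=1)
    fit = _fit_linear if model == "linear" else _fit_logistic
    for j in range(m):
        g = X_all[:, j]
        rows = base_ok & ~np.isnan(g)
        n = int(rows.sum())
        n_used[j] = n
        k = 2 + C_all.shape[1]
        if n < k + 1:
            status[j] = STATUS_TOO_FEW
            continue
        gj = g[rows]
        if np.all(gj == gj[0]):
            status[j] = STATUS_DEGENERATE
            continue
        X = np.column_stack([np.ones(n), gj, C_all[rows]])
        beta[j], se[j], status[j] = fit(X, y_all[rows])

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(se > 0, (beta / se) ** 2, np.where(se == 0, np.inf, np.nan))
    p = np.where(np.isnan(chi2), np.nan, _chi2_sf(np.where(np.isnan(chi2), 0.0, chi2)))
    return _assoc_frame(G, n_used, beta, se, chi2, p, status)
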