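"""PRS-disease association: ancestry covariates, logistic fits, Nagelkerke R2.

The headline statistic is the increment in Nagelkerke's pseudo-R2 when a
standardized polygenic score is added to a logistic model of disease
status that already contains k ancestry-informative principal
components: dNR2 = NR2(covariates + PRS) - NR2(covariates).

The logistic fit is a plain Newton-Raphson maximum-likelihood routine
written out here (rather than delegated) because the Wald test and the
likelihoods entering NR2 are the package's core statistic; it is
cross-checked against independent optimizers in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import ld
from .gwas_io import GenotypePanel, PHENO_UNKNOWN
from .scoring import ScoreSet

logger = logging.getLogger("crosstrait.association")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges."""


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    cov: np.ndarray
    n_iter: int


@dataclass
class AssociationResult:
    """One threshold's PRS-disease association summary."""

    threshold: float
    n_snps: int
    beta_prs: float
    wald_p: float
    delta_nr2: float
    case_mean: float
    control_mean: float
    #: (cases above controls' 95% quantile, controls above it,
    #:  cases below controls' 5% quantile, controls below it)
    tail_report: dict[str, float]


# ---------------------------------------------------------------------------
# ancestry dimensions
# ---------------------------------------------------------------------------

def ancestry_dims(
    panel: GenotypePanel,
    k: int = 5,
    prune_spec: ld.ClumpSpec | None = ld.ClumpSpec(tag="ancestry-prune"),
) -> np.ndarray:
    """Top-k principal axes of the pruned, standardized genotype matrix.

    Columns are centered and scaled by sqrt(2 f (1-f)) with empirical f;
    missing entries become 0 after centering.  Coordinates are the
    sample projections (U S of the thin SVD), with each dimension's sign
    fixed so its largest-magnitude SNP loading is positive.
    """
    if k >= panel.n_samples:
        raise ValueError("k must be below the sample count")
    work = panel
    if prune_spec is not None:
        kept = ld.prune(panel, prune_spec.window_kb, prune_spec.r2_threshold)
        keep_idx = np.flatnonzero(panel.variants["snp_id"].isin(kept))
        work = panel.subset_variants(keep_idx)
        logger.info("ancestry_dims: pruned %d -> %d SNPs", panel.n_variants, len(keep_idx))
    d = work.dosages
    f = np.nanmean(d, axis=0) / 2.0
    scale = np.sqrt(2 * f * (1 - f))
    ok = scale > 0
    z = (d[:, ok] - 2 * f[ok]) / scale[ok]
    z = np.where(np.isnan(z), 0.0, z)
    if k < min(z.shape) // 4:
        # truncated SVD with a fixed start vector keeps this deterministic
        from scipy.sparse.linalg import svds

        u, s, vt = svds(z, k=k, v0=np.ones(min(z.shape)), maxiter=5000)
        desc = np.argsort(s)[::-1]
        u, s, vt = u[:, desc], s[desc], vt[desc]
    else:
        u, s, vt = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :k] * s[:k]
    # deterministic sign: largest-|loading| SNP positive per dimension
    for j in range(min(k, vt.shape[0])):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] *= -1
    return coords


# ---------------------------------------------------------------------------
# logistic regression from first principles
# ---------------------------------------------------------------------------

def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    *,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-12,
    coef_bound: float = 30.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    ``X`` must include its intercept column and be full rank; ``y`` must
    contain both classes.  Convergence: max |score| < ``grad_tol`` or
    relative log-likelihood change < ``ll_tol``, with step-halving when
    a Newton step would decrease the likelihood.  Wald standard errors
    come from the observed information at the optimum.  Divergent
    coefficients raise :class:`SeparationError`.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X row counts differ")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("y must contain both classes")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll = _loglik(y, X, beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < grad_tol:
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("information matrix singular (separation?)") from exc
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(y, X, cand)
            if ll_new >= ll - 1e-14:
                break
            scale /= 2
        beta = beta + scale * step
        if np.max(np.abs(beta)) > coef_bound:
            raise SeparationError(
                f"coefficients diverged (|beta| > {coef_bound}); perfect separation"
            )
        if abs(ll_new - ll) <= ll_tol * (abs(ll) + 1e-300):
            ll = ll_new
            break
        ll = ll_new
    # one polishing Newton step: quadratic convergence squares the
    # remaining error, so closed-form cases come out exact to float precision
    mu = _sigmoid(X @ beta)
    w = mu * (1 - mu)
    score = X.T @ (y - mu)
    info = (X * w[:, None]).T @ X
    try:
        beta = beta + np.linalg.solve(info, score)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("information matrix singular (separation?)") from exc
    mu = _sigmoid(X @ beta)
    w = mu * (1 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("observed information singular at optimum") from exc
    return LogisticFit(
        coef=beta, se=np.sqrt(np.diag(cov)), loglik=_loglik(y, X, beta),
        cov=cov, n_iter=n_iter,
    )


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def nagelkerke(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke's pseudo-R2 from nested-model log-likelihoods.

    Cox-Snell R2 = 1 - exp(2 (ll_null - ll_full) / n), rescaled by its
    attainable maximum 1 - exp(2 ll_null / n) so a saturated fit scores 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ll_full < ll_null - 1e-8:
        raise ValueError("ll_full < ll_null: models are not nested")
    ll_full = max(ll_full, ll_null)
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(min(cox_snell / max_cs, 1.0))


# ---------------------------------------------------------------------------
# PRS association sweep
# ---------------------------------------------------------------------------

def prs_association(
    scores: ScoreSet,
    phenotypes: np.ndarray,
    covariates: np.ndarray | None = None,
) -> list[AssociationResult]:
    """Per-threshold logistic association of disease status on the PRS.

    For each p_T: fit status ~ intercept + covariates + PRS and the
    covariate-only reduced model; report the PRS Wald p, the Nagelkerke
    R2 increment, case/control score means, and the share of each group
    in the controls' 5% score tails.  ``scores`` must be standardized.
    A threshold whose score column is constant yields dNR2 = 0 with a
    logged warning (the PRS term is dropped).
    """
    if not scores.standardized:
        raise ValueError("prs_association expects standardized scores")
    y = np.asarray(phenotypes)
    mask = y != PHENO_UNKNOWN
    y = y[mask].astype(float)
    n = y.size
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C[mask]
    X_reduced = np.column_stack([np.ones(n), C])
    fit_red = fit_logistic(y, X_reduced)
    nr2_red = nagelkerke(_null_ll(y), fit_red.loglik, n)

    results = []
    for k, p_t in enumerate(scores.thresholds):
        s = scores.scores[mask, k]
        case_mean = float(s[y == 1].mean())
        control_mean = float(s[y == 0].mean())
        controls = s[y == 0]
        hi = float(np.quantile(controls, 0.95))
        lo = float(np.quantile(controls, 0.05))
        tail = {
            "cases_above_hi": float(np.mean(s[y == 1] > hi)),
            "controls_above_hi": float(np.mean(controls > hi)),
            "cases_below_lo": float(np.mean(s[y == 1] < lo)),
            "controls_below_lo": float(np.mean(controls < lo)),
        }
        if s.std() == 0:
            logger.warning("threshold %g: constant PRS, term dropped", p_t)
            results.append(
                AssociationResult(
                    threshold=p_t, n_snps=int(scores.snp_counts[k]),
                    beta_prs=0.0, wald_p=1.0, delta_nr2=0.0,
                    case_mean=case_mean, control_mean=control_mean, tail_report=tail,
                )
            )
            continue
        X_full = np.column_stack([X_reduced, s])
        fit_full = fit_logistic(y, X_full)
        beta = float(fit_full.coef[-1])
        z = beta / float(fit_full.se[-1])
        wald_p = float(np.clip(2 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
        nr2_full = nagelkerke(_null_ll(y), fit_full.loglik, n)
        results.append(
            AssociationResult(
                threshold=p_t,
                n_snps=int(scores.snp_counts[k]),
                beta_prs=beta,
                wald_p=wald_p,
                delta_nr2=max(0.0, nr2_full - nr2_red),
                case_mean=case_mean,
                control_mean=control_mean,
                tail_report=tail,
            )
        )
    return results


def _null_ll(y: np.ndarray) -> float:
    """Intercept-only log-likelihood in closed form."""
    n1 = float(y.sum())
    n0 = float(y.size - n1)
    p = n1 / (n1 + n0)
    return n1 * np.log(p) + n0 * np.log(1 - p)
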