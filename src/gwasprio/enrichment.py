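"""Enrichment estimation: local FDR posteriors and penalized logistic priors.

The two-step procedure (posterior-marginal logistic regression):

1. Ignore annotations and estimate each SNP's marginal posterior probability
   of association (mPPA), ``psi_j = 1 - lfdr(z_j)``, from the two-group
   mixture ``z ~ pi0 N(0,1) + (1-pi0) f1`` via Efron's local false discovery
   rate with a theoretical N(0,1) null.
2. Regress class-mean mPPA values on the annotation rows with an
   elastic-net-penalized logistic regression (classes weighted by size).
   The fitted values ``pi_i = logistic(kappa + beta' V_i)`` are the shrunken
   per-class prior probabilities of association.

This replaces a full mixture-likelihood maximization with two standard,
numerically stable fits and is equivalent to a single EM step from a valid
initial estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .mapping import EquivalenceClasses

logger = logging.getLogger(__name__)

Z_CLAMP = 38.0
PSI_CLIP = 1e-6


class EstimationError(RuntimeError):
    """Raised when a density or model fit cannot be carried out."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg, lam=None):
        super().__init__(msg)
        self.lam = lam


def pvalues_to_zscores(stats):
    """Fill one-sided Z-scores ``z = Phi^{-1}(1 - p)``, clamped to |z| <= 38."""
    p = stats.p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = np.clip(norm.isf(p), -Z_CLAMP, Z_CLAMP)
    return stats.with_z(z)


# --------------------------------------------------------------------------
# local FDR


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    ``knots`` includes the two boundary knots; with ``K`` knots the basis has
    ``K - 1`` columns (linear term plus K-2 curvature terms) and is linear
    beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)
    xiK, xiK1 = knots[-1], knots[-2]

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - xiK, 0.0) ** 3
        return num / (xiK - knots[k])

    cols = [x]
    dK1 = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


@dataclass
class LocalFdrFit:
    """Local-FDR decomposition of a vector of Z-scores.

    ``lfdr[j] = min(1, pi0 * phi(z_j) / fhat(z_j))`` with a theoretical
    N(0,1) null, and ``mppa = 1 - lfdr``.
    """

    pi0: float
    z_grid: np.ndarray       # histogram bin midpoints
    fhat: np.ndarray         # marginal density estimate on the grid
    lfdr: np.ndarray         # per SNP, in [0, 1]
    mppa: np.ndarray         # per SNP, 1 - lfdr

    def to_json_dict(self) -> dict:
        return {"pi0": float(self.pi0),
                "mean_mppa": float(np.mean(self.mppa)),
                "n_snps": int(len(self.lfdr))}


def estimate_mppa(z: np.ndarray, bins: int = 120, spline_df: int = 7) -> LocalFdrFit:
    """Estimate per-SNP mPPA by local FDR with a theoretical N(0,1) null.

    The marginal density is a Lindsey-type estimate: histogram the Z-scores
    into ``bins`` equal-width bins and fit a Poisson regression of the counts
    on a natural cubic spline (``spline_df`` degrees of freedom) of the bin
    midpoints.  ``pi0`` is estimated by central matching,
    ``min(1, fhat(0) / phi(0))``.  The estimated lfdr is made monotone
    non-increasing in z over the upper tail (isotonic clean-up).
    """
    z = np.asarray(z, dtype=float)
    M = len(z)
    if M == 0:
        raise EstimationError("no Z-scores")
    if np.ptp(z) == 0:
        raise EstimationError("degenerate Z-scores: all values identical")
    if M < 1000:
        logger.warning("only %d SNPs: local-FDR density estimate may be unstable", M)

    lo, hi = z.min(), z.max()
    counts, edges = np.histogram(z, bins=bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    # knots: boundary at the extreme midpoints, interior at equal quantiles
    qs = np.linspace(0, 1, spline_df + 1)
    knots = np.unique(np.quantile(mids, qs))
    if len(knots) < 4:
        raise EstimationError("too few distinct Z-scores for a spline fit")

    def design(x):
        return sm.add_constant(_natural_spline_basis(x, knots), has_constant="add")

    try:
        fit = sm.GLM(counts, design(mids), family=sm.families.Poisson()).fit()
    except Exception as exc:
        raise EstimationError(f"Poisson density fit failed: {exc}") from exc

    def density(x):
        mu = np.exp(np.clip(design(np.atleast_1d(x)) @ fit.params, -700, 700))
        return np.maximum(mu / (M * width), 1e-300)

    pi0 = float(min(1.0, density(0.0)[0] / norm.pdf(0.0)))
    fhat_grid = density(mids)
    lfdr = np.clip(pi0 * norm.pdf(z) / density(z), 0.0, 1.0)

    # isotonic clean-up: lfdr non-increasing in z over the upper tail
    upper = z > 0
    if upper.sum() >= 2:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        lfdr[upper] = iso.fit_transform(z[upper], lfdr[upper])
    lfdr = np.clip(lfdr, 0.0, 1.0)
    return LocalFdrFit(pi0, mids, fhat_grid, lfdr, 1.0 - lfdr)


def class_mean_mppa(eqclasses: EquivalenceClasses, lfdrfit: LocalFdrFit) -> EquivalenceClasses:
    """Average mPPA within each equivalence class, clipped into (0, 1)."""
    if len(lfdrfit.mppa) != eqclasses.n_snps:
        raise ValueError("mPPA vector length does not match SNP count")
    tot = np.bincount(eqclasses.class_of_snp, weights=lfdrfit.mppa,
                      minlength=eqclasses.n_classes)
    psibar = np.clip(tot / eqclasses.sizes, PSI_CLIP, 1.0 - PSI_CLIP)
    return eqclasses.with_psibar(psibar)


# --------------------------------------------------------------------------
# penalized logistic prior model


@dataclass
class PriorModel:
    """Fitted penalized logistic prior model (one model per penalty value).

    ``class_priors[i] = logistic(kappa + beta' V_i)`` for the equivalence
    classes the model was fitted on; ``class_logodds`` are their log-odds.
    """

    kappa: float
    beta: np.ndarray
    lam: float
    alpha_mix: float
    annotation_names: list
    class_priors: np.ndarray
    class_logodds: np.ndarray

    def predict_prior(self, V) -> np.ndarray:
        """Prior probability of association for arbitrary annotation rows."""
        return expit(self.predict_logodds(V))

    def predict_logodds(self, V) -> np.ndarray:
        eta = np.asarray(V @ self.beta).ravel() + self.kappa
        return eta

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.beta != 0))

    def to_json_dict(self) -> dict:
        nz = np.flatnonzero(self.beta)
        return {"kappa": float(self.kappa),
                "lambda": float(self.lam),
                "alpha_mix": float(self.alpha_mix),
                "nonzero_coefficients": {self.annotation_names[k]: float(self.beta[k])
                                         for k in nz}}


def lambda_max(eqclasses: EquivalenceClasses, alpha_mix: float = 1.0) -> float:
    """Smallest penalty at which every annotation coefficient is zero.

    From the stationarity condition of the objective
    ``-2 loglik + lam * (alpha * L1 + (1 - alpha) * L2)`` at ``beta = 0``
    with the intercept at its weighted mean:
    ``lambda_max = max_k 2 |sum_i n_i V_ik (psibar_i - pbar)| / alpha``.
    """
    if eqclasses.psibar is None:
        raise ValueError("class-mean mPPA not computed")
    if not 0 < alpha_mix <= 1:
        raise ValueError("alpha_mix must lie in (0, 1] for a finite lambda_max")
    n, psi = eqclasses.sizes.astype(float), eqclasses.psibar
    pbar = float(np.sum(n * psi) / n.sum())
    g = np.asarray(eqclasses.V_classes.T @ (n * (psi - pbar))).ravel()
    return float(2.0 * np.max(np.abs(g), initial=0.0) / alpha_mix)


def _dense_V(V) -> np.ndarray:
    return V.toarray().astype(float) if sp.issparse(V) else np.asarray(V, dtype=float)


def _deviance(n, psi, eta):
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return -2.0 * np.sum(n * (psi * np.log(mu) + (1 - psi) * np.log(1 - mu)))


def _kkt_violation(X, n, psi, theta, l1, l2):
    """Largest violation of the stationarity conditions of the penalized
    objective (intercept unpenalized, soft-threshold conditions for beta)."""
    mu = expit(X @ theta)
    g = -2.0 * (X.T @ (n * (psi - mu)))        # gradient of -2*loglik
    beta = theta[1:]
    gb = g[1:] + 2.0 * l2 * beta
    active = beta != 0
    viol = abs(g[0])
    if active.any():
        viol = max(viol, np.max(np.abs(gb[active] + l1 * np.sign(beta[active]))))
    if (~active).any():
        viol = max(viol, np.max(np.maximum(np.abs(gb[~active]) - l1, 0.0)))
    return viol


def _penalized_logistic(V, psi, n, lam, alpha_mix, kappa0=None, beta0=None,
                        kkt_tol=1e-9, max_outer=200, max_sweeps=5000):
    """Damped IRLS + cyclic coordinate descent for the weighted
    fractional-response elastic-net logistic objective

        -2 * sum_i n_i [psi_i log mu_i + (1-psi_i) log(1-mu_i)]
        + lam * (alpha * ||beta||_1 + (1-alpha) * ||beta||_2^2),

    mu_i = logistic(kappa + V_i beta).  The intercept is unpenalized.

    Each IRLS step solves the penalized weighted-least-squares subproblem by
    coordinate descent in covariance form (the Gram matrix X'WX, X = [1, V],
    is formed once per step so a CD sweep costs O(K^2) scalar work), and the
    resulting step is accepted with backtracking halving so the penalized
    objective decreases monotonically.
    """
    Vd = _dense_V(V)
    C, K = Vd.shape
    n = np.asarray(n, dtype=float)
    X = np.column_stack([np.ones(C), Vd])
    theta = np.zeros(K + 1)
    theta[0] = float(logit(np.sum(n * psi) / n.sum())) if kappa0 is None else float(kappa0)
    if beta0 is not None:
        theta[1:] = np.asarray(beta0, dtype=float)
    l1, l2 = lam * alpha_mix, lam * (1.0 - alpha_mix)

    def pen_obj(th):
        return (_deviance(n, psi, X @ th)
                + l1 * np.abs(th[1:]).sum() + l2 * (th[1:] ** 2).sum())

    gtol = kkt_tol * max(1.0, n.sum())
    obj = pen_obj(theta)
    for _ in range(max_outer):
        if _kkt_violation(X, n, psi, theta, l1, l2) < gtol:
            return float(theta[0]), theta[1:].copy()
        eta = X @ theta
        mu = np.clip(expit(eta), 1e-6, 1 - 1e-6)
        w = 2.0 * n * mu * (1 - mu)                 # curvature of -2*loglik
        zw = eta + (psi - mu) / (mu * (1 - mu))     # working response
        A = X.T @ (w[:, None] * X)
        b = X.T @ (w * zw)
        diag = np.diag(A).copy()
        cd_tol = 1e-11 * diag[0]                    # scaled by total weight
        th = theta.copy()
        for _ in range(max_sweeps):
            d2 = 0.0
            for k in range(K + 1):
                u = b[k] - A[k] @ th + diag[k] * th[k]
                if k == 0:
                    new = u / diag[0]
                else:
                    den = diag[k] + 2.0 * l2
                    new = (np.sign(u) * max(abs(u) - l1, 0.0) / den
                           if den > 0 else 0.0)
                dd = new - th[k]
                if dd != 0.0:
                    d2 = max(d2, diag[k] * dd * dd)
                    th[k] = new
            if d2 < cd_tol:
                break
        step = th - theta
        t_step, new_obj = 1.0, np.inf
        for _ in range(60):
            cand = theta + t_step * step
            new_obj = pen_obj(cand)
            if np.isfinite(new_obj) and new_obj <= obj + 1e-14 * (abs(obj) + 1.0):
                break
            t_step *= 0.5
        else:
            # no improving direction at floating-point resolution
            return float(theta[0]), theta[1:].copy()
        theta = cand
        obj = new_obj
    if _kkt_violation(X, n, psi, theta, l1, l2) < 100 * gtol:
        return float(theta[0]), theta[1:].copy()
    raise ConvergenceError(f"penalized logistic fit did not converge at lambda={lam}",
                           lam=lam)


def fit_prior_model(eqclasses: EquivalenceClasses, lam: float,
                    alpha_mix: float = 1.0, kappa0=None, beta0=None) -> PriorModel:
    """Fit the penalized logistic regression of class-mean mPPA on annotations.

    Each class contributes a fractional binomial response ``psibar_i`` with
    prior weight ``n_i`` (class size), so the collapse to equivalence classes
    is information-preserving.  ``alpha_mix = 1`` is the LASSO.
    """
    if eqclasses.psibar is None:
        raise ValueError("class-mean mPPA not computed; run class_mean_mppa first")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 <= alpha_mix <= 1:
        raise ValueError("alpha_mix must lie in [0, 1]")
    kappa, beta = _penalized_logistic(
        eqclasses.V_classes, eqclasses.psibar, eqclasses.sizes,
        lam, alpha_mix, kappa0=kappa0, beta0=beta0)
    logodds = np.asarray(eqclasses.V_classes @ beta).ravel() + kappa
    return PriorModel(kappa, beta, float(lam), float(alpha_mix),
                      list(eqclasses.annotation_names), expit(logodds), logodds)


def default_lambda_path(eqclasses: EquivalenceClasses, alpha_mix: float = 1.0,
                        n_lambda: int = 100, lambda_min_ratio: float = 1e-3) -> np.ndarray:
    """Geometric penalty sequence from ``lambda_max`` down to
    ``lambda_min_ratio * lambda_max``."""
    lmax = max(lambda_max(eqclasses, alpha_mix), 1e-8)
    return np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)


def fit_prior_path(eqclasses: EquivalenceClasses, lambdas=None,
                   alpha_mix: float = 1.0) -> list:
    """Fit one :class:`PriorModel` per penalty, warm-started along the path."""
    if lambdas is None:
        lambdas = default_lambda_path(eqclasses, alpha_mix)
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda sequence must be strictly decreasing")
    models, kappa0, beta0 = [], None, None
    for lam in lambdas:
        m = fit_prior_model(eqclasses, lam, alpha_mix, kappa0=kappa0, beta0=beta0)
        models.append(m)
        kappa0, beta0 = m.kappa, m.beta
    return models


# --------------------------------------------------------------------------
# alternative distribution


@dataclass
class AlternativeModel:
    """Alternative Z-score distribution N(mu, 1 + tau2)."""

    mu: float
    tau2: float

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")

    @property
    def sd(self) -> float:
        return float(np.sqrt(1.0 + self.tau2))

    def upper_tail(self, x) -> np.ndarray:
        """P(Z > x) under the alternative."""
        return norm.sf((np.asarray(x, dtype=float) - self.mu) / self.sd)


def estimate_alternative(z: np.ndarray, mppa: np.ndarray) -> AlternativeModel:
    """mPPA-weighted moment estimate of the alternative N(mu, 1 + tau2).

    ``mu = sum(psi z)/sum(psi)``;
    ``tau2 = max(0, weighted variance - 1)``.  Falls back to (mu=2, tau2=0)
    when all posterior weights vanish.
    """
    z = np.asarray(z, dtype=float)
    psi = np.asarray(mppa, dtype=float)
    s = psi.sum()
    if s <= 0:
        logger.warning("all mPPA are zero; falling back to alternative N(2, 1)")
        return AlternativeModel(2.0, 0.0)
    mu = float(np.sum(psi * z) / s)
    var = float(np.sum(psi * (z - mu) ** 2) / s)
    return AlternativeModel(mu, max(0.0, var - 1.0))
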