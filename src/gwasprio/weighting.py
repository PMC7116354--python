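"""FWER-preserving p-value weights from class prior probabilities.

Given per-class priors ``pi_i`` (and their log-odds ``beta_i``), a weight
``w_i > 0`` is assigned to every SNP of class ``i`` subject to the global
constraint that the class-size-weighted mean weight is one,
``sum_i n_i w_i / M = 1``.  Rejecting SNP j when ``p_j / w_j <= alpha / M``
then keeps the expected number of false positives under the global null at
``alpha``, exactly as in unweighted Bonferroni testing.

Two weight families are provided:

* Simple weighting (SPW): ``w_i proportional to exp(beta_i)`` — weights
  proportional to the prior odds of association.
* Cubic weighting (CPW):  ``w_i proportional to
  exp(g1 beta_i + g2 beta_i^2 + g3 beta_i^3)`` with ``(g1, g2, g3)`` chosen
  by Nelder-Mead to maximize the expected number of true positives.  SPW is
  the special case ``(1, 0, 0)`` and is used as the starting point, so CPW
  never scores below SPW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .enrichment import AlternativeModel, PriorModel
from .mapping import EquivalenceClasses

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-6


@dataclass
class WeightAssignment:
    """Per-class p-value weights satisfying ``sum n_i w_i / M = 1``."""

    scheme: str                      # "spw" or "cpw"
    gammas: tuple                    # (g1, g2, g3); g0 absorbed by normalization
    class_weights: np.ndarray        # w_i > 0, one per class
    alpha_fwer: float
    objective: float                 # attained expected true positives

    def __post_init__(self):
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if np.any(self.class_weights <= 0):
            raise ValueError("weights must be positive")


@dataclass
class WeightedResults:
    """Per-SNP weighted p-values, ``p_weighted = min(1, p / w)``."""

    p: np.ndarray
    weight: np.ndarray
    p_weighted: np.ndarray
    class_id: np.ndarray


def _normalize_log_weights(log_raw: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Rescale log-weights so the class-size-weighted mean weight is 1.

    Equal log-weights short-circuit to exact ones, so a fully shrunk prior
    model reduces the pipeline to unweighted analysis bit for bit.
    """
    log_raw = np.asarray(log_raw, dtype=float)
    if log_raw.size and np.ptp(log_raw) == 0:
        return np.ones_like(log_raw)
    n = np.asarray(sizes, dtype=float)
    M = n.sum()
    log_norm = logsumexp(np.log(n) + log_raw) - np.log(M)
    # keep astronomically down-weighted classes strictly positive
    return np.maximum(np.exp(log_raw - log_norm), np.finfo(float).tiny)


def expected_true_positives(class_weights, priors, sizes,
                            altmodel: AlternativeModel,
                            alpha_fwer: float, M: int | float) -> float:
    """Expected number of true positives at per-class thresholds
    ``alpha * w_i / M``:

        E[TP] = sum_i n_i pi_i Fbar1( Phibar^{-1}( alpha w_i / M ) )

    with ``Fbar1`` the upper tail of the alternative N(mu, 1+tau2) and
    ``Phibar`` the N(0,1) upper tail.
    """
    w = np.asarray(class_weights, dtype=float)
    t = alpha_fwer * w / M
    if np.any(t >= 1):
        logger.warning("per-class threshold >= 1 for %d class(es); clipping",
                       int(np.sum(t >= 1)))
        t = np.minimum(t, 1 - 1e-12)
    zcut = norm.isf(t)
    return float(np.sum(np.asarray(sizes, float) * np.asarray(priors, float)
                        * altmodel.upper_tail(zcut)))


def simple_weights(priormodel: PriorModel,
                   eqclasses: EquivalenceClasses,
                   alpha_fwer: float = 0.05,
                   altmodel: AlternativeModel | None = None) -> WeightAssignment:
    """Simple weighting: ``w_i = exp(beta_i) / (sum_k n_k exp(beta_k) / M)``.

    Computed in log space; the attained E[TP] is recorded when an alternative
    model is supplied (otherwise NaN).
    """
    beta = np.asarray(priormodel.class_logodds, dtype=float)
    w = _normalize_log_weights(beta, eqclasses.sizes)
    obj = np.nan
    if altmodel is not None:
        obj = expected_true_positives(w, priormodel.class_priors, eqclasses.sizes,
                                      altmodel, alpha_fwer, eqclasses.sizes.sum())
    return WeightAssignment("spw", (1.0, 0.0, 0.0), w, alpha_fwer, obj)


def cubic_weights(priormodel: PriorModel,
                  eqclasses: EquivalenceClasses,
                  altmodel: AlternativeModel,
                  alpha_fwer: float = 0.05,
                  gammas: tuple | None = None,
                  max_iter: int = 500) -> WeightAssignment:
    """Cubic weighting: maximize E[TP] over ``(g1, g2, g3)``.

    ``w_i(g) = exp(g1 b + g2 b^2 + g3 b^3)`` renormalized to mean 1 inside
    the objective (``g0`` is thereby absorbed).  Optimization is Nelder-Mead
    started at the SPW point (1, 0, 0); if the optimizer ends below the start
    or fails, the SPW weights are returned.  When ``gammas`` is given, the
    weights are evaluated at that point without optimization.
    """
    beta = np.asarray(priormodel.class_logodds, dtype=float)
    n = eqclasses.sizes
    M = n.sum()
    if np.ptp(beta) == 0:
        w = np.ones_like(beta)
        obj = expected_true_positives(w, priormodel.class_priors, n,
                                      altmodel, alpha_fwer, M)
        g = gammas if gammas is not None else (1.0, 0.0, 0.0)
        return WeightAssignment("cpw", tuple(g), w, alpha_fwer, obj)

    B = np.column_stack([beta, beta ** 2, beta ** 3])

    def weights_at(g):
        return _normalize_log_weights(B @ np.asarray(g, float), n)

    def neg_etp(g):
        w = weights_at(g)
        return -expected_true_positives(w, priormodel.class_priors, n,
                                        altmodel, alpha_fwer, M)

    if gammas is not None:
        g_opt = tuple(float(v) for v in gammas)
        w = weights_at(g_opt)
        return WeightAssignment("cpw", g_opt, w, alpha_fwer, -neg_etp(g_opt))

    start = np.array([1.0, 0.0, 0.0])
    f_start = neg_etp(start)
    try:
        res = minimize(neg_etp, start, method="Nelder-Mead",
                       options={"maxiter": max_iter, "fatol": 1e-8, "xatol": 1e-8})
        g_opt, f_opt = res.x, res.fun
    except Exception as exc:  # pragma: no cover - scipy failure path
        logger.warning("Nelder-Mead failed (%s); falling back to simple weights", exc)
        g_opt, f_opt = start, f_start
    if not np.isfinite(f_opt) or f_opt > f_start:
        g_opt, f_opt = start, f_start
    return WeightAssignment("cpw", tuple(float(v) for v in g_opt),
                            weights_at(g_opt), alpha_fwer, -float(f_opt))


def apply_weights(stats, assignment: WeightAssignment,
                  eqclasses: EquivalenceClasses) -> WeightedResults:
    """Divide each SNP's p-value by its class weight, capping at 1.

    Weights are floored at 1e-6 before division so massively down-weighted
    classes cannot overflow.
    """
    if len(assignment.class_weights) != eqclasses.n_classes:
        raise ValueError("one weight per equivalence class required")
    w_snp = np.maximum(eqclasses.expand(assignment.class_weights), WEIGHT_FLOOR)
    pw = np.minimum(1.0, stats.p / w_snp)
    return WeightedResults(stats.p.copy(), w_snp, pw, eqclasses.class_of_snp.copy())
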