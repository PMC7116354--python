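"""Penalty selection by segment-preserving half-split cross-validation.

SNPs are cut into short genome-contiguous segments (to respect local LD
structure) and, in each of the replicates, whole segments are randomly
assigned to a training half; the prior model is fitted on the training half
for every candidate penalty and scored by the expected number of true
positives of Simple weighting on the held-out half.  The penalty with the
best replicate-averaged test score is selected, ties broken toward more
shrinkage (larger lambda).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enrichment import AlternativeModel, LocalFdrFit, _penalized_logistic
from .mapping import EquivalenceClasses
from .weighting import _normalize_log_weights, expected_true_positives

logger = logging.getLogger(__name__)


def _genome_order(stats) -> np.ndarray:
    """Stable SNP ordering by (chromosome, position); numeric chromosomes
    first in numeric order, then others lexicographically."""
    def chrom_key(c):
        try:
            return (0, int(c), "")
        except ValueError:
            return (1, 0, str(c))
    keys = [(*chrom_key(c), p) for c, p in zip(stats.chrom, stats.pos)]
    return np.array(sorted(range(stats.n_snps), key=lambda j: keys[j]), dtype=np.int64)


@dataclass
class CVPlan:
    """Train/test SNP index masks for each cross-validation replicate."""

    n_replicates: int
    segment_length: int
    seed: int
    train_masks: list  # list of boolean arrays over SNPs (original order)

    def __post_init__(self):
        for m in self.train_masks:
            if not (m.any() and (~m).any()):
                raise ValueError("each replicate needs non-empty train and test halves")


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_power: np.ndarray          # replicate-mean test E[TP] per lambda
    power_matrix: np.ndarray        # replicates x lambdas
    lambda_star: float

    def to_json_dict(self) -> dict:
        return {"lambdas": self.lambdas.tolist(),
                "mean_power": self.mean_power.tolist(),
                "lambda_star": float(self.lambda_star)}


def make_cv_plan(stats, segment_length: int = 100, n_replicates: int = 10,
                 seed: int = 0) -> CVPlan:
    """Cut genome-ordered SNPs into contiguous segments of ``segment_length``
    (last may be short) and assign each segment to the training half with
    probability 1/2, independently per replicate.

    A replicate with an empty half is redrawn (vanishingly rare except on
    tiny inputs).
    """
    if segment_length < 1:
        raise ValueError("segment_length must be >= 1")
    M = stats.n_snps
    if M < 2 * segment_length:
        raise ValueError(
            f"cannot split {M} SNPs into two halves with segments of {segment_length}")
    order = _genome_order(stats)
    n_seg = int(np.ceil(M / segment_length))
    seg_of_rank = np.repeat(np.arange(n_seg), segment_length)[:M]
    seg_of_snp = np.empty(M, dtype=np.int64)
    seg_of_snp[order] = seg_of_rank

    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n_replicates):
        for _try in range(100):
            to_train = rng.random(n_seg) < 0.5
            mask = to_train[seg_of_snp]
            if mask.any() and not mask.all():
                break
        else:  # pragma: no cover - probabilistically unreachable
            raise RuntimeError("could not draw a non-degenerate split")
        masks.append(mask)
    return CVPlan(n_replicates, segment_length, seed, masks)


def _half_fit_inputs(eqclasses: EquivalenceClasses, lfdrfit: LocalFdrFit, mask):
    """Class sizes and class-mean mPPA restricted to the SNPs in ``mask``."""
    C = eqclasses.n_classes
    cls = eqclasses.class_of_snp[mask]
    n_half = np.bincount(cls, minlength=C).astype(float)
    tot = np.bincount(cls, weights=lfdrfit.mppa[mask], minlength=C)
    present = n_half > 0
    psibar = np.clip(tot[present] / n_half[present], 1e-6, 1 - 1e-6)
    return present, n_half[present], psibar


def select_lambda(eqclasses: EquivalenceClasses, lfdrfit: LocalFdrFit,
                  cvplan: CVPlan, lambdas, altmodel: AlternativeModel,
                  alpha_fwer: float = 0.05, alpha_mix: float = 1.0) -> CVResult:
    """Choose the LASSO penalty maximizing mean held-out E[TP] under SPW.

    For each replicate: fit the warm-started penalty path on the training
    half's classes, derive Simple weights from the fitted model on the
    held-out half (class sizes recomputed there), and score them by the
    expected number of true positives with the held-out half's own
    class-mean mPPA standing in for the class priors.  Scoring against
    held-out posteriors (rather than the training model's own priors) is
    what penalizes overfit penalties: weights aligned with training noise
    find no matching signal in the test half.  The selected lambda maximizes
    the replicate mean; exact ties go to the largest lambda.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) > 1 and np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda sequence must be strictly decreasing")
    R, L = cvplan.n_replicates, len(lambdas)
    power = np.full((R, L), np.nan)

    for r, train in enumerate(cvplan.train_masks):
        tr_present, tr_n, tr_psi = _half_fit_inputs(eqclasses, lfdrfit, train)
        te_present, te_n, te_psi = _half_fit_inputs(eqclasses, lfdrfit, ~train)
        V_tr = eqclasses.V_classes[tr_present]
        V_te = eqclasses.V_classes[te_present]
        M_te = te_n.sum()
        kappa0 = beta0 = None
        for li, lam in enumerate(lambdas):
            try:
                kappa, beta = _penalized_logistic(V_tr, tr_psi, tr_n, lam,
                                                  alpha_mix, kappa0, beta0)
            except Exception as exc:
                logger.warning("CV replicate %d, lambda=%.4g: fit failed (%s)",
                               r, lam, exc)
                continue
            kappa0, beta0 = kappa, beta
            logodds = np.asarray(V_te @ beta).ravel() + kappa
            w = _normalize_log_weights(logodds, te_n)
            power[r, li] = expected_true_positives(w, te_psi, te_n, altmodel,
                                                   alpha_fwer, M_te)

    ok = ~np.all(np.isnan(power), axis=0)
    if not ok.any():
        raise RuntimeError("cross-validation failed at every candidate lambda")
    if not ok.all():
        logger.warning("dropped %d lambda value(s) where all CV fits failed",
                       int((~ok).sum()))
    mean_power = np.where(ok, np.nanmean(power, axis=0), -np.inf)
    # lambdas are decreasing, argmax returns the first (largest) maximizer
    lambda_star = float(lambdas[int(np.argmax(mean_power))])
    return CVResult(lambdas, np.where(ok, mean_power, np.nan), power, lambda_star)
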