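"""End-to-end orchestration: reweighting runs and simulation studies.

``reweight`` chains the full method — probit transform, SNP-to-pathway
mapping, equivalence classes, local-FDR posteriors, penalized prior model
(with optional cross-validated penalty), weight construction, weighted
p-values.  ``run_simulation_study`` wraps the whole-genome simulator around
that chain and tallies Type-1 error and power per analysis method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import crossval, enrichment, mapping, simulate, weighting
from .io import GeneCoordinates, GeneSetCollection, SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class ReweightResult:
    """Everything produced by one reweighting run."""

    stats: SummaryStats
    eqclasses: mapping.EquivalenceClasses
    lfdrfit: enrichment.LocalFdrFit
    altmodel: enrichment.AlternativeModel
    prior_model: enrichment.PriorModel
    assignments: dict            # scheme -> WeightAssignment
    results: dict                # scheme -> WeightedResults
    cv_result: crossval.CVResult | None
    diagnostics: dict = field(default_factory=dict)


def reweight(stats: SummaryStats, coords: GeneCoordinates,
             genesets: GeneSetCollection, *,
             flank_bp: int = 0, scheme: str = "cpw", alpha_mix: float = 1.0,
             lam="cv", lambdas=None, n_lambda: int = 100,
             lambda_min_ratio: float = 1e-3,
             cv_segment_length: int = 100, cv_replicates: int = 10,
             alpha_fwer: float = 0.05, seed: int = 0) -> ReweightResult:
    """Run the full pathway-guided reweighting chain on one GWAS.

    Parameters
    ----------
    scheme : {"spw", "cpw", "both"}
        Weighting scheme(s) to compute.
    lam : "cv" or float
        Penalty; ``"cv"`` selects it by segment-preserving cross-validation.
    """
    if scheme not in ("spw", "cpw", "both"):
        raise ValueError("scheme must be 'spw', 'cpw' or 'both'")
    stats = enrichment.pvalues_to_zscores(stats)
    annot = mapping.map_snps_to_pathways(stats, coords, genesets, flank_bp)
    eq = mapping.collapse_equivalence_classes(annot)
    lfdrfit = enrichment.estimate_mppa(stats.z)
    eq = enrichment.class_mean_mppa(eq, lfdrfit)
    altmodel = enrichment.estimate_alternative(stats.z, lfdrfit.mppa)

    if lambdas is None:
        lambdas = enrichment.default_lambda_path(eq, alpha_mix, n_lambda,
                                                 lambda_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    cv_result = None
    if isinstance(lam, str) and lam == "cv":
        plan = crossval.make_cv_plan(stats, cv_segment_length, cv_replicates, seed)
        cv_result = crossval.select_lambda(eq, lfdrfit, plan, lambdas, altmodel,
                                           alpha_fwer, alpha_mix)
        lam_star = cv_result.lambda_star
    else:
        lam_star = float(lam)

    model = enrichment.fit_prior_model(eq, lam_star, alpha_mix)
    assignments, results = {}, {}
    if scheme in ("spw", "both"):
        wa = weighting.simple_weights(model, eq, alpha_fwer, altmodel)
        assignments["spw"] = wa
        results["spw"] = weighting.apply_weights(stats, wa, eq)
    if scheme in ("cpw", "both"):
        wa = weighting.cubic_weights(model, eq, altmodel, alpha_fwer)
        assignments["cpw"] = wa
        results["cpw"] = weighting.apply_weights(stats, wa, eq)

    diag = {
        "n_snps": stats.n_snps,
        "n_annotations": annot.n_annotations,
        "n_classes": eq.n_classes,
        "lambda_star": lam_star,
        "pi0": lfdrfit.pi0,
        "alt_mu": altmodel.mu,
        "alt_tau2": altmodel.tau2,
        "alpha_fwer": alpha_fwer,
        "alpha_mix": alpha_mix,
        "flank_bp": flank_bp,
        "seed": seed,
        "prior_model": model.to_json_dict(),
    }
    if cv_result is not None:
        diag["cv"] = cv_result.to_json_dict()
    for name, wa in assignments.items():
        diag[f"{name}_gammas"] = list(wa.gammas)
        diag[f"{name}_expected_tp"] = float(wa.objective)
    logger.info("reweight: M=%d K=%d C=%d lambda*=%.4g pi0=%.3f",
                stats.n_snps, annot.n_annotations, eq.n_classes,
                lam_star, lfdrfit.pi0)
    return ReweightResult(stats, eq, lfdrfit, altmodel, model,
                          assignments, results, cv_result, diag)


def write_results(result: ReweightResult, scheme: str, path) -> None:
    """Write the per-SNP results table with parameter-echo header lines."""
    wr = result.results[scheme]
    with open(path, "w") as fh:
        for k in ("n_snps", "n_annotations", "n_classes", "lambda_star", "pi0",
                  "alpha_fwer", "alpha_mix", "flank_bp", "seed"):
            fh.write(f"# {k}={result.diagnostics[k]}\n")
        fh.write(f"# scheme={scheme}\n")
        fh.write("SNP\tCHR\tBP\tP\tWEIGHT\tP_WEIGHTED\tCLASS_ID\n")
        s = result.stats
        for j in range(s.n_snps):
            fh.write(f"{s.snp_id[j]}\t{s.chrom[j]}\t{s.pos[j]}\t{s.p[j]:.6g}\t"
                     f"{wr.weight[j]:.6g}\t{wr.p_weighted[j]:.6g}\t{wr.class_id[j]}\n")


def write_diagnostics(result: ReweightResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.diagnostics, fh, indent=2, default=float)


# --------------------------------------------------------------------------
# simulation studies


class _EvalAccumulator:
    """Streaming tally of rejection counts, one per analysis method."""

    def __init__(self, truth: simulate.TruthLabels, levels):
        self.truth = truth
        self.levels = np.asarray(levels, dtype=float)
        self.null_count = np.zeros(len(self.levels))
        self.causal_hits = np.zeros((int(truth.delta.sum()), len(self.levels)))
        self.n_reps = 0

    def add(self, p: np.ndarray) -> None:
        pn, pc = p[self.truth.is_null], p[self.truth.delta]
        for li, t in enumerate(self.levels):
            self.null_count[li] += np.count_nonzero(pn <= t)
            self.causal_hits[:, li] += pc <= t
        self.n_reps += 1

    def report(self) -> simulate.EvalReport:
        n_null = int(self.truth.is_null.sum())
        type1 = self.null_count / (self.n_reps * n_null)
        per_snp = self.causal_hits / self.n_reps
        power = per_snp.mean(axis=0) if per_snp.size else np.zeros(len(self.levels))
        return simulate.EvalReport(self.levels, type1, power, per_snp,
                                   n_null, per_snp.shape[0], self.n_reps)


DEFAULT_METHODS = {
    "unweighted": {"scheme": "unweighted"},
    "spw": {"scheme": "spw"},
    "cpw": {"scheme": "cpw"},
}


@dataclass
class SimulationStudyResult:
    reports: dict                # method name -> EvalReport
    lambda_stars: np.ndarray     # selected penalty per replicate
    truth: simulate.TruthLabels


def run_simulation_study(scenario: simulate.SimScenario,
                         pathway_config: simulate.SyntheticPathwayConfig,
                         *, methods: dict | None = None,
                         levels=simulate.DEFAULT_LEVELS,
                         lambda_mode="cv", n_lambda: int = 20,
                         lambda_min_ratio: float = 1e-2,
                         cv_replicates: int = 10, cv_segment_length: int = 100,
                         alpha_fwer: float = 0.05,
                         flank_bp: int = 0) -> SimulationStudyResult:
    """Replicate the whole-genome simulation design and evaluate analyses.

    Per replicate: simulate summary statistics, estimate mPPA, select the
    penalty (``lambda_mode="cv"`` for cross-validation, or a fixed float),
    fit the prior model and produce weighted p-values for every requested
    method.  Methods are given as ``{name: {"scheme": "unweighted"|"spw"|
    "cpw", "lambda_factor": f}}``; the factor multiplies the selected penalty
    (e.g. 10 for deliberate over-shrinkage, 0.1 for over-fitting).

    The SNP layout, pathway list and annotation matrix are fixed across
    replicates; only the Z-scores are redrawn.  All randomness descends from
    ``scenario.seed``.
    """
    methods = dict(DEFAULT_METHODS) if methods is None else methods
    snp_map = simulate.build_snp_map(scenario)
    truth = snp_map.truth()
    master = np.random.SeedSequence(scenario.seed)
    path_seed, *rep_seeds = master.spawn(scenario.n_replicates + 1)

    pathways = simulate.make_synthetic_pathways(
        pathway_config, snp_map.causal_genes, snp_map.null_genes,
        np.random.default_rng(path_seed))
    annot = mapping.map_snps_to_pathways(snp_map.base_stats(), snp_map.coords,
                                         pathways, flank_bp)
    eq0 = mapping.collapse_equivalence_classes(annot)

    acc = {name: _EvalAccumulator(truth, levels) for name in methods}
    lambda_stars = np.empty(scenario.n_replicates)

    for r in range(scenario.n_replicates):
        rng = np.random.default_rng(rep_seeds[r])
        stats, _ = simulate.simulate_replicate(scenario, rng, snp_map)
        lfdrfit = enrichment.estimate_mppa(stats.z)
        eq = enrichment.class_mean_mppa(eq0, lfdrfit)
        altmodel = enrichment.estimate_alternative(stats.z, lfdrfit.mppa)
        lambdas = enrichment.default_lambda_path(eq, 1.0, n_lambda,
                                                 lambda_min_ratio)
        if isinstance(lambda_mode, str) and lambda_mode == "cv":
            cv_seed = int(rep_seeds[r].generate_state(1)[0] % (2 ** 31))
            plan = crossval.make_cv_plan(stats, cv_segment_length,
                                         cv_replicates, cv_seed)
            cv = crossval.select_lambda(eq, lfdrfit, plan, lambdas, altmodel,
                                        alpha_fwer)
            lam_star = cv.lambda_star
        else:
            lam_star = float(lambda_mode)
        lambda_stars[r] = lam_star

        model_cache: dict = {}
        for name, spec in methods.items():
            schm = spec["scheme"]
            if schm == "unweighted":
                acc[name].add(stats.p)
                continue
            lam = lam_star * float(spec.get("lambda_factor", 1.0))
            if lam not in model_cache:
                model_cache[lam] = enrichment.fit_prior_model(eq, lam)
            model = model_cache[lam]
            if schm == "spw":
                wa = weighting.simple_weights(model, eq, alpha_fwer, altmodel)
            elif schm == "cpw":
                wa = weighting.cubic_weights(model, eq, altmodel, alpha_fwer)
            else:
                raise ValueError(f"unknown scheme {schm!r} for method {name!r}")
            wr = weighting.apply_weights(stats, wa, eq)
            acc[name].add(wr.p_weighted)
        logger.debug("replicate %d/%d done (lambda*=%.4g)",
                     r + 1, scenario.n_replicates, lam_star)

    return SimulationStudyResult({n: a.report() for n, a in acc.items()},
                                 lambda_stars, truth)
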