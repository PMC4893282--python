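"""Cross-validated predictive ability: AUC, liability-scale R2, heritability.

Predictive ability is assessed at the patient level: the posterior-mean
linear predictor eta-hat scores each test patient against the ever-event
indicator within follow-up (AUC), and the liability-scale coefficient of
determination is

    R2_probit = var(eta_hat) / (var(eta_hat) + sigma2_e),   sigma2_e = 1,

the proportion of liability variance explained by the predictors in the
testing set.  The SNP-only model's cross-validated R2_probit doubles as a
(lower-bound-style) estimate of the outcome's common-SNP heritability.

Folds are stratified by event status with a seed-deterministic assignment
that does not depend on the input row order, so shuffled cohorts yield
identical fold means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .intervals import IntervalGrid
from .samplers import FitResult, LassoState, SamplerConfig, fit, \
    sample_snp_effects

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Per-fold and averaged cross-validation statistics."""

    model_label: str
    n_folds: int
    per_fold: list[dict] = field(default_factory=list)
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    r2_mean: float = float("nan")
    r2_sd: float = float("nan")
    heritability_estimate: float | None = None   # SNP-only model

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def to_row(self) -> dict:
        """One Table-style row: model, AUC (sd), R2 (sd)."""
        return {
            "model": self.model_label,
            "AUC": self.auc_mean, "AUC_sd": self.auc_sd,
            "R2_probit": self.r2_mean, "R2_probit_sd": self.r2_sd,
        }


def auc_roc(score: np.ndarray, label: np.ndarray) -> float:
    """Area under the ROC curve of a continuous score.

    Equals the normalised Mann-Whitney U statistic,
    P(score_event > score_censored) + 0.5 * P(tie).
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    if len(set(label.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(label, score))


def r2_probit(eta_test: np.ndarray) -> float:
    """Liability-scale determination coefficient var/(var+1).

    Sample variance with denominator n-1; a constant predictor returns 0.
    """
    eta_test = np.asarray(eta_test, dtype=float)
    if len(eta_test) < 2:
        raise ValueError("need at least 2 test patients")
    v = float(np.var(eta_test, ddof=1))
    if v == 0.0:
        return 0.0
    return v / (v + 1.0)


def _stratified_folds(patient_ids: np.ndarray, event: np.ndarray,
                      n_folds: int, seed: int) -> np.ndarray:
    """Seed-deterministic, order-independent fold assignment.

    Patients are sorted by id within each event stratum, shuffled with the
    seeded generator, and dealt to folds round-robin; the assignment
    therefore depends only on the id/event pairs and the seed.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(patient_ids), dtype=int)
    pos = {pid: i for i, pid in enumerate(patient_ids)}
    for stratum in (0, 1):
        ids = sorted(patient_ids[event == stratum])
        perm = rng.permutation(len(ids))
        for slot, j in enumerate(perm):
            assignment[pos[ids[j]]] = slot % n_folds
    return assignment


def _fold_seeds(seed: int, n_folds: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n_folds)]


def crossvalidate(cohort, grid: IntervalGrid, model: str, n_folds: int = 10,
                  config: SamplerConfig | None = None,
                  seed: int | None = None) -> EvalReport:
    """K-fold cross-validation of one model variant.

    Folds are stratified by event status.  Each fold's model is fitted on
    the training patients; test patients are scored with the posterior-mean
    linear predictor, from which AUC (against the event indicator) and
    R2_probit are computed.  A fold whose test set lacks events (or
    non-events) has no AUC and is excluded from the AUC mean with a
    warning.
    """
    config = config or SamplerConfig()
    if seed is None:
        seed = config.seed
    assignment = _stratified_folds(cohort.patient_ids, cohort.event,
                                   n_folds, seed)
    seeds = _fold_seeds(seed, n_folds)
    per_fold: list[dict] = []
    for f in range(n_folds):
        test = assignment == f
        train = ~test
        # canonical (id-sorted) order inside each fold, so results do not
        # depend on the cohort's row order
        train_idx = np.flatnonzero(train)
        train_idx = train_idx[np.argsort(cohort.patient_ids[train_idx])]
        res = fit(cohort.subset(train_idx), grid, model,
                  config.replace(seed=seeds[f]))
        test_idx = np.flatnonzero(test)
        test_idx = test_idx[np.argsort(cohort.patient_ids[test_idx])]
        eta_test = res.predict(
            covariates=cohort.covariates[test_idx],
            genotypes=cohort.genotypes[test_idx]
            if model in ("snp", "cpp_snp") else None,
        )
        labels = cohort.event[test_idx]
        if len(set(labels.tolist())) < 2:
            log.warning("fold %d has a single outcome class; AUC undefined", f)
            auc = float("nan")
        else:
            auc = auc_roc(eta_test, labels)
        per_fold.append({"fold": f, "auc": auc,
                         "r2_probit": r2_probit(eta_test)})
    aucs = np.array([d["auc"] for d in per_fold])
    r2s = np.array([d["r2_probit"] for d in per_fold])
    valid = ~np.isnan(aucs)
    report = EvalReport(
        model_label=model, n_folds=n_folds, per_fold=per_fold,
        auc_mean=float(np.mean(aucs[valid])) if valid.any() else float("nan"),
        auc_sd=float(np.std(aucs[valid], ddof=1)) if valid.sum() > 1
        else float("nan"),
        r2_mean=float(np.mean(r2s)),
        r2_sd=float(np.std(r2s, ddof=1)) if len(r2s) > 1 else float("nan"),
    )
    if model == "snp":
        report.heritability_estimate = report.r2_mean
    return report


def heritability(snp_report: EvalReport) -> float:
    """Common-SNP heritability estimate from the SNP-only model.

    Taken as that model's mean cross-validated R2_probit — the fraction of
    liability variance captured by the genome-wide markers.  This is a
    lower-bound-style estimate: shrinkage, finite sample size and marker
    pruning all bias it downward.
    """
    if snp_report.model_label != "snp":
        raise ValueError("heritability requires the SNP-only model's report")
    return float(snp_report.r2_mean)


def heritability_whole_sample(cohort, grid: IntervalGrid,
                              config: SamplerConfig | None = None) -> float:
    """Whole-sample (non-cross-validated) variant of the estimate."""
    res = fit(cohort, grid, "snp", config)
    eta = res.predict(genotypes=cohort.genotypes)
    return r2_probit(eta)


# ---------------------------------------------------------------------------
# Decomposition: how much of the covariate-based prediction do SNPs explain
# ---------------------------------------------------------------------------

def _linear_lasso_gibbs(y: np.ndarray, W: np.ndarray, config: SamplerConfig,
                        rng: np.random.Generator,
                        ) -> tuple[np.ndarray, float]:
    """Bayesian LASSO for a continuous response with free residual variance.

    Same Park–Casella hierarchy as the probit-model SNP block, but the
    response is observed directly and sigma2 is drawn from its
    inverse-gamma full conditional.  Returns posterior means of the effects
    and sigma2.
    """
    n, p = W.shape
    y = y - y.mean()
    effects = np.zeros(p)
    state = LassoState(lambda2=1.0, tau2=np.ones(p))
    sigma2 = max(float(np.var(y)), 1e-6)
    wtw = np.einsum("ij,ij->j", W, W)
    eff_sum = np.zeros(p)
    s2_sum = 0.0
    n_kept = 0
    for it in range(config.n_iter):
        effects, state = sample_snp_effects(
            y, W, state, rng, effects=effects, wtw=wtw, sigma2=sigma2,
            lasso_shape=config.lasso_shape, lasso_rate=config.lasso_rate)
        res = y - W @ effects
        shape = (n + p) / 2.0
        rate = (res @ res + np.sum(effects ** 2 / state.tau2)) / 2.0
        sigma2 = 1.0 / rng.gamma(shape, 1.0 / max(rate, 1e-12))
        sigma2 = max(sigma2, 1e-10)
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            eff_sum += effects
            s2_sum += sigma2
            n_kept += 1
    return eff_sum / n_kept, s2_sum / n_kept


def decompose_cpp_prediction(cohort, grid: IntervalGrid, cpp_fit: FitResult,
                             config: SamplerConfig | None = None,
                             n_folds: int = 10,
                             seed: int | None = None) -> float:
    """Proportion of the covariate-based prediction variance captured by SNPs.

    The covariate model's posterior-mean predictor eta-hat is treated as a
    continuous dependent variable and regressed on the SNPs with a linear
    Bayesian LASSO whose residual variance is free.  Cross-validated
    var(predicted)/(var(predicted) + sigma2-hat) on held-out patients
    quantifies how much of what the clinico-pathological prognosticators
    predict is itself predictable from the genome.
    """
    config = config or SamplerConfig()
    if seed is None:
        seed = config.seed
    if list(cpp_fit.patient_ids) != list(cohort.patient_ids):
        raise AlignmentError("cpp_fit patients do not match the cohort")
    if np.isnan(cohort.genotypes).any():
        raise ValueError("genotypes contain missing calls; impute first")
    eta_cpp = cohort.covariates @ cpp_fit.beta_mean
    assignment = _stratified_folds(cohort.patient_ids, cohort.event,
                                   n_folds, seed)
    seeds = _fold_seeds(seed, n_folds)
    r2s = []
    for f in range(n_folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        train = train[np.argsort(cohort.patient_ids[train])]
        center = cohort.genotypes[train].mean(axis=0)
        Wtr = cohort.genotypes[train] - center
        rng = np.random.default_rng(seeds[f])
        effects, sigma2 = _linear_lasso_gibbs(eta_cpp[train], Wtr, config, rng)
        pred = (cohort.genotypes[test] - center) @ effects
        v = float(np.var(pred, ddof=1)) if len(pred) > 1 else 0.0
        r2s.append(v / (v + sigma2))
    return float(np.mean(r2s))


def summary_table(reports: list[EvalReport]) -> pd.DataFrame:
    """One row per model: AUC (sd) and R2_probit (sd)."""
    return pd.DataFrame([r.to_row() for r in reports])
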