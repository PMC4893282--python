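"""Gibbs samplers for the sequential threshold (discrete-time probit) model.

Three model variants are supported on the person-interval expanded data:

* ``cpp`` — clinico-pathological covariates only, with vague independent
  normal priors on the coefficients (Bayesian regression);
* ``snp`` — genome-wide SNP effects only, under the Park–Casella Bayesian
  LASSO hierarchy (effect_j ~ N(0, tau2_j), tau2_j ~ Exp(lambda2/2),
  lambda2 ~ Gamma(a, b));
* ``cpp_snp`` — both blocks combined additively on the liability scale.

Sampling uses probit data augmentation: each record's latent liability is a
unit-variance normal centred at the patient's linear predictor, truncated
below/above the interval cutoff gamma_k according to the binary outcome.
The cutoffs are unordered and act as interval-specific intercepts; each is
drawn from its normal full conditional under a weakly informative
N(0, gamma_prior_var) prior (the last, open-ended interval can carry
event-only records, under which a fully flat prior would leave the cutoff's
conditional improper).  The residual variance is fixed at 1 throughout to
identify the liability scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtri
from scipy.stats import truncnorm

from .intervals import ExpandedData, IntervalGrid, expand

log = logging.getLogger(__name__)

MODELS = ("cpp", "snp", "cpp_snp")


@dataclass
class SamplerConfig:
    """Chain bookkeeping and prior settings for the Gibbs samplers."""

    n_iter: int = 20000
    n_burnin: int = 5000
    thin: int = 10
    seed: int = 0
    beta_prior_var: float = 1e6       # vague normal prior for covariates
    gamma_prior_var: float = 100.0    # weakly informative prior for cutoffs
    lasso_shape: float = 0.1          # Gamma(a, b) hyperprior on lambda2
    lasso_rate: float = 0.1
    store_chains: bool = False

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.beta_prior_var <= 0 or self.gamma_prior_var <= 0:
            raise ValueError("prior variances must be positive")

    def replace(self, **kw) -> "SamplerConfig":
        d = {**self.__dict__, **kw}
        return SamplerConfig(**d)


@dataclass
class LassoState:
    """Current LASSO hyperparameters: lambda2 and per-SNP variances."""

    lambda2: float
    tau2: np.ndarray

    def __post_init__(self) -> None:
        self.tau2 = np.asarray(self.tau2, dtype=float)
        if self.lambda2 <= 0 or (self.tau2 <= 0).any():
            raise ValueError("lambda2 and tau2 entries must be positive")


@dataclass
class FitResult:
    """Posterior summaries from a Gibbs run."""

    model: str
    gamma_mean: np.ndarray
    beta_mean: np.ndarray                  # empty for model="snp"
    snp_effect_mean: np.ndarray            # empty for model="cpp"
    lambda_mean: float | None              # None for model="cpp"
    sigma2_e: float
    n_iter: int
    n_burnin: int
    thin: int
    seed: int
    snp_center: np.ndarray | None = None   # training-set marker means
    covariate_names: list[str] = field(default_factory=list)
    patient_ids: list[str] = field(default_factory=list)
    boundaries: np.ndarray | None = None
    chains: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.sigma2_e != 1.0:
            raise ValueError("residual variance is fixed at 1.0")

    def predict(self, covariates: np.ndarray | None = None,
                genotypes: np.ndarray | None = None) -> np.ndarray:
        """Posterior-mean linear predictor (liability scale) for new data.

        Genotypes are centred with the training-set marker means, so the
        covariate and SNP contributions add on a common scale.
        """
        eta = None
        if self.model in ("cpp", "cpp_snp"):
            if covariates is None:
                raise ValueError(f"model {self.model!r} needs covariates")
            eta = np.asarray(covariates) @ self.beta_mean
        if self.model in ("snp", "cpp_snp"):
            if genotypes is None:
                raise ValueError(f"model {self.model!r} needs genotypes")
            g = (np.asarray(genotypes) - self.snp_center) @ self.snp_effect_mean
            eta = g if eta is None else eta + g
        return eta

    def to_json(self, path: str | Path) -> None:
        obj = {
            "model": self.model,
            "gamma_mean": self.gamma_mean.tolist(),
            "beta_mean": self.beta_mean.tolist(),
            "snp_effect_mean": self.snp_effect_mean.tolist(),
            "lambda_mean": self.lambda_mean,
            "sigma2_e": self.sigma2_e,
            "n_iter": self.n_iter, "n_burnin": self.n_burnin,
            "thin": self.thin, "seed": self.seed,
            "snp_center": (None if self.snp_center is None
                           else self.snp_center.tolist()),
            "covariate_names": self.covariate_names,
            "patient_ids": list(self.patient_ids),
            "boundaries": (None if self.boundaries is None else [
                "inf" if np.isinf(b) else float(b) for b in self.boundaries]),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            model=obj["model"],
            gamma_mean=np.array(obj["gamma_mean"]),
            beta_mean=np.array(obj["beta_mean"]),
            snp_effect_mean=np.array(obj["snp_effect_mean"]),
            lambda_mean=obj["lambda_mean"],
            sigma2_e=obj["sigma2_e"],
            n_iter=obj["n_iter"], n_burnin=obj["n_burnin"],
            thin=obj["thin"], seed=obj["seed"],
            snp_center=(None if obj["snp_center"] is None
                        else np.array(obj["snp_center"])),
            covariate_names=obj["covariate_names"],
            patient_ids=obj["patient_ids"],
            boundaries=(None if obj["boundaries"] is None else np.array(
                [np.inf if b == "inf" else float(b)
                 for b in obj["boundaries"]])),
        )


# ---------------------------------------------------------------------------
# Full conditional draws
# ---------------------------------------------------------------------------

def _draw_truncated(mean: np.ndarray, outcome: np.ndarray,
                    thresh: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance normal draws centred at ``mean``, truncated at
    ``thresh``: below it when outcome=0, at/above it when outcome=1.

    Uses scipy's truncated-normal sampler, which remains accurate in far
    tails (|thresh - mean| > 8), so draws are always finite.
    """
    alpha = thresh - mean
    lo = np.where(outcome == 1, alpha, -np.inf)
    hi = np.where(outcome == 1, np.inf, alpha)
    draws = truncnorm.rvs(lo, hi, size=len(mean), random_state=rng)
    return mean + draws


def sample_liabilities(expanded: ExpandedData, gamma: np.ndarray,
                       eta: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Data-augmentation step: one latent liability per expanded record.

    ``eta`` is the per-patient linear predictor; the returned draws are
    N(eta_i, 1) truncated to u < gamma_k for records with outcome 0 and
    u >= gamma_k for outcome 1.
    """
    eta_rec = np.asarray(eta, dtype=float)[expanded.record_patient]
    thresh = np.asarray(gamma, dtype=float)[expanded.record_interval - 1]
    return _draw_truncated(eta_rec, expanded.record_outcome, thresh, rng)


def _gamma_step(z: np.ndarray, record_interval: np.ndarray,
                eta_rec: np.ndarray, gamma: np.ndarray, prior_var: float,
                rng: np.random.Generator, warn_empty: bool = True) -> np.ndarray:
    """Cutoff update in the intercept parameterisation.

    With z_r = eta_i - gamma_k + e_r the full conditional of gamma_k under a
    N(0, prior_var) prior is normal with precision n_k + 1/prior_var and
    mean sum(eta - z)/precision over interval-k records.
    """
    K = len(gamma)
    new = gamma.copy()
    prior_prec = 0.0 if np.isinf(prior_var) else 1.0 / prior_var
    resid = eta_rec - z
    for k in range(1, K + 1):
        mask = record_interval == k
        n_k = int(mask.sum())
        if n_k == 0:
            if warn_empty:
                log.warning("interval %d has no records; cutoff not updated", k)
            continue
        prec = n_k + prior_prec
        new[k - 1] = rng.normal(resid[mask].sum() / prec, np.sqrt(1.0 / prec))
    return new


def sample_gamma(latents: np.ndarray, record_interval: np.ndarray,
                 eta_rec: np.ndarray, gamma: np.ndarray,
                 rng: np.random.Generator,
                 prior_var: float = 100.0) -> np.ndarray:
    """Draw the K unordered cutoffs from their normal full conditionals.

    ``latents`` are the liabilities of :func:`sample_liabilities` (truncated
    at the current ``gamma``); internally the update treats -gamma_k as an
    interval-specific intercept with a N(0, prior_var) prior
    (``prior_var=inf`` gives the flat-prior limit).  Cutoffs of intervals
    with disjoint record sets are conditionally independent.
    """
    gamma = np.asarray(gamma, dtype=float)
    z = latents - gamma[np.asarray(record_interval) - 1]
    return _gamma_step(z, np.asarray(record_interval), np.asarray(eta_rec),
                       gamma, prior_var, rng)


def sample_beta(latents: np.ndarray, X: np.ndarray, prior_var: float,
                rng: np.random.Generator,
                offset: np.ndarray | float = 0.0) -> np.ndarray:
    """Joint multivariate-normal draw of the covariate effects.

    ``latents`` are record-level liabilities from
    :func:`sample_liabilities` (the interval intercepts cancel in this
    parameterisation); ``offset`` holds any other linear-predictor part
    (e.g. the SNP contribution).  Independent N(0, prior_var) priors,
    residual variance 1.
    """
    resp = latents - offset
    q = X.shape[1]
    A = X.T @ X + np.eye(q) / prior_var
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "collinear covariate columns; posterior precision is singular"
        ) from exc
    mean = np.linalg.solve(A, X.T @ resp)
    z = rng.standard_normal(q)
    from scipy.linalg import solve_triangular
    return mean + solve_triangular(L.T, z, lower=False)


def sample_snp_effects(latents: np.ndarray, W: np.ndarray, state: LassoState,
                       rng: np.random.Generator,
                       offset: np.ndarray | float = 0.0,
                       effects: np.ndarray | None = None,
                       wtw: np.ndarray | None = None,
                       sigma2: float = 1.0,
                       update_lambda: bool = True,
                       lasso_shape: float = 0.1, lasso_rate: float = 0.1,
                       ) -> tuple[np.ndarray, LassoState]:
    """Single-site Gibbs sweep over SNP effects plus hyperparameter updates.

    ``W`` must be a complete (imputed) centred dosage matrix at the record
    level.  Each effect is drawn from its scalar normal full conditional
    with prior variance sigma2*tau2_j; then tau2_j from its inverse-Gaussian
    conditional and lambda2 from its Gamma conditional (Park–Casella forms).
    ``sigma2`` is 1 for the probit model; the linear-response LASSO used in
    the prediction decomposition passes its current residual variance.
    Zero-variance markers keep their effect fixed at 0.
    """
    p = W.shape[1]
    if effects is None:
        effects = np.zeros(p)
    else:
        effects = effects.copy()
    if wtw is None:
        wtw = np.einsum("ij,ij->j", W, W)
    res = latents - offset - W @ effects
    normals = rng.standard_normal(p)
    zero_var = wtw == 0
    if zero_var.any() and (effects[zero_var] != 0).any():
        log.warning("zero-variance marker(s); effects fixed at 0")
    for j in range(p):
        if zero_var[j]:
            if effects[j] != 0.0:
                res += W[:, j] * effects[j]
                effects[j] = 0.0
            continue
        d = wtw[j] + 1.0 / state.tau2[j]
        m = (W[:, j] @ res + wtw[j] * effects[j]) / d
        new = m + normals[j] * np.sqrt(sigma2 / d)
        res += W[:, j] * (effects[j] - new)
        effects[j] = new
    # tau2_j: 1/tau2_j ~ InverseGaussian(sqrt(lambda2*sigma2/effect^2), lambda2)
    a2 = np.maximum(effects ** 2, 1e-20)
    mu = np.clip(np.sqrt(state.lambda2 * sigma2 / a2), 1e-10, 1e8)
    inv_tau2 = rng.wald(mu, state.lambda2)
    tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
    lambda2 = state.lambda2
    if update_lambda:
        shape = p + lasso_shape
        rate = lasso_rate + tau2.sum() / 2.0
        lambda2 = rng.gamma(shape, 1.0 / rate)
    return effects, LassoState(lambda2=lambda2, tau2=tau2)


# ---------------------------------------------------------------------------
# Full Gibbs loop
# ---------------------------------------------------------------------------

def _check_covariate_rank(X: np.ndarray, names: list[str]) -> None:
    q = X.shape[1]
    if q == 0:
        raise ValueError("model includes covariates but none are present")
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        # name columns whose removal does not reduce the rank (collinear set)
        suspects = [names[j] if j < len(names) else f"col{j}"
                    for j in range(q)
                    if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"covariate matrix is rank deficient; collinear "
                         f"candidates: {suspects}")


def fit(cohort, grid: IntervalGrid, model: str,
        config: SamplerConfig | None = None) -> FitResult:
    """Fit one model variant by Gibbs sampling on the expanded data.

    The scan order per iteration is: latent liabilities, cutoffs gamma,
    covariate effects beta (if present), SNP effects + tau2 + lambda2 (if
    present).  Burn-in draws are discarded and the rest thinned; posterior
    means (and optionally thinned chains) are returned.  Runs are
    deterministic under a fixed seed, and the residual variance stays fixed
    at 1.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    config = config or SamplerConfig()
    expanded = expand(cohort, grid)
    if expanded.n_records == 0:
        raise ValueError("expanded data is empty")
    use_cov = model in ("cpp", "cpp_snp")
    use_snp = model in ("snp", "cpp_snp")
    rng = np.random.default_rng(config.seed)
    pat = expanded.record_patient
    k_rec = expanded.record_interval
    y = expanded.record_outcome
    K = grid.K

    X = np.empty((expanded.n_records, 0))
    if use_cov:
        _check_covariate_rank(cohort.covariates, cohort.covariate_names)
        X = np.ascontiguousarray(cohort.covariates[pat])
    W = np.empty((expanded.n_records, 0))
    center = None
    if use_snp:
        if np.isnan(cohort.genotypes).any():
            raise ValueError("genotypes contain missing calls; impute first")
        center = cohort.genotypes.mean(axis=0)
        W = np.asfortranarray(cohort.genotypes[pat] - center)
    wtw = np.einsum("ij,ij->j", W, W)

    # initial cutoffs from per-interval empirical survival fractions
    gamma = np.zeros(K)
    for k in range(1, K + 1):
        mask = k_rec == k
        if mask.sum():
            gamma[k - 1] = ndtri(np.clip(1.0 - y[mask].mean(), 0.02, 0.98))
    empty_intervals = [k for k in range(1, K + 1) if (k_rec == k).sum() == 0]
    if empty_intervals:
        log.warning("interval(s) %s have no records; cutoffs not updated",
                    empty_intervals)
    beta = np.zeros(X.shape[1])
    effects = np.zeros(W.shape[1])
    state = LassoState(lambda2=1.0, tau2=np.ones(max(W.shape[1], 1)))

    n_kept = 0
    gamma_sum = np.zeros(K)
    beta_sum = np.zeros(X.shape[1])
    eff_sum = np.zeros(W.shape[1])
    lambda_sum = 0.0
    chains: dict[str, list] = {"gamma": [], "beta": [], "snp": [],
                               "lambda2": []} if config.store_chains else None

    xb = X @ beta if use_cov else 0.0
    g_rec = W @ effects if use_snp else 0.0
    for it in range(config.n_iter):
        eta_rec = xb + g_rec if (use_cov or use_snp) else np.zeros(len(y))
        if not np.isscalar(eta_rec) and not np.isfinite(eta_rec).all():
            raise RuntimeError(f"divergent chain at iteration {it}")
        thresh = gamma[k_rec - 1]
        u = _draw_truncated(np.broadcast_to(eta_rec, y.shape).astype(float),
                            y, thresh, rng)
        z = u - thresh
        gamma = _gamma_step(z, k_rec, np.broadcast_to(eta_rec, y.shape), gamma,
                            config.gamma_prior_var, rng, warn_empty=False)
        u_cur = z + gamma[k_rec - 1]
        if use_cov:
            beta = sample_beta(u_cur, X, config.beta_prior_var, rng,
                               offset=g_rec)
            xb = X @ beta
        if use_snp:
            effects, state = sample_snp_effects(
                u_cur, W, state, rng, offset=xb, effects=effects, wtw=wtw,
                lasso_shape=config.lasso_shape, lasso_rate=config.lasso_rate)
            g_rec = W @ effects
        if not (np.isfinite(gamma).all() and np.isfinite(beta).all()
                and np.isfinite(effects).all()):
            raise RuntimeError(f"divergent chain at iteration {it}")
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            n_kept += 1
            gamma_sum += gamma
            beta_sum += beta
            eff_sum += effects
            lambda_sum += state.lambda2
            if chains is not None:
                chains["gamma"].append(gamma.copy())
                chains["beta"].append(beta.copy())
                chains["snp"].append(effects.copy())
                chains["lambda2"].append(state.lambda2)

    return FitResult(
        model=model,
        gamma_mean=gamma_sum / n_kept,
        beta_mean=beta_sum / n_kept,
        snp_effect_mean=eff_sum / n_kept,
        lambda_mean=(lambda_sum / n_kept) if use_snp else None,
        sigma2_e=1.0,
        n_iter=config.n_iter, n_burnin=config.n_burnin,
        thin=config.thin, seed=config.seed,
        snp_center=center,
        covariate_names=list(cohort.covariate_names) if use_cov else [],
        patient_ids=list(cohort.patient_ids),
        boundaries=grid.boundaries.copy(),
        chains=(None if chains is None
                else {k: np.asarray(v) for k, v in chains.items()}),
    )
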