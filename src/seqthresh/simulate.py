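"""Synthetic cohorts with the structure the sequential model assumes.

The generator emulates a prospective cohort of non-muscle invasive bladder
cancer patients: ~800 patients, biallelic SNPs with MAF >= 0.02 arranged in
LD blocks, six clinico-pathological prognosticators (stage, grade, tumour
multiplicity, tumour size, carcinoma in situ, standardised age at
diagnosis), and discrete-time outcomes over K intervals with heavy right
censoring.  Two presets mirror the study conditions: a recurrence-like
outcome (K=9, ~33% of patients with an event) and a progression-like one
(K=4, ~9% events); in both the non-event fraction (>=50%) is censored.

Outcomes are generated in the model's own generative direction: per
interval, a patient still under observation is first censored with an
independent per-interval probability (loss to follow-up), otherwise has the
event with probability 1 - Phi(gamma_k - eta); patients surviving all K
intervals are administratively censored at the end of the study.  True SNP
effects are scaled against the *empirical* genotype variance so the target
liability-scale heritability is met per realisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .intervals import IntervalGrid
from .io import Cohort, GenotypePart, write_plink_raw

log = logging.getLogger(__name__)

COVARIATE_NAMES = ("stage_t1", "grade_high", "multiple_tumors",
                   "size_gt3cm", "cis", "age_std")


@dataclass
class SimSpec:
    """All knobs of the synthetic cohort generator.

    Defaults describe the recurrence-like study conditions at a reduced
    genomic scale; ``tfr_like``/``tp_like`` return the two outcome presets.
    """

    n_patients: int = 822
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.02, 0.5)
    n_causal: int = 20
    snp_h2: float = 0.01              # liability-scale SNP variance fraction
    cpp_effects: tuple[float, ...] = (0.30, 0.25, 0.20, 0.20, 0.40, 0.15)
    cov_prevalence: tuple[float, ...] = (0.35, 0.30, 0.40, 0.25, 0.05)
    n_intervals: int = 9
    event_fraction: float = 0.33      # target marginal event fraction
    gamma_true: tuple[float, ...] | None = None   # overrides event_fraction
    censor_rate: float = 0.02         # per-interval loss to follow-up
    ld_block_size: int = 10
    ld_rho: float = 0.6               # latent within-block correlation
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.snp_h2 < 1:
            raise ValueError("snp_h2 must be in [0, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if not -1 < self.ld_rho < 1:
            raise ValueError("ld_rho must be in (-1, 1)")
        if self.gamma_true is not None and \
                len(self.gamma_true) != self.n_intervals:
            raise ValueError("gamma_true length must equal n_intervals")

    @property
    def K(self) -> int:
        return self.n_intervals


def tfr_like(**overrides) -> SimSpec:
    """Recurrence-like preset: 9 intervals, ~33% events, h2 ~ 1%."""
    kw = dict(n_intervals=9, event_fraction=0.33, snp_h2=0.01)
    kw.update(overrides)
    return SimSpec(**kw)


def tp_like(**overrides) -> SimSpec:
    """Progression-like preset: 4 intervals, ~9% events, h2 ~ 0.1%."""
    kw = dict(n_intervals=4, event_fraction=0.09, snp_h2=0.001)
    kw.update(overrides)
    return SimSpec(**kw)


def default_grid(spec: SimSpec) -> IntervalGrid:
    """Unit-width grid matching the generator's interval coding."""
    K = spec.K
    return IntervalGrid(np.concatenate((np.arange(K, dtype=float), [np.inf])))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: SimSpec, rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, list[str], np.ndarray,
                                  np.ndarray]:
    """Hardy-Weinberg dosages with block LD via a latent Gaussian copula.

    Within each block of ``ld_block_size`` markers two latent haplotype
    vectors share an equicorrelated Gaussian structure (``ld_rho``);
    thresholding each at the quantile of its marker's MAF yields alleles,
    whose sum is the dosage.  Returns (dosages, snp_ids, chroms, mafs);
    no missingness is injected here (see :func:`simulate_cohort`).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n, p = spec.n_patients, spec.n_snps
    mafs = rng.uniform(*spec.maf_range, size=p)
    thresh = ndtri(mafs)
    dosages = np.empty((n, p))
    b = max(spec.ld_block_size, 1)
    for start in range(0, p, b):
        size = min(b, p - start)
        if spec.ld_rho != 0 and size > 1:
            C = np.full((size, size), spec.ld_rho)
            np.fill_diagonal(C, 1.0)
            L = np.linalg.cholesky(C)
        else:
            L = np.eye(size)
        block = np.zeros((n, size))
        for _hap in range(2):
            Z = rng.standard_normal((n, size)) @ L.T
            block += Z < thresh[start:start + size]
        dosages[:, start:start + size] = block
    snp_ids = [f"snp{j:06d}" for j in range(p)]
    chroms = np.array([str(1 + ((j // b) % 22)) for j in range(p)],
                      dtype=object)
    return dosages, snp_ids, chroms, mafs


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_covariates(spec: SimSpec, rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, list[str]]:
    """Six prognosticator-like columns: five binaries and standardised age."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_patients
    cols = [(rng.random(n) < prev).astype(float)
            for prev in spec.cov_prevalence]
    cols.append(rng.standard_normal(n))
    return np.column_stack(cols), list(COVARIATE_NAMES)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def _solve_baseline_hazard(K: int, target_event_fraction: float,
                           censor_rate: float) -> float:
    """Per-interval hazard h with total event probability equal to target.

    Censoring is checked before the event in every interval, so
    P(event) = (1-c) h * sum_{k=0}^{K-1} [(1-c)(1-h)]^k.
    """
    c = censor_rate

    def total(h: float) -> float:
        q = (1 - c) * (1 - h)
        return (1 - c) * h * (1 - q ** K) / (1 - q) - target_event_fraction

    if total(1 - 1e-9) < 0:
        raise ValueError("event_fraction unreachable under this censor_rate")
    return brentq(total, 1e-9, 1 - 1e-9)


def resolve_gamma(spec: SimSpec) -> np.ndarray:
    """True cutoffs: explicit if given, else a flat hazard solved so the
    marginal (eta=0) event fraction matches ``event_fraction``."""
    if spec.gamma_true is not None:
        return np.asarray(spec.gamma_true, dtype=float)
    h = _solve_baseline_hazard(spec.K, spec.event_fraction, spec.censor_rate)
    return np.full(spec.K, ndtri(1.0 - h))


def scale_snp_effects(genotypes: np.ndarray, covariate_part: np.ndarray,
                      spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw causal effects and scale them to the target liability h2.

    With residual variance 1 and empirical covariate variance V_c, the SNP
    part needs variance h2 * (V_c + 1) / (1 - h2) for the liability-scale
    SNP fraction to equal h2.
    """
    p = genotypes.shape[1]
    effects = np.zeros(p)
    if spec.n_causal == 0 or spec.snp_h2 == 0:
        return effects
    causal = rng.choice(p, size=spec.n_causal, replace=False)
    raw = rng.standard_normal(spec.n_causal)
    centred = genotypes - genotypes.mean(axis=0)
    g_raw = centred[:, causal] @ raw
    v_raw = float(np.var(g_raw))
    if v_raw == 0:
        raise ValueError("causal markers carry no variance")
    v_c = float(np.var(covariate_part))
    target = spec.snp_h2 * (v_c + 1.0) / (1.0 - spec.snp_h2)
    effects[causal] = raw * np.sqrt(target / v_raw)
    return effects


def simulate_outcomes(genotypes: np.ndarray, covariates: np.ndarray,
                      spec: SimSpec, rng: np.random.Generator | None = None,
                      snp_effects: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Walk the intervals generatively; returns (time, event, truth).

    Times are interval-coded against :func:`default_grid`: an event or
    within-interval censoring in interval k gets time k - 0.5; survivors of
    all K intervals are censored at time K.  ``truth`` records the true
    parameters, liabilities and the per-interval event/censoring log.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = genotypes.shape[0]
    gamma = resolve_gamma(spec)
    beta = np.asarray(spec.cpp_effects, dtype=float)
    cov_part = covariates @ beta
    if snp_effects is None:
        snp_effects = scale_snp_effects(genotypes, cov_part, spec, rng)
    centred = genotypes - genotypes.mean(axis=0)
    g_part = centred @ snp_effects
    # cutoffs are defined against a centred liability (the model absorbs
    # location into gamma), so centre the systematic part
    eta = (cov_part - cov_part.mean()) + g_part

    time = np.full(n, float(spec.K))
    event = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    events_per_interval = np.zeros(spec.K, dtype=int)
    censored_per_interval = np.zeros(spec.K, dtype=int)
    for k in range(1, spec.K + 1):
        p_event = 1.0 - ndtr(gamma[k - 1] - eta)
        cens = alive & (rng.random(n) < spec.censor_rate)
        ev = alive & ~cens & (rng.random(n) < p_event)
        time[cens | ev] = k - 0.5
        event[ev] = 1
        events_per_interval[k - 1] = int(ev.sum())
        censored_per_interval[k - 1] = int(cens.sum())
        alive &= ~(cens | ev)
    truth = {
        "gamma_true": gamma,
        "beta_true": beta,
        "snp_effects_true": snp_effects,
        "causal_idx": np.flatnonzero(snp_effects),
        "eta_true": eta,
        "events_per_interval": events_per_interval,
        "censored_per_interval": censored_per_interval,
        "n_end_of_study_censored": int(alive.sum()),
        "boundaries": default_grid(spec).boundaries,
    }
    return time, event, truth


def simulate_cohort(spec: SimSpec) -> tuple[Cohort, dict]:
    """Full synthetic cohort plus the generating truth.

    Genotypes are generated complete, outcomes drawn from the true (fully
    observed) dosages, and missingness injected only afterwards — genotype
    missingness is a measurement artefact, not part of the disease process.
    Identical specs give identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    genotypes, snp_ids, chroms, mafs = simulate_genotypes(spec, rng)
    covariates, cov_names = simulate_covariates(spec, rng)
    time, event, truth = simulate_outcomes(genotypes, covariates, spec, rng)
    truth["maf_true"] = mafs
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = np.nan
    cohort = Cohort(
        patient_ids=np.array([f"P{i:05d}" for i in range(spec.n_patients)]),
        genotypes=genotypes,
        snp_ids=snp_ids,
        snp_chroms=chroms,
        covariates=covariates,
        covariate_names=cov_names,
        time=time,
        event=event,
    )
    return cohort, truth


def write_simulation(cohort: Cohort, truth: dict, prefix: str | Path) -> None:
    """Write a cohort as PLINK .raw + phenotype CSV + truth JSON."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gp = GenotypePart(cohort.patient_ids, cohort.snp_ids, cohort.snp_chroms,
                      cohort.genotypes)
    write_plink_raw(gp, f"{prefix}.raw")
    df = pd.DataFrame({"IID": cohort.patient_ids, "time": cohort.time,
                       "event": cohort.event})
    for j, name in enumerate(cohort.covariate_names):
        df[name] = cohort.covariates[:, j]
    df.to_csv(f"{prefix}.pheno.csv", index=False)
    serial = {}
    for k, v in truth.items():
        if isinstance(v, np.ndarray):
            serial[k] = ["inf" if isinstance(x, float) and np.isinf(x)
                         else (x.item() if hasattr(x, "item") else x)
                         for x in v]
        else:
            serial[k] = v
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(serial, fh)
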