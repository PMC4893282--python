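import numpy as np
import pytest

from seqthresh.io import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(time, event, covariates=None, genotypes=None,
                covariate_names=None, snp_ids=None):
    """Hand-built cohort for unit tests."""
    time = np.asarray(time, dtype=float)
    n = len(time)
    if genotypes is None:
        genotypes = np.zeros((n, 0))
    genotypes = np.asarray(genotypes, dtype=float)
    if covariates is None:
        covariates = np.zeros((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    p = genotypes.shape[1]
    return Cohort(
        patient_ids=np.array([f"p{i:03d}" for i in range(n)]),
        genotypes=genotypes,
        snp_ids=snp_ids or [f"s{j}" for j in range(p)],
        snp_chroms=np.array(["1"] * p),
        covariates=covariates,
        covariate_names=covariate_names
        or [f"c{j}" for j in range(covariates.shape[1])],
        time=time,
        event=np.asarray(event, dtype=int),
    )


@pytest.fixture
def cohort_factory():
    return make_cohort
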