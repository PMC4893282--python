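"""Marker quality control: filtering, LD pruning and imputation.

The filtering pipeline removes, in order: markers on sex chromosomes,
markers with a low call rate (default < 0.95), markers with minor allele
frequency below a threshold (default < 0.02), then markers in high linkage
disequilibrium (greedy pruning at squared dosage correlation >= 0.2 by
default, keeping the marker with less missing data of any correlated pair).
Remaining missing genotypes are imputed per marker.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: Chromosome labels treated as sex chromosomes by default.
SEX_CHROM_LABELS = frozenset({"X", "Y", "XY", "23", "24", "25"})


@dataclass
class QCReport:
    """Per-stage marker counts of the QC pipeline."""

    n_input_snps: int
    n_removed_sex_chrom: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_ld: int
    n_retained: int
    thresholds_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = (self.n_removed_sex_chrom, self.n_removed_callrate,
                  self.n_removed_maf, self.n_removed_ld, self.n_retained)
        if any(c < 0 for c in counts):
            raise ValueError("negative count in QC report")
        if sum(counts) != self.n_input_snps:
            raise ValueError("QC counts do not sum to the input marker count")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "QCReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def minor_allele_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Per-marker MAF from non-missing dosages: min(p, 1-p), p = mean/2."""
    n_obs = (~np.isnan(genotypes)).sum(axis=0)
    sums = np.nansum(genotypes, axis=0)
    p = sums / np.maximum(2 * n_obs, 1)   # all-missing marker -> p = 0
    return np.minimum(p, 1.0 - p)


def filter_markers(genotypes: np.ndarray, snp_chroms: np.ndarray,
                   callrate_min: float = 0.95, maf_min: float = 0.02,
                   sex_labels: frozenset[str] | set[str] = SEX_CHROM_LABELS,
                   ) -> tuple[np.ndarray, np.ndarray, QCReport]:
    """Stagewise marker filter: sex chromosomes, call rate, then MAF.

    Returns (filtered matrix, retained column indices, report).  A marker
    with all calls missing has call rate 0 and is removed at the call-rate
    stage.  The LD count in the report is 0; :func:`ld_prune` is a separate
    stage (see :func:`run_qc`).
    """
    if not (0 <= callrate_min <= 1 and 0 <= maf_min <= 1):
        raise ValueError("callrate_min and maf_min must be in [0,1]")
    genotypes = np.asarray(genotypes, dtype=float)
    snp_chroms = np.asarray(snp_chroms, dtype=str)
    p = genotypes.shape[1]
    alive = np.ones(p, dtype=bool)

    is_sex = np.isin(snp_chroms, list(sex_labels))
    n_sex = int(is_sex.sum())
    alive &= ~is_sex

    n_obs = (~np.isnan(genotypes)).sum(axis=0)
    callrate = n_obs / max(genotypes.shape[0], 1)
    low_call = alive & ((callrate < callrate_min) | (n_obs == 0))
    n_call = int(low_call.sum())
    alive &= ~low_call

    maf = minor_allele_frequency(genotypes)
    low_maf = alive & (maf < maf_min)
    n_maf = int(low_maf.sum())
    alive &= ~low_maf

    kept = np.flatnonzero(alive)
    report = QCReport(
        n_input_snps=p,
        n_removed_sex_chrom=n_sex,
        n_removed_callrate=n_call,
        n_removed_maf=n_maf,
        n_removed_ld=0,
        n_retained=len(kept),
        thresholds_used={"callrate_min": callrate_min, "maf_min": maf_min,
                         "ld_r2_max": None},
    )
    return genotypes[:, kept], kept, report


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on pairwise-complete observations; returns 0 when fewer than
    two complete pairs exist or either vector is constant on them (no
    evidence of LD).
    """
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        return 0.0
    xa, ya = x[mask], y[mask]
    sx, sy = xa.std(), ya.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xa - xa.mean()) * (ya - ya.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(genotypes: np.ndarray, r2_max: float = 0.2,
             window: int | None = None) -> np.ndarray:
    """Greedy LD pruning; returns sorted retained column indices.

    Markers are visited in order of increasing missingness (ties broken by
    input order, so of two duplicated markers the less-missing one wins).
    A marker is retained iff its r-squared with every already retained
    marker within ``window`` columns (all columns when ``window`` is None)
    is below ``r2_max``.  Zero-variance markers are dropped with a warning.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    genotypes = np.asarray(genotypes, dtype=float)
    p = genotypes.shape[1]
    miss = np.isnan(genotypes).mean(axis=0)
    order = np.argsort(miss, kind="stable")
    retained: list[int] = []
    for j in order:
        col = genotypes[:, j]
        obs = col[~np.isnan(col)]
        if len(obs) == 0 or obs.std() == 0:
            log.warning("dropping zero-variance marker at column %d", j)
            continue
        keep = True
        for m in retained:
            if window is not None and abs(int(j) - m) > window:
                continue
            if pairwise_r2(col, genotypes[:, m]) >= r2_max:
                keep = False
                break
        if keep:
            retained.append(int(j))
    return np.sort(np.array(retained, dtype=int))


def impute_missing(genotypes: np.ndarray, strategy: str = "mode",
                   seed: int = 0, n_neighbors: int = 5,
                   n_estimators: int = 50) -> np.ndarray:
    """Replace missing dosages; never alters observed cells.

    Strategies: ``mode`` (most frequent dosage per marker, ties to the
    lower dosage), ``mean_rounded`` (per-marker mean rounded to the nearest
    of {0,1,2}) and ``forest`` (per-marker random-forest classifier trained
    on the most correlated neighbouring markers).
    """
    genotypes = np.asarray(genotypes, dtype=float)
    missing = np.isnan(genotypes)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValueError(
            f"marker column {j} has no observed calls; apply call-rate "
            "filtering before imputation"
        )
    out = genotypes.copy()
    if not missing.any():
        return out

    if strategy == "mode":
        for j in np.flatnonzero(missing.any(axis=0)):
            obs = genotypes[~missing[:, j], j].astype(int)
            counts = np.bincount(obs, minlength=3)
            out[missing[:, j], j] = float(np.argmax(counts))
    elif strategy == "mean_rounded":
        means = np.nanmean(genotypes, axis=0)
        fill = np.clip(np.rint(means), 0, 2)
        for j in np.flatnonzero(missing.any(axis=0)):
            out[missing[:, j], j] = fill[j]
    elif strategy == "forest":
        out = _impute_forest(genotypes, missing, seed, n_neighbors,
                             n_estimators)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    assert not np.isnan(out).any()
    return out


def _impute_forest(genotypes: np.ndarray, missing: np.ndarray, seed: int,
                   n_neighbors: int, n_estimators: int) -> np.ndarray:
    """Per-marker random-forest imputation on correlated neighbours."""
    from sklearn.ensemble import RandomForestClassifier

    base = impute_missing(genotypes, strategy="mode")
    out = genotypes.copy()
    centered = base - base.mean(axis=0)
    sd = centered.std(axis=0)
    for j in np.flatnonzero(missing.any(axis=0)):
        if sd[j] == 0:
            out[missing[:, j], j] = base[missing[:, j], j]
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (centered.T @ centered[:, j]) / (
                len(base) * sd * max(sd[j], 1e-12))
        corr[j] = 0.0
        corr[sd == 0] = 0.0
        nb = np.argsort(-np.abs(corr), kind="stable")[:n_neighbors]
        nb = nb[np.abs(corr[nb]) > 0]
        if len(nb) == 0:
            out[missing[:, j], j] = base[missing[:, j], j]
            continue
        train = ~missing[:, j]
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=seed)
        clf.fit(base[train][:, nb], genotypes[train, j].astype(int))
        out[missing[:, j], j] = clf.predict(
            base[missing[:, j]][:, nb]).astype(float)
    return out


def run_qc(genotypes: np.ndarray, snp_chroms: np.ndarray,
           callrate_min: float = 0.95, maf_min: float = 0.02,
           ld_r2_max: float = 0.2, ld_window: int | None = None,
           impute_strategy: str = "mode", seed: int = 0,
           force_include: np.ndarray | None = None,
           ) -> tuple[np.ndarray, np.ndarray, QCReport]:
    """Full QC pipeline: filter -> LD prune -> impute.

    ``force_include`` is a list of original column indices re-added after
    pruning (e.g. markers significant in a previous prognostic study),
    provided they survived the filtering stages.  Returns the imputed
    matrix, retained original column indices, and the complete report.
    """
    filtered, kept, rep = filter_markers(genotypes, snp_chroms,
                                         callrate_min, maf_min)
    pruned_local = ld_prune(filtered, r2_max=ld_r2_max, window=ld_window)
    keep_local = set(pruned_local.tolist())
    if force_include is not None:
        pos = {orig: i for i, orig in enumerate(kept)}
        keep_local |= {pos[j] for j in force_include if j in pos}
    final_local = np.sort(np.array(sorted(keep_local), dtype=int))
    final = kept[final_local]
    report = QCReport(
        n_input_snps=rep.n_input_snps,
        n_removed_sex_chrom=rep.n_removed_sex_chrom,
        n_removed_callrate=rep.n_removed_callrate,
        n_removed_maf=rep.n_removed_maf,
        n_removed_ld=rep.n_retained - len(final),
        n_retained=len(final),
        thresholds_used={"callrate_min": callrate_min, "maf_min": maf_min,
                         "ld_r2_max": ld_r2_max},
    )
    imputed = impute_missing(filtered[:, final_local],
                             strategy=impute_strategy, seed=seed)
    return imputed, final, report
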