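"""Core containers and readers/writers for genotype and phenotype data.

Genotypes are additive dosages: the count (0, 1 or 2) of a designated effect
allele per patient and marker.  For PLINK ``.raw`` input the counted allele is
the one PLINK chose when exporting; for VCF input the ALT allele is counted.
Missing genotypes are represented by ``numpy.nan`` in a float matrix.

Phenotypes are a per-patient follow-up duration (``time``), an event
indicator (1 = the event of interest was observed, 0 = censored) and a matrix
of encoded clinico-pathological covariates.  Categorical covariates are
dummy-encoded at load time with the most frequent level as the reference;
the reference levels are recorded so the encoding can be reported alongside
any downstream estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

log = logging.getLogger(__name__)

#: Fixed leading columns of a PLINK .raw file, in order.
RAW_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass
class GenotypePart:
    """Genotype side of a cohort: patients x markers dosage matrix."""

    patient_ids: np.ndarray          # (N,) str
    snp_ids: list[str]               # length P
    snp_chroms: np.ndarray           # (P,) str, "0" when unknown
    dosages: np.ndarray              # (N, P) float, nan = missing
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=str)
        self.snp_chroms = np.asarray(self.snp_chroms, dtype=str)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length does not match dosage rows")
        if len(self.snp_ids) != p or len(self.snp_chroms) != p:
            raise ValueError("snp metadata length does not match dosage columns")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage {self.dosages[i, j]!r} at patient row {i}, "
                f"marker {self.snp_ids[j]!r} is not in {{0,1,2,missing}}"
            )


@dataclass
class PhenotypePart:
    """Phenotype side of a cohort: outcome and encoded covariates."""

    patient_ids: np.ndarray          # (N,) str
    time: np.ndarray                 # (N,) float, >= 0
    event: np.ndarray                # (N,) int in {0,1}
    covariates: np.ndarray           # (N, Q) float
    covariate_names: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)


@dataclass
class Cohort:
    """Aligned genotype + phenotype data for N patients.

    Row ``i`` of every per-patient container refers to ``patient_ids[i]``.
    """

    patient_ids: np.ndarray
    genotypes: np.ndarray            # (N, P) float dosages, nan = missing
    snp_ids: list[str]
    snp_chroms: np.ndarray
    covariates: np.ndarray           # (N, Q) float
    covariate_names: list[str]
    time: np.ndarray                 # (N,) float months (unit is opaque)
    event: np.ndarray                # (N,) int {0,1}

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=str)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.patient_ids)
        for name, arr in (("genotypes", self.genotypes),
                          ("covariates", self.covariates),
                          ("time", self.time), ("event", self.event)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has {arr.shape[0]} rows, expected {n}")
        if (self.time < 0).any():
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator outside {0,1}")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]

    @property
    def q(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row-subset of the cohort (e.g. one cross-validation fold)."""
        idx = np.asarray(idx)
        return Cohort(
            patient_ids=self.patient_ids[idx],
            genotypes=self.genotypes[idx],
            snp_ids=self.snp_ids,
            snp_chroms=self.snp_chroms,
            covariates=self.covariates[idx],
            covariate_names=self.covariate_names,
            time=self.time[idx],
            event=self.event[idx],
        )

    def select_markers(self, idx: np.ndarray) -> "Cohort":
        """Column-subset of the genotype matrix (e.g. after QC)."""
        idx = np.asarray(idx)
        return Cohort(
            patient_ids=self.patient_ids,
            genotypes=self.genotypes[:, idx],
            snp_ids=[self.snp_ids[j] for j in idx],
            snp_chroms=self.snp_chroms[idx],
            covariates=self.covariates,
            covariate_names=self.covariate_names,
            time=self.time,
            event=self.event,
        )


# ---------------------------------------------------------------------------
# PLINK .raw
# ---------------------------------------------------------------------------

def read_plink_raw(path: str | Path) -> GenotypePart:
    """Read a PLINK ``.raw`` additive-coded genotype export.

    The header must start with ``FID IID PAT MAT SEX PHENOTYPE``; every
    following column is a marker whose cells are in ``{0, 1, 2, NA}``.
    Column order is preserved.  Chromosome labels are not carried by the
    ``.raw`` format and are set to ``"0"`` (unknown).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < len(RAW_META_COLS):
        raise FormatError(
            f"header has {len(cols)} columns, expected at least "
            f"{len(RAW_META_COLS)} ({' '.join(RAW_META_COLS)})"
        )
    for k, expected in enumerate(RAW_META_COLS):
        if cols[k] != expected:
            raise FormatError(
                f"header column {k + 1} is {cols[k]!r}, expected {expected!r}"
            )
    snp_cols = cols[len(RAW_META_COLS):]
    n = len(df)
    dosages = np.full((n, len(snp_cols)), np.nan)
    if snp_cols:
        raw = df[snp_cols].to_numpy(dtype=str)
        is_na = raw == "NA"
        valid = is_na | np.isin(raw, ("0", "1", "2"))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"dosage {raw[i, j]!r} at row {i + 1} (patient "
                f"{df['IID'].iloc[i]!r}), column {snp_cols[j]!r} is not in "
                "{0,1,2,NA}"
            )
        num = np.where(is_na, "nan", raw).astype(float)
        dosages = num
    return GenotypePart(
        patient_ids=df["IID"].to_numpy(dtype=str),
        snp_ids=snp_cols,
        snp_chroms=np.full(len(snp_cols), "0", dtype=object),
        dosages=dosages,
    )


def write_plink_raw(part: GenotypePart | Cohort, path: str | Path,
                    phenotype: np.ndarray | None = None) -> None:
    """Write dosages as a PLINK ``.raw`` file (``NA`` for missing)."""
    ids = part.patient_ids
    dosages = part.dosages if isinstance(part, GenotypePart) else part.genotypes
    snp_ids = part.snp_ids
    pheno = np.full(len(ids), -9) if phenotype is None else phenotype
    with open(path, "w") as fh:
        fh.write(" ".join(RAW_META_COLS))
        if snp_ids:
            fh.write(" " + " ".join(snp_ids))
        fh.write("\n")
        for i, pid in enumerate(ids):
            cells = [pid, pid, "0", "0", "0", str(pheno[i])]
            for x in dosages[i]:
                cells.append("NA" if np.isnan(x) else str(int(x)))
            fh.write(" ".join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path: str | Path) -> GenotypePart:
    """Read GT-based dosages from a VCF.

    Biallelic records are converted with the ALT allele counted
    (0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing).  Multiallelic
    records are skipped with a warning and counted in
    ``n_skipped_multiallelic``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    has_gt = any(
        h["HeaderType"] == "FORMAT" and h.info().get("ID") == "GT"
        for h in vcf.header_iter()
    )
    if not has_gt:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    samples = np.asarray(vcf.samples, dtype=str)
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    chroms: list[str] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            log.warning("skipping multiallelic record %s:%s", var.CHROM, var.POS)
            continue
        gt = var.gt_types.astype(float)
        gt[gt == 3] = np.nan
        cols.append(gt)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
    if cols:
        dosages = np.column_stack(cols)
    else:
        dosages = np.empty((len(samples), 0))
    return GenotypePart(
        patient_ids=samples,
        snp_ids=snp_ids,
        snp_chroms=np.asarray(chroms, dtype=object),
        dosages=dosages,
        n_skipped_multiallelic=skipped,
    )


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, time_col: str, event_col: str,
                    covariate_cols: list[str] | None = None,
                    id_col: str = "IID") -> PhenotypePart:
    """Read a delimited phenotype table (CSV or TSV, one row per patient).

    Categorical covariate columns are dummy-encoded with the most frequent
    level as the reference (recorded in ``reference_levels``); numeric
    columns pass through unchanged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (id_col, time_col, event_col, *(covariate_cols or [])):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    if (time < 0).any():
        bad = int(np.argwhere(time < 0)[0, 0])
        raise ValueError(f"negative follow-up time at row {bad + 1}")
    event_raw = pd.to_numeric(df[event_col], errors="raise").to_numpy()
    if not np.isin(event_raw, (0, 1)).all():
        bad = int(np.argwhere(~np.isin(event_raw, (0, 1)))[0, 0])
        raise ValueError(
            f"event indicator {event_raw[bad]!r} at row {bad + 1} outside {{0,1}}"
        )
    blocks: list[np.ndarray] = []
    names: list[str] = []
    refs: dict[str, str] = {}
    for col in covariate_cols or []:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            counts = s.astype(str).value_counts()
            ref = sorted(counts.index[counts == counts.max()])[0]
            refs[col] = ref
            for level in sorted(set(s.astype(str)) - {ref}):
                blocks.append((s.astype(str) == level).to_numpy(float)[:, None])
                names.append(f"{col}[{level}]")
    cov = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return PhenotypePart(
        patient_ids=df[id_col].to_numpy(dtype=str),
        time=time,
        event=event_raw.astype(int),
        covariates=cov,
        covariate_names=names,
        reference_levels=refs,
    )


def assemble_cohort(geno: GenotypePart, pheno: PhenotypePart) -> Cohort:
    """Join genotype and phenotype parts by patient id (order-independent).

    The genotype file's patient order is kept.  Any id present in one source
    but not the other raises :class:`AlignmentError` listing the unmatched
    ids.
    """
    gset, pset = set(geno.patient_ids), set(pheno.patient_ids)
    if gset != pset:
        missing = sorted((gset - pset) | (pset - gset))
        raise AlignmentError(f"unmatched patient ids: {missing}")
    pos = {pid: i for i, pid in enumerate(pheno.patient_ids)}
    order = np.array([pos[pid] for pid in geno.patient_ids])
    return Cohort(
        patient_ids=geno.patient_ids,
        genotypes=geno.dosages,
        snp_ids=geno.snp_ids,
        snp_chroms=geno.snp_chroms,
        covariates=pheno.covariates[order],
        covariate_names=pheno.covariate_names,
        time=pheno.time[order],
        event=pheno.event[order],
    )
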