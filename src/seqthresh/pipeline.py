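"""End-to-end pipeline: QC -> fit -> evaluate -> report.

Driven by a :class:`RunConfig` (YAML on disk).  Every run writes a machine
manifest with the package version, a hash of the resolved configuration and
the seed, so identical configurations reproduce identical numeric outputs.
Stages can be resumed from intermediates when the manifest hash matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import crossvalidate, decompose_cpp_prediction, \
    heritability, summary_table
from .intervals import IntervalGrid, build_grid_from_survival
from .io import assemble_cohort, read_phenotypes, read_plink_raw, \
    read_vcf_genotypes
from .qc import run_qc
from .samplers import MODELS, SamplerConfig, fit

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    genotypes: str
    phenotypes: str
    outdir: str
    time_col: str = "time"
    event_col: str = "event"
    id_col: str = "IID"
    covariate_cols: list[str] = field(default_factory=list)
    n_intervals: int | None = None
    boundaries: list[float] | None = None
    models: list[str] = field(default_factory=lambda: list(MODELS))
    qc: dict = field(default_factory=dict)       # kwargs of run_qc
    sampler: dict = field(default_factory=dict)  # kwargs of SamplerConfig
    n_folds: int = 10
    decompose: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        return cls(**obj)

    def validate(self) -> None:
        for p in (self.genotypes, self.phenotypes):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if (self.n_intervals is None) == (self.boundaries is None):
            raise ValueError("give exactly one of n_intervals and boundaries")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort(cfg: RunConfig):
    if cfg.genotypes.endswith(".vcf") or cfg.genotypes.endswith(".vcf.gz"):
        geno = read_vcf_genotypes(cfg.genotypes)
    else:
        geno = read_plink_raw(cfg.genotypes)
    pheno = read_phenotypes(cfg.phenotypes, cfg.time_col, cfg.event_col,
                            cfg.covariate_cols, id_col=cfg.id_col)
    return assemble_cohort(geno, pheno)


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the manifest dict.

    Artifacts written to ``cfg.outdir``: ``qc_report.json``,
    ``fit_<model>.json``, ``eval_<model>.json``, ``summary.csv``,
    ``summary.txt`` and ``manifest.json``.  Any stage error surfaces as an
    exception naming the stage; with ``resume=True`` stages whose outputs
    exist under a matching manifest hash are skipped.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = cfg.config_hash()
    prior = None
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            prior = json.load(fh)
        if prior.get("config_hash") != chash:
            log.warning("existing outputs come from a different config; "
                        "treating them as stale")
            prior = None

    manifest = {"package": "seqthresh", "version": __version__,
                "config_hash": chash, "seed": cfg.seed, "stages": {}}

    def _stage(name):
        def deco(fn):
            t0 = _time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "seconds": round(_time.perf_counter() - t0, 3)}
            return out
        return deco

    cohort = _stage("load")(lambda: _load_cohort(cfg))

    needs_snp = any(m in ("snp", "cpp_snp") for m in cfg.models)
    if needs_snp:
        def _qc():
            qc_path = outdir / "qc_report.json"
            imputed, kept, report = run_qc(
                cohort.genotypes, cohort.snp_chroms, seed=cfg.seed, **cfg.qc)
            report.to_json(qc_path)
            c = cohort.select_markers(kept)
            c.genotypes = imputed
            return c
        cohort = _stage("qc")(_qc)

    def _grid():
        if cfg.boundaries is not None:
            return IntervalGrid(np.array([*map(float, cfg.boundaries),
                                          np.inf]))
        return build_grid_from_survival(cohort.time, cohort.event,
                                        cfg.n_intervals)
    grid = _stage("grid")(_grid)

    sampler = SamplerConfig(seed=cfg.seed, **cfg.sampler)
    fits, reports = {}, []
    for model in cfg.models:
        fit_path = outdir / f"fit_{model}.json"
        eval_path = outdir / f"eval_{model}.json"

        def _fit(model=model, fit_path=fit_path):
            if prior is not None and fit_path.exists():
                from .samplers import FitResult
                log.info("resuming: reusing %s", fit_path)
                return FitResult.from_json(fit_path)
            res = fit(cohort, grid, model, sampler)
            res.to_json(fit_path)
            return res
        fits[model] = _stage(f"fit_{model}")(_fit)

        def _eval(model=model, eval_path=eval_path):
            rep = crossvalidate(cohort, grid, model, n_folds=cfg.n_folds,
                                config=sampler, seed=cfg.seed)
            rep.to_json(eval_path)
            return rep
        reports.append(_stage(f"eval_{model}")(_eval))

    if cfg.decompose and "cpp" in fits and needs_snp:
        r2 = _stage("decompose")(lambda: decompose_cpp_prediction(
            cohort, grid, fits["cpp"], sampler, n_folds=cfg.n_folds,
            seed=cfg.seed))
        manifest["decomposition_r2"] = r2

    table = summary_table(reports)
    table.to_csv(outdir / "summary.csv", index=False)
    lines = ["model  AUC(sd)  R2_probit(sd)"]
    for rep in reports:
        lines.append(f"{rep.model_label:8s} {rep.auc_mean:.3f} "
                     f"({rep.auc_sd:.3f})  {rep.r2_mean:.4f} "
                     f"({rep.r2_sd:.4f})")
        if rep.model_label == "snp":
            lines.append(f"  heritability estimate: "
                         f"{heritability(rep):.4f}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
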