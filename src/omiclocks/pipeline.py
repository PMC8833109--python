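"""End-to-end pipeline: simulate -> QC -> clocks -> OCAA -> overlap -> associations.

Stages communicate only through files in a run directory, every stage's
outputs are digested into a run manifest, and a stage is skipped on rerun
when all of its outputs already exist - so a partially deleted run
recomputes only what is missing, and identical config + seed reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (DEFAULT_EXCLUSIONS, POOLED_DISEASE_DIVISOR,
                           apply_screening, associate_ocaa_disease,
                           associate_ocaa_risk_factor, enrichment_summary,
                           finalize_fdr, is_excluded, ivw_by_clock,
                           results_table, screen_chronage_disease,
                           screen_chronage_risk_factor,
                           sex_stratified_consistency, standardise_outcome)
from .clocks import (ClockModel, build_mega_matrix, clock_age_table,
                     mega_selection_shares, pc_clock, predict_age,
                     split_cohort, stability_select, train_clock)
from .config import SimulationConfig, default_config
from .containers import OmicsMatrix
from .errors import ConfigError, DataError
from .overlap import (ocaa_correlation_matrix, overlap_matrix,
                      partition_variance, pairwise_overlap_table)
from .preprocess import QcConfig, qc_pipeline
from .simulate import read_study, simulate_cohort, union_disease, write_study
from .tables import file_digest, read_json, read_table, write_json, write_table


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = None
    qc: QcConfig = field(default_factory=QcConfig)
    split_fraction: float = 0.75
    alpha: float | str = 0.5
    folds: int = 10
    n_lambdas: int = 50
    stability_iterations: int = 100
    stability_threshold: float = 0.95
    pc_components: list = field(default_factory=lambda: [3, 5])
    fdr_q: float = 0.10
    min_events: int = 5
    pooled_divisor: float = POOLED_DISEASE_DIVISOR
    exclusions: list = field(default_factory=lambda: list(DEFAULT_EXCLUSIONS))

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = default_config(seed=self.seed)

    def validate(self):
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must be in (0, 1)")
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must be in (0, 1)")
        self.simulation.validate()
        self.qc.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QcConfig(**d["qc"])
        if "exclusions" in d:
            d["exclusions"] = [tuple(e) for e in d["exclusions"]]
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(f"bad pipeline config: {e}") from e

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                loaded = yaml.safe_load(fh)
        except (OSError, yaml.YAMLError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        return cls.from_dict(loaded or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)   # {name, skipped, outputs: {path: digest}}

    def record(self, name: str, outputs, skipped: bool) -> None:
        self.stages.append({
            "name": name, "skipped": skipped,
            "outputs": {str(Path(p).name): file_digest(p) for p in outputs}})

    def to_dict(self) -> dict:
        return asdict(self)


# ---- stage implementations ----------------------------------------------

def _stage_simulate(cfg: PipelineConfig, run: Path):
    study = simulate_cohort(cfg.simulation)
    return [str(p) for p in write_study(study, run / "data")]


def _stage_preprocess(cfg: PipelineConfig, run: Path):
    study = read_study(run / "data")
    out = run / "corrected"
    out.mkdir(exist_ok=True)
    paths, reports = [], []
    for m in study.omics:
        corrected, report = qc_pipeline(m, cfg.qc)
        p = out / f"{m.assay_name}.corrected.tsv"
        write_table(corrected.data, p)
        paths.append(str(p))
        reports.append(report)
    p = out / "qc_report.json"
    write_json(reports, p)
    paths.append(str(p))
    return paths


def _load_corrected(cfg: PipelineConfig, run: Path):
    study = read_study(run / "data")
    mats = []
    for spec in cfg.simulation.assays:
        data = read_table(run / "corrected" / f"{spec.name}.corrected.tsv",
                          index_col="individual_id")
        covs = read_table(run / "data" / f"{spec.name}.covariates.tsv",
                          index_col="individual_id")
        mats.append(OmicsMatrix(spec.name, data, covs.loc[data.index]))
    return study, mats


def _stage_train(cfg: PipelineConfig, run: Path):
    study, mats = _load_corrected(cfg, run)
    chron_age = study.cohort["chron_age"]
    complete = set(study.cohort.index)
    for m in mats:
        complete &= set(m.complete_ids())
    train_ids, test_ids = split_cohort(
        study.cohort.index, fraction=cfg.split_fraction,
        complete_ids=sorted(complete), seed=cfg.seed)
    out = run / "clocks"
    out.mkdir(exist_ok=True)
    paths = []

    def _save(model):
        p = out / f"{model.assay_name}.clock.json"
        model.to_json(p)
        paths.append(str(p))

    summary_rows = []
    for m in mats:
        model = train_clock(m, chron_age, train_ids, test_ids,
                            alpha=cfg.alpha, folds=cfg.folds,
                            n_lambdas=cfg.n_lambdas, seed=cfg.seed)
        _save(model)
        summary_rows.append({
            "clock_name": m.assay_name, "n_individuals": m.n_individuals,
            "n_available": m.n_features, "n_selected": model.n_selected,
            "train_r": model.train_r, "test_r": model.test_r})
        try:
            _, core = stability_select(
                m, chron_age, iterations=cfg.stability_iterations,
                threshold=cfg.stability_threshold,
                fraction=cfg.split_fraction, alpha=cfg.alpha,
                folds=cfg.folds, n_lambdas=cfg.n_lambdas, seed=cfg.seed,
                final_split=(train_ids, test_ids))
            _save(core)
            summary_rows.append({
                "clock_name": core.assay_name,
                "n_individuals": m.n_individuals,
                "n_available": len(core.feature_stats) or core.n_selected,
                "n_selected": core.n_selected,
                "train_r": core.train_r, "test_r": core.test_r})
        except DataError as e:
            warnings.warn(f"core clock skipped: {e}")
        for k in cfg.pc_components:
            try:
                model = pc_clock(m, k, chron_age, (train_ids, test_ids),
                                 seed=cfg.seed, alpha=cfg.alpha,
                                 folds=cfg.folds, n_lambdas=cfg.n_lambdas)
            except DataError as e:
                warnings.warn(f"PC clock skipped: {e}")
                continue
            _save(model)
            summary_rows.append({
                "clock_name": model.assay_name,
                "n_individuals": m.n_individuals, "n_available": k,
                "n_selected": model.n_selected,
                "train_r": model.train_r, "test_r": model.test_r})

    mega = build_mega_matrix(mats)
    model = train_clock(mega, chron_age, train_ids, test_ids,
                        alpha=cfg.alpha, folds=cfg.folds,
                        n_lambdas=cfg.n_lambdas, seed=cfg.seed)
    _save(model)
    summary_rows.append({
        "clock_name": "mega", "n_individuals": mega.n_individuals,
        "n_available": mega.n_features, "n_selected": model.n_selected,
        "train_r": model.train_r, "test_r": model.test_r})
    p = out / "mega_selection_shares.json"
    write_json(mega_selection_shares(model), p)
    paths.append(str(p))

    p = out / "training_summary.tsv"
    write_table(pd.DataFrame(summary_rows), p, index=False)
    paths.append(str(p))
    p = out / "split.json"
    write_json({"train_ids": train_ids, "test_ids": test_ids}, p)
    paths.append(str(p))
    return paths


def _load_clocks(run: Path):
    return [ClockModel.from_json(p)
            for p in sorted((run / "clocks").glob("*.clock.json"))]


def _matrix_for(model: ClockModel, mats, mega_cache: dict) -> OmicsMatrix:
    if model.assay_name == "mega":
        if "mega" not in mega_cache:
            mega_cache["mega"] = build_mega_matrix(mats)
        return mega_cache["mega"]
    base = model.assay_name.split("_pc")[0].removesuffix("_core")
    for m in mats:
        if m.assay_name == base:
            return m
    raise DataError(f"no corrected matrix found for clock {model.assay_name}; "
                    "run the preprocess stage first")


def _stage_predict(cfg: PipelineConfig, run: Path):
    study, mats = _load_corrected(cfg, run)
    chron_age = study.cohort["chron_age"]
    split = read_json(run / "clocks" / "split.json")
    tables, mega_cache = [], {}
    for model in _load_clocks(run):
        matrix = _matrix_for(model, mats, mega_cache)
        oca = predict_age(model, matrix)
        tab = clock_age_table(model.assay_name, oca, chron_age,
                              eval_ids=split["test_ids"])
        tables.append(tab.loc[tab.index.intersection(
            pd.Index(split["test_ids"]))])
    ages = pd.concat(tables)
    ages.index.name = "individual_id"
    p = run / "clock_ages.tsv"
    write_table(ages.reset_index(), p, index=False)
    return [str(p)]


def _ocaa_wide(run: Path, column: str = "ocaa"):
    ages = read_table(run / "clock_ages.tsv")
    return ages.pivot(index="individual_id", columns="clock_name",
                      values=column)


def _standard_clock_columns(cfg: PipelineConfig, columns) -> list:
    names = {a.name for a in cfg.simulation.assays}
    return [c for c in columns if c in names]


def _stage_overlap(cfg: PipelineConfig, run: Path):
    study = read_study(run / "data")
    chron_age = study.cohort["chron_age"]
    oca = _ocaa_wide(run, "oca")
    ocaa = _ocaa_wide(run, "ocaa")
    standard = _standard_clock_columns(cfg, oca.columns)
    paths = []

    part = partition_variance(chron_age, oca[standard])
    p = run / "partition.json"
    write_json(part.to_dict(), p)
    paths.append(str(p))

    pairs = pairwise_overlap_table(chron_age, oca[standard])
    p = run / "pairwise_overlap.tsv"
    write_table(pairs, p, index=False)
    paths.append(str(p))

    p = run / "excess_overlap_matrix.tsv"
    write_table(overlap_matrix(pairs), p)
    paths.append(str(p))

    corr = ocaa_correlation_matrix(ocaa[standard])
    p = run / "ocaa_correlation.tsv"
    write_table(corr, p)
    paths.append(str(p))
    return paths


def _stage_associate(cfg: PipelineConfig, run: Path):
    study = read_study(run / "data")
    cohort = study.cohort
    chron_age, sex = cohort["chron_age"], cohort["sex"]
    disease = pd.concat([study.disease, union_disease(study.disease)],
                        ignore_index=True)
    ocaa = _ocaa_wide(run, "ocaa")
    standard = _standard_clock_columns(cfg, ocaa.columns)

    rf_screens = [
        screen_chronage_risk_factor(
            standardise_outcome(study.risk_factors[c]), chron_age, sex)
        for c in study.risk_factors.columns]
    apply_screening(rf_screens, q=cfg.fdr_q, min_events=cfg.min_events)
    dz_screens = []
    for name in sorted(disease["disease_name"].unique()):
        try:
            dz_screens.append(screen_chronage_disease(disease, cohort, name))
        except DataError as e:
            warnings.warn(f"screen skipped: {e}")
    apply_screening(dz_screens, q=cfg.fdr_q, min_events=cfg.min_events)
    screens = rf_screens + dz_screens

    exclusions = [tuple(e) for e in cfg.exclusions]
    results = []
    for clock in standard:
        for s in rf_screens:
            if not s.eligible or is_excluded(clock, s.outcome_name,
                                             "risk_factor", exclusions):
                continue
            results.append(associate_ocaa_risk_factor(
                standardise_outcome(study.risk_factors[s.outcome_name]),
                ocaa[clock], chron_age, sex, s.chron_age_beta,
                clock_name=clock))
        for s in dz_screens:
            if not s.eligible or is_excluded(clock, s.outcome_name,
                                             "disease", exclusions):
                continue
            try:
                results.append(associate_ocaa_disease(
                    disease, cohort, ocaa[clock], s.outcome_name,
                    pooled_divisor=cfg.pooled_divisor, clock_name=clock))
            except DataError as e:
                warnings.warn(f"association skipped: {e}")
    finalize_fdr(results, q=cfg.fdr_q)

    paths = []
    p = run / "screen.tsv"
    write_table(pd.DataFrame([s.to_dict() for s in screens]), p, index=False)
    paths.append(str(p))
    p = run / "associations.tsv"
    write_table(results_table(results), p, index=False)
    paths.append(str(p))
    p = run / "ivw.tsv"
    write_table(ivw_by_clock(results), p, index=False)
    paths.append(str(p))
    summary = {
        "enrichment": enrichment_summary(results),
        "sex_consistency": sex_stratified_consistency(
            disease, cohort, ocaa, results, q=cfg.fdr_q,
            min_events=cfg.min_events),
        "fdr_families": sorted({r.outcome_type for r in results}),
    }
    p = run / "association_summary.json"
    write_json(summary, p)
    paths.append(str(p))
    return paths


def _stage_report(cfg: PipelineConfig, run: Path):
    paths = []
    out = run / "report"
    out.mkdir(exist_ok=True)

    summary = read_table(run / "clocks" / "training_summary.tsv")
    p = out / "clock_performance.tsv"
    write_table(summary, p, index=False)
    paths.append(str(p))

    for src in ("ocaa_correlation.tsv", "excess_overlap_matrix.tsv"):
        df = read_table(run / src, index_col=0)
        p = out / src
        write_table(df, p)
        paths.append(str(p))

    assoc = read_table(run / "associations.tsv")
    grid = assoc.pivot_table(index="clock_name", columns="outcome_name",
                             values="rescaled_beta")
    p = out / "association_grid.tsv"
    write_table(grid, p)
    paths.append(str(p))

    ivw = read_table(run / "ivw.tsv")
    summary_json = read_json(run / "association_summary.json")
    lines = ["# Run summary", ""]
    for otype, s in summary_json["enrichment"].items():
        lines.append(
            f"{otype}: {s['n_tests']} tests, "
            f"{100 * s['positive_fraction']:.1f}% positive effects, "
            f"{100 * s['nominal_fraction']:.1f}% nominally significant")
    lines.append("")
    for _, r in ivw.iterrows():
        lines.append(
            f"IVW {r['clock_name']} on {r['outcome_type']}: one year of OCAA "
            f"~ {r['ivw_rescaled_beta']:.3f} years of chronAge "
            f"(SE~{r['ivw_se_indicative']:.3f}, over {r['n_outcomes']:.0f} "
            "outcomes)")
    sc = summary_json["sex_consistency"]
    lines.append("")
    lines.append(
        f"sex sign consistency: {sc['n_assessed']} assessed, "
        f"consistency {sc['sign_consistency']}")
    p = out / "summary.txt"
    Path(p).write_text("\n".join(lines) + "\n")
    paths.append(str(p))
    return paths


STAGES = [
    ("simulate", _stage_simulate),
    ("preprocess", _stage_preprocess),
    ("train", _stage_train),
    ("predict", _stage_predict),
    ("overlap", _stage_overlap),
    ("associate", _stage_associate),
    ("report", _stage_report),
]

_STAGE_SENTINELS = {
    "simulate": ["data/cohort.tsv", "data/disease.tsv"],
    "preprocess": ["corrected/qc_report.json"],
    "train": ["clocks/split.json", "clocks/training_summary.tsv"],
    "predict": ["clock_ages.tsv"],
    "overlap": ["partition.json", "pairwise_overlap.tsv",
                "excess_overlap_matrix.tsv", "ocaa_correlation.tsv"],
    "associate": ["screen.tsv", "associations.tsv", "ivw.tsv",
                  "association_summary.json"],
    "report": ["report/summary.txt", "report/clock_performance.tsv"],
}


def run_pipeline(config, run_dir, force: bool = False,
                 stages=None) -> RunManifest:
    """Execute the pipeline end to end; returns the run manifest.

    ``config`` may be a :class:`PipelineConfig` or a path to a YAML file.
    A stage is skipped when all of its sentinel outputs already exist
    (unless ``force``), so deleting one stage's outputs recomputes only
    from that stage's files.
    """
    cfg = config if isinstance(config, PipelineConfig) \
        else PipelineConfig.from_yaml(config)
    cfg.validate()
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run / "pipeline_config.yaml")
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed,
                           version=__version__)
    wanted = set(stages) if stages else {name for name, _ in STAGES}
    for name, fn in STAGES:
        if name not in wanted:
            continue
        sentinels = [run / s for s in _STAGE_SENTINELS[name]]
        if not force and all(s.exists() for s in sentinels):
            manifest.record(name, [s for s in sentinels if s.exists()],
                            skipped=True)
            continue
        for s in sentinels:
            if not s.parent.exists():
                s.parent.mkdir(parents=True, exist_ok=True)
        try:
            outputs = fn(cfg, run)
        except FileNotFoundError as e:
            raise DataError(
                f"stage {name!r}: missing upstream artifact {e.filename}; "
                "run the earlier stages first") from e
        manifest.record(name, outputs, skipped=False)
    write_json(manifest.to_dict(), run / "run_manifest.json")
    return manifest
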