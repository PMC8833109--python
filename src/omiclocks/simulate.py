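"""Synthetic cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: chronological age (chronAge) uniform on the configured range, a
latent scalar biological-age acceleration ``delta`` per individual, omics
assays whose features load on standardised chronAge and delta with
assay-specific informativeness, risk factors linear in both, and
proportional-hazards disease processes with censoring at end of follow-up
and prevalent (pre-baseline) cases.

Randomness
----------
All randomness flows from ``SimulationConfig.seed`` through a documented
stream-splitting rule: the stream for stage ``s`` with within-stage index
``i`` is ``numpy.random.SeedSequence([seed, STAGE[s], i]])``. Stages can
therefore be regenerated independently and the same seed yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, DiseaseSpec
from .containers import OmicsMatrix
from .errors import ConfigError, DataError
from .tables import write_table, read_table

# Fixed stage indices of the stream-splitting rule. Never renumber.
STAGE = {
    "cohort": 0,
    "truth": 1,
    "assay": 2,
    "risk_factor": 3,
    "disease": 4,
    "bank": 5,
}


def stream(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """The random stream for one stage of the simulation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), STAGE[stage], int(index)]))


@dataclass
class SimulatedStudy:
    """Everything one simulated cohort produces.

    ``truth`` (the latent delta) exists for tests and oracles only; the
    analysis pipeline never reads it.
    """

    cohort: pd.DataFrame          # individual_id-indexed: chron_age, sex, smoking, assessment_time
    truth: pd.DataFrame           # individual_id-indexed: delta
    omics: list                   # list[OmicsMatrix]
    risk_factors: pd.DataFrame    # individual_id-indexed, one column per risk factor
    disease: pd.DataFrame         # long: individual_id, disease_name, event_time, event_flag, prevalent_flag, censor_time
    config: SimulationConfig


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full synthetic study from one configuration.

    chronAge is uniform on ``config.age_range`` (the real cohort's age
    distribution shape is unknown; uniform maximises spread for clock
    training). delta ~ Normal(0, sigma_delta^2). Feature j of assay k is
    ``a_kj * z(chronAge) + b_kj * z(delta) + batch + noise`` with loadings
    drawn once per feature from half-normal distributions.
    """
    config.validate()
    seed = config.seed
    n = config.n_individuals
    ids = pd.Index([f"I{i:05d}" for i in range(n)], name="individual_id")

    rng = stream(seed, "cohort")
    lo, hi = config.age_range
    chron_age = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)
    smoking = (rng.random(n) < config.smoking_rate).astype(int)
    cohort = pd.DataFrame(
        {"chron_age": chron_age, "sex": sex, "smoking": smoking,
         "assessment_time": 0.0},
        index=ids)

    rng = stream(seed, "truth")
    if config.sigma_delta > 0:
        delta = rng.normal(0.0, config.sigma_delta, size=n)
    else:
        delta = np.zeros(n)
    truth = pd.DataFrame({"delta": delta}, index=ids)

    z_age = _standardise(chron_age)
    z_delta = _standardise(delta)

    omics = []
    for k, spec in enumerate(config.assays):
        rng = stream(seed, "assay", k)
        # loadings drawn once per feature, half-normal
        a = np.abs(rng.normal(0.0, spec.age_loading_scale, spec.n_features)) \
            if spec.age_loading_scale > 0 else np.zeros(spec.n_features)
        b = np.abs(rng.normal(0.0, spec.delta_loading_scale, spec.n_features)) \
            if spec.delta_loading_scale > 0 else np.zeros(spec.n_features)
        batch = rng.integers(0, spec.batch_levels, size=n)
        batch_eff = (rng.normal(0.0, spec.batch_sd,
                                (spec.batch_levels, spec.n_features))
                     if spec.batch_sd > 0 else
                     np.zeros((spec.batch_levels, spec.n_features)))
        noise = rng.normal(0.0, spec.noise_sd, (n, spec.n_features))
        values = (np.outer(z_age, a) + np.outer(z_delta, b)
                  + batch_eff[batch, :] + noise)
        if spec.missing_rate > 0:
            mask = rng.random(values.shape) < spec.missing_rate
            values[mask] = np.nan
        measured = np.flatnonzero(rng.random(n) < spec.coverage) \
            if spec.coverage < 1 else np.arange(n)
        feats = [f"{spec.name}_f{j:04d}" for j in range(spec.n_features)]
        data = pd.DataFrame(values, index=ids, columns=feats).iloc[measured]
        covs = pd.DataFrame(
            {"sex": sex, "smoking": smoking, "batch": batch},
            index=ids).iloc[measured]
        omics.append(OmicsMatrix(spec.name, data, covs))

    rf = {}
    for k, spec in enumerate(config.risk_factors):
        rng = stream(seed, "risk_factor", k)
        rf[spec.name] = (spec.beta_age * chron_age
                         + spec.beta_delta * delta
                         + spec.beta_sex * sex
                         + spec.beta_smoking * smoking
                         + rng.normal(0.0, spec.noise_sd, n))
    risk_factors = pd.DataFrame(rf, index=ids)

    records = []
    for k, spec in enumerate(config.diseases):
        records.append(simulate_disease_times(
            cohort, truth, spec, config.followup_years,
            seed=np.random.SeedSequence([seed, STAGE["disease"], k])))
    disease = (pd.concat(records, ignore_index=True) if records
               else pd.DataFrame(columns=["individual_id", "disease_name",
                                          "event_time", "event_flag",
                                          "prevalent_flag", "censor_time"]))

    return SimulatedStudy(cohort, truth, omics, risk_factors, disease, config)


def simulate_disease_times(cohort: pd.DataFrame, truth: pd.DataFrame,
                           spec: DiseaseSpec, followup: float,
                           seed) -> pd.DataFrame:
    """Draw incident and prevalent event times for one disease.

    Event times are exponential with per-individual rate
    ``baseline_rate * exp(log_hr_age*age + log_hr_delta*delta + log_hr_sex*sex)``,
    censored at ``followup``. The same hazard is run backwards over the
    prevalence window: individuals whose backward draw lands inside the
    window get a prevalent row with a negative event time (these are the
    cases the association stage must exclude).

    Returns a long table with one incident row per individual and an
    additional prevalent row where applicable.
    """
    if followup <= 0:
        raise ConfigError("followup must be > 0")
    spec.validate()
    rng = np.random.default_rng(seed)
    age = cohort["chron_age"].to_numpy()
    sex = cohort["sex"].to_numpy()
    delta = truth.loc[cohort.index, "delta"].to_numpy()
    rate = spec.baseline_rate * np.exp(
        spec.log_hr_age * age + spec.log_hr_delta * delta
        + spec.log_hr_sex * sex)

    t_inc = rng.exponential(1.0 / rate)
    t_prev = rng.exponential(1.0 / rate)
    event = t_inc <= followup

    rows = {
        "individual_id": cohort.index,
        "disease_name": spec.name,
        "event_time": np.where(event, t_inc, np.nan),
        "event_flag": event,
        "prevalent_flag": False,
        "censor_time": followup,
    }
    out = pd.DataFrame(rows)
    prev = t_prev <= spec.prevalence_window_years
    if prev.any():
        prows = pd.DataFrame({
            "individual_id": cohort.index[prev],
            "disease_name": spec.name,
            "event_time": -t_prev[prev],
            "event_flag": True,
            "prevalent_flag": True,
            "censor_time": followup,
        })
        out = pd.concat([out, prows], ignore_index=True)
    return out


def incident_table(disease: pd.DataFrame, disease_name: str | None = None
                   ) -> pd.DataFrame:
    """Per-individual incident duration/event table with prevalent cases excluded.

    Mirrors record-linkage practice: any individual with a recorded event
    before baseline is dropped entirely for that disease grouping.
    """
    d = disease if disease_name is None else \
        disease[disease["disease_name"] == disease_name]
    if d.empty:
        raise DataError(f"no records for disease {disease_name!r}")
    prevalent = set(d.loc[d["prevalent_flag"], "individual_id"])
    inc = d[~d["prevalent_flag"] &
            ~d["individual_id"].isin(prevalent)].copy()
    inc["duration"] = np.where(inc["event_flag"],
                               inc["event_time"], inc["censor_time"])
    return inc.set_index("individual_id")[["duration", "event_flag"]]


def union_disease(disease: pd.DataFrame, name: str = "ALL") -> pd.DataFrame:
    """First event in any disease block, as an extra outcome grouping.

    An individual is prevalent for the union if prevalent for any block;
    the incident event is the earliest incident event across blocks.
    """
    g = disease.groupby("individual_id")
    rows = []
    for iid, sub in g:
        prev = sub["prevalent_flag"].any()
        inc = sub[~sub["prevalent_flag"]]
        ev = inc[inc["event_flag"]]
        censor = float(inc["censor_time"].min()) if len(inc) else float(
            sub["censor_time"].min())
        rows.append({
            "individual_id": iid, "disease_name": name,
            "event_time": float(ev["event_time"].min()) if len(ev) else np.nan,
            "event_flag": bool(len(ev)), "prevalent_flag": False,
            "censor_time": censor})
        if prev:
            first_prev = sub.loc[sub["prevalent_flag"], "event_time"].min()
            rows.append({
                "individual_id": iid, "disease_name": name,
                "event_time": float(first_prev), "event_flag": True,
                "prevalent_flag": True, "censor_time": censor})
    return pd.DataFrame(rows)


def simulate_latent_predictor_bank(n: int, p: int, seed=0):
    """A complete latent predictor bank for exact ISLSP experiments.

    Constructs ``p`` mutually orthogonal, mean-zero, equal-variance
    predictors whose sum equals standardised chronAge exactly (noise-free).
    Columns are built by orthonormalising a centred Gaussian matrix and
    rescaling, so empirical regressions of the target on any predictor
    subset have R^2 exactly |subset|/p, to machine precision - which is
    what makes the independent-sampling (ISLSP) null exactly computable.

    Returns
    -------
    (X, y)
        ``X``: DataFrame (n × p) of predictors ``z0000..``;
        ``y``: Series, the standardised chronAge target (row sums of X).
    """
    if p < 1:
        raise ConfigError("p must be >= 1")
    if n < p + 2:
        raise ConfigError("n must be at least p + 2 for an exact construction")
    rng = stream(seed, "bank") if isinstance(seed, (int, np.integer)) \
        else np.random.default_rng(seed)
    raw = rng.standard_normal((n, p))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    # columns of q are orthonormal and lie in the span of centred vectors,
    # hence mean-zero; rescale to sample variance 1/p
    x = q * np.sqrt((n - 1) / p)
    ids = pd.Index([f"I{i:05d}" for i in range(n)], name="individual_id")
    cols = [f"z{j:04d}" for j in range(p)]
    xdf = pd.DataFrame(x, index=ids, columns=cols)
    y = pd.Series(x.sum(axis=1), index=ids, name="z_chron_age")
    return xdf, y


# ---- on-disk layout -----------------------------------------------------

def write_study(study: SimulatedStudy, out_dir) -> list:
    """Write a study as the TSV dialect all stages share; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _w(df, name, index=True):
        p = out / name
        write_table(df, p, index=index)
        paths.append(p)

    _w(study.cohort, "cohort.tsv")
    _w(study.truth, "truth.tsv")
    for m in study.omics:
        _w(m.data, f"{m.assay_name}.features.tsv")
        _w(m.covariates, f"{m.assay_name}.covariates.tsv")
    _w(study.risk_factors, "riskfactors.tsv")
    _w(study.disease, "disease.tsv", index=False)
    study.config.to_yaml(out / "simulation_config.yaml")
    paths.append(out / "simulation_config.yaml")
    return paths


def read_study(in_dir) -> SimulatedStudy:
    src = Path(in_dir)
    config = SimulationConfig.from_yaml(src / "simulation_config.yaml")
    cohort = read_table(src / "cohort.tsv", index_col="individual_id")
    truth = read_table(src / "truth.tsv", index_col="individual_id")
    omics = []
    for spec in config.assays:
        data = read_table(src / f"{spec.name}.features.tsv",
                          index_col="individual_id")
        covs = read_table(src / f"{spec.name}.covariates.tsv",
                          index_col="individual_id")
        omics.append(OmicsMatrix(spec.name, data, covs))
    risk_factors = read_table(src / "riskfactors.tsv",
                              index_col="individual_id")
    disease = read_table(src / "disease.tsv")
    return SimulatedStudy(cohort, truth, omics, risk_factors, disease, config)
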