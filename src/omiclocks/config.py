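"""Study-design configuration for the synthetic cohort generator.

The generator emulates a deeply omics-profiled population cohort: one or
two thousand adults spanning ages 16-100, several omics assays whose
features load both on chronological age (chronAge) and on a latent
biological-age acceleration, age-linked risk factors, and linked
hospital-admission records with ~10 years of follow-up.

Defaults here ARE the study conditions: assay informativeness is chosen so
trained clocks span roughly the 0.2-0.97 range of clock-chronAge
correlations seen across real omics platforms, the latent acceleration has
a standard deviation of a few years, and disease hazards rise with age at
~0.05 log hazard units per year (a doubling of risk every ~14 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError


@dataclass
class AssaySpec:
    """Moment structure of one simulated omics assay.

    Each feature j is generated as

        x_ij = a_j * z(chronAge_i) + b_j * z(delta_i) + batch_i + e_ij

    with loadings a_j, b_j drawn once per feature from half-normal
    distributions with scales ``age_loading_scale`` / ``delta_loading_scale``,
    an additive batch shift (level assigned per individual) and iid Gaussian
    noise. ``coverage`` < 1 leaves some individuals unmeasured on the whole
    assay; ``missing_rate`` knocks out individual cells.
    """

    name: str
    n_features: int
    age_loading_scale: float = 1.0
    delta_loading_scale: float = 0.5
    noise_sd: float = 1.0
    batch_levels: int = 1
    batch_sd: float = 0.0
    coverage: float = 1.0
    missing_rate: float = 0.0

    def validate(self):
        if self.n_features < 1:
            raise ConfigError(f"assay {self.name}: n_features must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError(f"assay {self.name}: noise_sd must be > 0")
        if self.age_loading_scale < 0 or self.delta_loading_scale < 0:
            raise ConfigError(f"assay {self.name}: loading scales must be >= 0")
        if self.batch_levels < 1:
            raise ConfigError(f"assay {self.name}: batch_levels must be >= 1")
        if not 0 < self.coverage <= 1:
            raise ConfigError(f"assay {self.name}: coverage must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"assay {self.name}: missing_rate must be in [0, 1)")


@dataclass
class RiskFactorSpec:
    """A continuous health risk factor linear in age and latent acceleration.

    ``beta_age`` and ``beta_delta`` are in outcome units per year; the
    outcome is standardised downstream, so units are arbitrary.
    """

    name: str
    beta_age: float = 0.0
    beta_delta: float = 0.0
    beta_sex: float = 0.0
    beta_smoking: float = 0.0
    noise_sd: float = 1.0

    def validate(self):
        if self.noise_sd <= 0:
            raise ConfigError(f"risk factor {self.name}: noise_sd must be > 0")


@dataclass
class DiseaseSpec:
    """Proportional-hazards disease process.

    The hazard for individual i is

        baseline_rate * exp(log_hr_age * chronAge_i
                            + log_hr_delta * delta_i
                            + log_hr_sex * sex_i)

    constant over time (exponential event times). Events may also occur in
    the ``prevalence_window_years`` before the baseline assessment (the same
    hazard run backwards), producing prevalent cases that the association
    stage must exclude.
    """

    name: str
    baseline_rate: float = 1e-4
    log_hr_age: float = 0.0492
    log_hr_delta: float = 0.0
    log_hr_sex: float = 0.0
    prevalence_window_years: float = 10.0

    def validate(self):
        if self.baseline_rate <= 0:
            raise ConfigError(f"disease {self.name}: baseline_rate must be > 0")
        if self.prevalence_window_years < 0:
            raise ConfigError(
                f"disease {self.name}: prevalence_window_years must be >= 0")


@dataclass
class SimulationConfig:
    """Full design of one synthetic cohort."""

    n_individuals: int = 1000
    age_range: tuple = (16.0, 100.0)
    sigma_delta: float = 5.0
    assays: list = field(default_factory=list)
    risk_factors: list = field(default_factory=list)
    diseases: list = field(default_factory=list)
    followup_years: float = 10.0
    smoking_rate: float = 0.25
    seed: int = 0

    def validate(self):
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ConfigError("age_range must satisfy 0 <= min < max <= 120")
        if self.sigma_delta < 0:
            raise ConfigError("sigma_delta must be >= 0")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be > 0")
        if not self.assays:
            raise ConfigError("at least one assay must be configured")
        for a in self.assays:
            a.validate()
        for r in self.risk_factors:
            r.validate()
        for d in self.diseases:
            d.validate()

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        try:
            d["assays"] = [AssaySpec(**a) for a in d.get("assays", [])]
            d["risk_factors"] = [RiskFactorSpec(**r)
                                 for r in d.get("risk_factors", [])]
            d["diseases"] = [DiseaseSpec(**x) for x in d.get("diseases", [])]
            if "age_range" in d:
                d["age_range"] = tuple(d["age_range"])
            return cls(**d)
        except TypeError as e:
            raise ConfigError(f"bad simulation config: {e}") from e

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0, n_individuals: int = 1000) -> SimulationConfig:
    """The default study conditions.

    Four assays are graded in informativeness so that trained clocks span a
    wide range of clock-chronAge correlations: a CpG-panel-like assay (many
    strongly age-loaded features, low noise -> r near 0.95), a
    proteomics-like assay, a glycomics-like assay, and a weakly informative
    metabolomics-like assay (r in the 0.2-0.5 range). Seven risk factors
    mirror common clinical measures; four disease groups use ICD10-block-like
    labels with per-year log hazard ratios of chronAge near 0.05 and latent
    acceleration effects of 0-0.05.
    """
    assays = [
        AssaySpec("cpg_panel", n_features=60, age_loading_scale=0.55,
                  delta_loading_scale=0.15, noise_sd=1.0,
                  batch_levels=4, batch_sd=0.15, coverage=0.96,
                  missing_rate=0.0005),
        AssaySpec("proteomics", n_features=100, age_loading_scale=0.35,
                  delta_loading_scale=0.35, noise_sd=1.0,
                  batch_levels=6, batch_sd=0.2, coverage=0.94,
                  missing_rate=0.0005),
        AssaySpec("glycomics", n_features=30, age_loading_scale=0.25,
                  delta_loading_scale=0.3, noise_sd=1.0,
                  batch_levels=3, batch_sd=0.2, coverage=0.97,
                  missing_rate=0.0005),
        AssaySpec("metabolomics", n_features=60, age_loading_scale=0.08,
                  delta_loading_scale=0.25, noise_sd=1.2,
                  batch_levels=4, batch_sd=0.2, coverage=0.95,
                  missing_rate=0.0005),
    ]
    risk_factors = [
        RiskFactorSpec("bmi", beta_age=0.05, beta_delta=0.10, noise_sd=4.0),
        RiskFactorSpec("sbp", beta_age=0.45, beta_delta=0.35,
                       beta_sex=3.0, noise_sd=16.0),
        RiskFactorSpec("cortisol", beta_age=0.8, beta_delta=0.6, noise_sd=90.0),
        RiskFactorSpec("creatinine", beta_age=0.15, beta_delta=0.20,
                       beta_sex=9.0, noise_sd=12.0),
        RiskFactorSpec("crp", beta_age=0.02, beta_delta=0.08,
                       beta_smoking=0.8, noise_sd=2.5),
        RiskFactorSpec("fev1", beta_age=-0.03, beta_delta=-0.02,
                       beta_sex=0.6, beta_smoking=-0.3, noise_sd=0.5),
        RiskFactorSpec("cholesterol", beta_age=0.012, beta_delta=0.012,
                       noise_sd=1.0),
    ]
    diseases = [
        DiseaseSpec("C00-C97", baseline_rate=4e-4, log_hr_age=0.0492,
                    log_hr_delta=0.02, prevalence_window_years=10.0),
        DiseaseSpec("E10-E14", baseline_rate=3e-4, log_hr_age=0.0492,
                    log_hr_delta=0.05, prevalence_window_years=10.0),
        DiseaseSpec("I10-I15", baseline_rate=6e-4, log_hr_age=0.0492,
                    log_hr_delta=0.05, log_hr_sex=0.3,
                    prevalence_window_years=10.0),
        DiseaseSpec("J09-J18", baseline_rate=4e-4, log_hr_age=0.0492,
                    log_hr_delta=0.0, prevalence_window_years=10.0),
    ]
    return SimulationConfig(
        n_individuals=n_individuals,
        age_range=(16.0, 100.0),
        sigma_delta=5.0,
        assays=assays,
        risk_factors=risk_factors,
        diseases=diseases,
        followup_years=10.0,
        smoking_rate=0.25,
        seed=seed,
    )
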