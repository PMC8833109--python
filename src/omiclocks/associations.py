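"""OCAA associations with risk factors and incident disease.

The analysis follows a two-stage design. Outcomes are first screened for a
positive chronAge association (one-sided, Benjamini-Hochberg FDR < 10%
within the outcome family, and more than 5 incident cases for disease
blocks); only screened-eligible outcomes are ever tested against OCAA, to
restrict the burden of multiple testing.

Risk factors are standardised and fit by linear regression with chronAge
and sex as covariates; incident disease is fit by Cox proportional hazards
on time since assessment (Efron ties), with prevalent cases excluded
before fitting. OCAA effects are rescaled into per-year-of-chronAge units:
trait-by-trait for risk factors (dividing by that trait's chronAge beta
from the same adjusted model) and by a single pooled chronAge log hazard
(magnitude 0.0492 per year, a doubling of risk every ~14 years) for all
disease groups.

Estimates are additionally shrunk toward zero under a Normal(0, 1) prior
(posterior mean beta / (1 + se^2)) and aggregated per clock by inverse
variance weighting; because outcomes are correlated, IVW standard errors
are indicative only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .errors import DataError
from .simulate import incident_table

#: per-year chronAge log hazard pooled across disease groups, used as the
#: common rescaling divisor for disease OCAA effects (applied by magnitude:
#: eligible outcomes have risk rising with age).
POOLED_DISEASE_DIVISOR = 0.0492

#: outcome-exclusion defaults: clocks whose predictors overlap an outcome
#: are never tested against it. Keyed by (clock substring, outcome); the
#: special outcome "*" bans a clock from every risk factor. Editable via
#: the pipeline config; entries matching nothing are inert.
DEFAULT_EXCLUSIONS = (
    ("clinomics", "*"),
    ("nmr_metabolomics", "creatinine"),
    ("metaboage", "creatinine"),
    ("nmr_metabolomics", "cholesterol"),
    ("metaboage", "cholesterol"),
    ("ms_metabolomics", "cholesterol"),
    ("ms_complex_lipidomics", "cholesterol"),
    ("ms_fatty_acids", "cholesterol"),
)


@dataclass
class ScreenResult:
    """One outcome's chronAge screening fit."""

    outcome_name: str
    outcome_type: str             # "risk_factor" | "disease"
    chron_age_beta: float
    se: float
    p_one_sided: float
    n_used: int
    n_events: int | None = None
    fdr_pass: bool = False
    eligible: bool = False
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AssociationResult:
    """One OCAA-outcome association.

    ``beta`` is per year of OCAA: SD units of the outcome for risk
    factors, log hazard ratio for disease. ``rescaled_beta`` divides by
    the relevant chronAge effect, so 1 means a year of OCAA is as
    deleterious as a year of chronAge.
    """

    clock_name: str
    outcome_name: str
    outcome_type: str
    beta: float
    se: float
    p_one_sided: float
    rescaled_beta: float
    rescaled_se: float
    shrunk_beta: float
    n_used: int
    n_events: int | None = None
    fdr_pass: bool = False
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


# ---- elementary statistics ----------------------------------------------

def one_sided_p(beta: float, se: float) -> float:
    """Normal upper-tail probability of the Wald z; H1: effect increases risk."""
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(stats.norm.sf(beta / se))


def bh_fdr(p_values, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up pass flags for one family of p-values."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def shrink_beta(beta, se):
    """Posterior mean under a Normal(0, 1) prior: beta / (1 + se^2).

    Estimates with larger standard errors are pulled harder toward zero.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    out = beta / (1.0 + se ** 2)
    return float(out) if out.ndim == 0 else out


def ivw_mean(betas, ses):
    """Inverse-variance-weighted mean and its (indicative) standard error.

    The SE assumes independent estimates; correlated outcomes violate
    that, so downstream reporting flags it as indicative.
    """
    b = np.asarray(list(betas), float)
    s = np.asarray(list(ses), float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    if not ok.any():
        return float("nan"), float("nan")
    w = 1.0 / s[ok] ** 2
    return float((w * b[ok]).sum() / w.sum()), float(math.sqrt(1.0 / w.sum()))


def sex_difference_test(beta_m: float, se_m: float, beta_f: float,
                        se_f: float) -> float:
    """Two-sided normal p for a male-female difference in effect size."""
    denom = math.sqrt(se_m ** 2 + se_f ** 2)
    if denom == 0:
        return 1.0 if beta_m == beta_f else 0.0
    z = (beta_m - beta_f) / denom
    return float(2 * stats.norm.sf(abs(z)))


def hazard_doubling_years(log_hr: float) -> float:
    """Years of chronAge over which risk doubles: ln(2) / per-year log HR."""
    if log_hr <= 0:
        raise DataError("doubling horizon requires a positive log hazard")
    return math.log(2) / log_hr


# ---- model fits ---------------------------------------------------------

def _drop_constant(df: pd.DataFrame, covariates) -> list:
    """Constant covariates (e.g. sex within a single-sex stratum) carry no
    information and break the fits; drop them silently."""
    return [c for c in covariates if df[c].nunique() > 1]


def _ols(y: np.ndarray, X: pd.DataFrame):
    X = X[_drop_constant(X, X.columns)]
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return fit.params, fit.bse


def _cox(df: pd.DataFrame, covariates):
    """Cox partial-likelihood fit (Efron ties); returns (params, ses, ok)."""
    covariates = _drop_constant(df, covariates)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["duration", "event"] + list(covariates)],
                    duration_col="duration", event_col="event")
        return cph.params_, cph.standard_errors_, True
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        idx = pd.Index(covariates)
        return (pd.Series(np.nan, index=idx),
                pd.Series(np.nan, index=idx), False)


def standardise_outcome(x: pd.Series) -> pd.Series:
    obs = x.dropna()
    sd = obs.std(ddof=1)
    if sd == 0:
        raise DataError(f"outcome {x.name!r} is constant")
    return (x - obs.mean()) / sd


# ---- screening ----------------------------------------------------------

def screen_chronage_risk_factor(outcome: pd.Series, chron_age: pd.Series,
                                sex: pd.Series) -> ScreenResult:
    """chronAge effect on a standardised risk factor (linear, sex-adjusted)."""
    df = pd.concat([outcome.rename("y"), chron_age.rename("chron_age"),
                    sex.rename("sex")], axis=1, join="inner").dropna()
    params, bse = _ols(df["y"].to_numpy(), df[["chron_age", "sex"]])
    beta, se = float(params["chron_age"]), float(bse["chron_age"])
    return ScreenResult(outcome_name=str(outcome.name),
                        outcome_type="risk_factor", chron_age_beta=beta,
                        se=se, p_one_sided=one_sided_p(beta, se),
                        n_used=len(df))


def cox_frame(records: pd.DataFrame, cohort: pd.DataFrame,
              disease_name: str | None = None, extra: dict | None = None
              ) -> pd.DataFrame:
    """Incident-only duration/event frame merged with covariates.

    Prevalent cases (any event before baseline) are excluded entirely.
    """
    inc = incident_table(records, disease_name)
    df = inc.join(cohort[["chron_age", "sex"]], how="inner")
    for name, series in (extra or {}).items():
        df[name] = series
    df = df.dropna()
    df["event"] = df["event_flag"].astype(bool)
    return df.rename(columns={"event_flag": "_event_flag"})


def screen_chronage_disease(records: pd.DataFrame, cohort: pd.DataFrame,
                            disease_name: str | None = None) -> ScreenResult:
    """chronAge log hazard for one disease grouping (Cox, sex-adjusted)."""
    df = cox_frame(records, cohort, disease_name)
    name = disease_name or str(records["disease_name"].iloc[0])
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise DataError(f"{name}: only {n_events} incident events")
    params, bse, ok = _cox(df, ["chron_age", "sex"])
    beta, se = float(params["chron_age"]), float(bse["chron_age"])
    return ScreenResult(outcome_name=name, outcome_type="disease",
                        chron_age_beta=beta, se=se,
                        p_one_sided=one_sided_p(beta, se), n_used=len(df),
                        n_events=n_events, converged=ok)


def apply_screening(screens, q: float = 0.10, min_events: int = 5):
    """BH-FDR over one screening family; set eligibility flags in place.

    Eligible = positive chronAge effect, FDR pass, and (for diseases)
    more than ``min_events`` incident cases.
    """
    screens = list(screens)
    flags = bh_fdr([s.p_one_sided for s in screens], q=q)
    for s, f in zip(screens, flags):
        s.fdr_pass = bool(f)
        enough = (s.n_events is None) or (s.n_events > min_events)
        s.eligible = bool(f and s.chron_age_beta > 0 and enough
                          and s.converged)
    return screens


# ---- OCAA associations --------------------------------------------------

def associate_ocaa_risk_factor(outcome: pd.Series, ocaa: pd.Series,
                               chron_age: pd.Series, sex: pd.Series,
                               chron_age_beta: float,
                               clock_name: str = "clock",
                               smoking: pd.Series | None = None
                               ) -> AssociationResult:
    """OCAA effect on a standardised risk factor, chronAge- and sex-adjusted.

    ``rescaled_beta`` divides by the trait's own chronAge beta (the same
    adjusted model's coefficient), giving per-year-of-chronAge units.
    """
    parts = [outcome.rename("y"), ocaa.rename("ocaa"),
             chron_age.rename("chron_age"), sex.rename("sex")]
    covs = ["ocaa", "chron_age", "sex"]
    if smoking is not None:
        parts.append(smoking.rename("smoking"))
        covs.append("smoking")
    df = pd.concat(parts, axis=1, join="inner").dropna()
    params, bse = _ols(df["y"].to_numpy(), df[covs])
    beta, se = float(params["ocaa"]), float(bse["ocaa"])
    rescale = chron_age_beta if chron_age_beta not in (0, None) else np.nan
    return AssociationResult(
        clock_name=clock_name, outcome_name=str(outcome.name),
        outcome_type="risk_factor", beta=beta, se=se,
        p_one_sided=one_sided_p(beta, se),
        rescaled_beta=beta / rescale, rescaled_se=abs(se / rescale),
        shrunk_beta=shrink_beta(beta, se), n_used=len(df))


def associate_ocaa_disease(records: pd.DataFrame, cohort: pd.DataFrame,
                           ocaa: pd.Series, disease_name: str | None = None,
                           pooled_divisor: float = POOLED_DISEASE_DIVISOR,
                           clock_name: str = "clock",
                           smoking: pd.Series | None = None
                           ) -> AssociationResult:
    """OCAA log hazard for one disease grouping, chronAge- and sex-adjusted.

    Prevalent cases are excluded. ``rescaled_beta`` divides by the
    magnitude of the pooled per-year chronAge log hazard.
    """
    extra = {"ocaa": ocaa}
    covs = ["ocaa", "chron_age", "sex"]
    if smoking is not None:
        extra["smoking"] = smoking
        covs.append("smoking")
    df = cox_frame(records, cohort, disease_name, extra=extra)
    name = disease_name or str(records["disease_name"].iloc[0])
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise DataError(f"{name}: only {n_events} incident events")
    params, bse, ok = _cox(df, covs)
    beta, se = float(params["ocaa"]), float(bse["ocaa"])
    divisor = abs(pooled_divisor)
    return AssociationResult(
        clock_name=clock_name, outcome_name=name, outcome_type="disease",
        beta=beta, se=se, p_one_sided=one_sided_p(beta, se),
        rescaled_beta=beta / divisor, rescaled_se=abs(se / divisor),
        shrunk_beta=shrink_beta(beta, se), n_used=len(df),
        n_events=n_events, converged=ok)


def is_excluded(clock_name: str, outcome_name: str, outcome_type: str,
                exclusions=DEFAULT_EXCLUSIONS) -> bool:
    """Whether a clock-outcome pair is on the exclusion list (risk factors:
    the wildcard outcome '*' bans the clock from the whole family)."""
    c = clock_name.lower()
    o = outcome_name.lower()
    for clock_pat, outcome_pat in exclusions:
        if clock_pat.lower() in c:
            if outcome_pat == "*" and outcome_type == "risk_factor":
                return True
            if outcome_pat.lower() == o:
                return True
    return False


def finalize_fdr(results, q: float = 0.10):
    """BH-FDR within each outcome-type family of association results."""
    results = list(results)
    for otype in {r.outcome_type for r in results}:
        fam = [r for r in results if r.outcome_type == otype and r.converged]
        flags = bh_fdr([r.p_one_sided for r in fam], q=q)
        for r, f in zip(fam, flags):
            r.fdr_pass = bool(f)
    return results


def enrichment_summary(results) -> dict:
    """Fractions of positive and nominally significant (one-sided p < 0.05)
    effects, per outcome family."""
    out = {}
    for otype in ("risk_factor", "disease"):
        fam = [r for r in results if r.outcome_type == otype and r.converged]
        if not fam:
            continue
        out[otype] = {
            "n_tests": len(fam),
            "positive_fraction": float(np.mean([r.beta > 0 for r in fam])),
            "nominal_fraction": float(
                np.mean([r.p_one_sided < 0.05 for r in fam])),
        }
    return out


def ivw_by_clock(results) -> pd.DataFrame:
    """Per-clock IVW mean of rescaled effects, one row per outcome family.

    Non-converged fits are excluded with a logged reason. SEs are
    indicative (independence is violated across correlated outcomes).
    """
    rows = []
    keys = sorted({(r.clock_name, r.outcome_type) for r in results})
    for clock, otype in keys:
        fam = [r for r in results
               if r.clock_name == clock and r.outcome_type == otype]
        used = [r for r in fam if r.converged]
        for r in fam:
            if not r.converged:
                warnings.warn(f"IVW: dropping non-converged fit "
                              f"{r.clock_name}~{r.outcome_name}")
        mean, se = ivw_mean([r.rescaled_beta for r in used],
                            [r.rescaled_se for r in used])
        rows.append({"clock_name": clock, "outcome_type": otype,
                     "ivw_rescaled_beta": mean, "ivw_se_indicative": se,
                     "n_outcomes": len(used)})
    return pd.DataFrame(rows)


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---- sex-stratified consistency ----------------------------------------

def sex_stratified_consistency(disease_records: pd.DataFrame,
                               cohort: pd.DataFrame, ocaa_df: pd.DataFrame,
                               pooled_results, q: float = 0.10,
                               min_events: int = 5) -> dict:
    """Sign consistency of OCAA-disease effects across the sexes.

    Restricts to associations nominally significant (one-sided p < 0.05)
    in the pooled analysis, re-screens each disease within each sex under
    the same eligibility rule (positive chronAge effect, FDR within the
    per-sex family, > ``min_events`` cases), refits the OCAA model per sex
    for pairs eligible in both, and counts sign agreement. Discrepant
    pairs get a two-sided difference test on the standardised effects.
    """
    candidates = [r for r in pooled_results
                  if r.outcome_type == "disease" and r.converged
                  and r.p_one_sided < 0.05]
    diseases = sorted({r.outcome_name for r in candidates})
    eligible_by_sex = {}
    for sex_val in (0, 1):
        sub_cohort = cohort[cohort["sex"] == sex_val]
        screens = []
        for d in diseases:
            recs = disease_records[
                disease_records["individual_id"].isin(sub_cohort.index)]
            try:
                s = screen_chronage_disease(recs, sub_cohort, d)
            except DataError:
                continue
            screens.append(s)
        apply_screening(screens, q=q, min_events=min_events)
        eligible_by_sex[sex_val] = {s.outcome_name for s in screens
                                    if s.eligible}
    both = eligible_by_sex.get(0, set()) & eligible_by_sex.get(1, set())

    assessed, agree, discrepant = 0, 0, []
    for r in candidates:
        if r.outcome_name not in both or r.clock_name not in ocaa_df.columns:
            continue
        per_sex = {}
        for sex_val in (0, 1):
            sub_cohort = cohort[cohort["sex"] == sex_val]
            recs = disease_records[
                disease_records["individual_id"].isin(sub_cohort.index)]
            df = cox_frame(recs, sub_cohort, r.outcome_name,
                           extra={"ocaa": ocaa_df[r.clock_name]})
            params, bse, ok = _cox(df, ["ocaa", "chron_age"])
            if not ok:
                break
            per_sex[sex_val] = (float(params["ocaa"]), float(bse["ocaa"]))
        if len(per_sex) < 2:
            continue
        assessed += 1
        (bm, sm_), (bf, sf) = per_sex[1], per_sex[0]
        if np.sign(bm) == np.sign(bf):
            agree += 1
        else:
            discrepant.append({
                "clock_name": r.clock_name, "outcome_name": r.outcome_name,
                "beta_male": bm, "beta_female": bf,
                "p_difference": sex_difference_test(bm, sm_, bf, sf)})
    return {
        "n_candidates": len(candidates),
        "n_assessed": assessed,
        "sign_consistency": (agree / assessed) if assessed else float("nan"),
        "discrepant": discrepant,
    }
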