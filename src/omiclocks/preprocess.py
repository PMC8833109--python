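"""Per-assay quality control.

The fixed QC order, applied per assay and logged, is:

1. first-pass outlier removal (|z| > threshold, default 6, set missing);
2. fixed-effects pre-correction for covariates (sex, batch, ...) - each
   feature is replaced by its least-squares residuals;
3. optional second-pass outlier removal on the residuals (default z > 3,
   where enabled for the assay);
4. scaling and centring of each feature to mean 0, SD 1, dropping
   constant features.

Z-scores for the second pass are computed on the post-correction residual
distribution. Missing values are excluded pairwise from means and SDs;
complete-case filtering happens only at clock-training time, per assay.
No operation reorders individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import OmicsMatrix
from .errors import ConfigError, DataError


@dataclass
class QcConfig:
    z_first_pass: float = 6.0
    z_second_pass: float | None = 3.0
    covariate_names: list = field(default_factory=lambda: ["sex", "batch"])
    categorical: list = field(default_factory=lambda: ["batch"])

    def validate(self):
        if self.z_first_pass <= 0:
            raise ConfigError("z_first_pass must be > 0")
        if self.z_second_pass is not None and self.z_second_pass <= 0:
            raise ConfigError("z_second_pass must be > 0")


def remove_outliers(values: pd.Series, z_threshold: float) -> pd.Series:
    """Set entries with |value - mean| / SD > threshold to missing.

    Mean and SD are computed on the non-missing entries. Constant and
    all-missing vectors are returned unchanged (SD = 0 guarded; all-missing
    triggers a warning). Single-shot: statistics are not recomputed after
    removal.
    """
    if z_threshold <= 0:
        raise ConfigError("z_threshold must be > 0")
    x = values.astype(float)
    obs = x.dropna()
    if obs.empty:
        warnings.warn(f"feature {values.name!r}: all values missing")
        return x
    sd = obs.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return x
    z = (x - obs.mean()).abs() / sd
    return x.mask(z > z_threshold)


def _design(covariates: pd.DataFrame, covariate_names, categorical):
    """Intercept + covariate design matrix; categoricals expand to indicators."""
    missing = [c for c in covariate_names if c not in covariates.columns]
    if missing:
        raise DataError(f"covariates not present: {missing}")
    cols = {"const": np.ones(len(covariates))}
    names = ["const"]
    for c in covariate_names:
        if c in categorical:
            dummies = pd.get_dummies(covariates[c].astype("category"),
                                     prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc].to_numpy()
                names.append(dc)
        else:
            cols[c] = covariates[c].astype(float).to_numpy()
            names.append(c)
    X = np.column_stack([cols[c] for c in names])
    return X, names


def precorrect_covariates(matrix: OmicsMatrix, covariate_names,
                          categorical=("batch",)) -> OmicsMatrix:
    """Replace each feature by residuals of a least-squares fit on covariates.

    Rank-deficient designs are handled by dropping aliased columns (pivoted
    QR); which columns were dropped is recorded in the matrix log.
    Residuals keep the original missingness pattern.
    """
    if matrix.covariates is None:
        raise DataError(f"{matrix.assay_name}: no covariates attached")
    X_full, names = _design(matrix.covariates.loc[matrix.individual_ids],
                            covariate_names, list(categorical))
    # detect aliased columns once, on the full design
    _, _, piv = scipy.linalg.qr(X_full, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X_full)
    keep = np.sort(piv[:rank])
    aliased = [names[i] for i in range(len(names)) if i not in set(keep)]
    if aliased:
        warnings.warn(
            f"{matrix.assay_name}: aliased covariate columns dropped: {aliased}")
    X = X_full[:, keep]

    out = matrix.data.copy()
    vals = out.to_numpy(dtype=float)
    for j in range(vals.shape[1]):
        y = vals[:, j]
        rows = np.isfinite(y)
        if rows.sum() <= X.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(X[rows], y[rows], rcond=None)
        vals[rows, j] = y[rows] - X[rows] @ beta
    out.iloc[:, :] = vals
    note = (f"precorrect: covariates={list(covariate_names)}"
            + (f", aliased_dropped={aliased}" if aliased else ""))
    res = matrix.copy_with(out, note)
    return res


def standardize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Scale and centre each feature to mean 0, SD 1 over non-missing entries.

    Constant features (SD = 0 on the observed entries) carry no signal and
    are dropped, with the drop recorded in the matrix log.
    """
    data = matrix.data.astype(float)
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=1)
    constant = sds.index[(sds == 0) | ~np.isfinite(sds)]
    kept = data.drop(columns=constant)
    out = (kept - means[kept.columns]) / sds[kept.columns]
    note = "standardize" + (f", dropped_constant={list(constant)}"
                            if len(constant) else "")
    return matrix.copy_with(out, note)


def qc_pipeline(matrix: OmicsMatrix, config: QcConfig | None = None
                ) -> tuple[OmicsMatrix, dict]:
    """Run the full per-assay QC in the fixed order; returns (matrix, report)."""
    config = config or QcConfig()
    config.validate()
    report = {"assay": matrix.assay_name,
              "n_individuals": int(matrix.n_individuals),
              "n_features_in": int(matrix.n_features)}

    before = matrix.data.notna().sum().sum()
    pass1 = matrix.data.apply(
        lambda col: remove_outliers(col, config.z_first_pass))
    report["outliers_first_pass"] = int(before - pass1.notna().sum().sum())
    m = matrix.copy_with(pass1, f"outliers pass 1 (z={config.z_first_pass})")

    m = precorrect_covariates(m, config.covariate_names, config.categorical)

    if config.z_second_pass is not None:
        before = m.data.notna().sum().sum()
        pass2 = m.data.apply(
            lambda col: remove_outliers(col, config.z_second_pass))
        report["outliers_second_pass"] = int(
            before - pass2.notna().sum().sum())
        m = m.copy_with(pass2, f"outliers pass 2 (z={config.z_second_pass})")
    else:
        report["outliers_second_pass"] = 0

    m = standardize(m)
    report["n_features_out"] = int(m.n_features)
    report["dropped_constant"] = int(matrix.n_features - m.n_features)
    report["log"] = list(m.log)
    return m, report
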