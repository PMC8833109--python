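"""Elastic-net ageing clocks.

A clock is a penalised linear model that maps one assay's standardised
features to an estimated age (the omics clock age, OCA); OCA minus
chronological age is the omics clock age acceleration (OCAA). The default
procedure mirrors common practice for chronAge-trained clocks:

* a 75/25 train/test split, with test individuals drawn preferentially
  from those complete across all assays (so every clock is evaluated in
  the same people);
* elastic-net regression with L1/L2 mixing ``alpha`` = 0.5, with the
  penalty strength ``lambda`` chosen at minimum mean-squared error by
  tenfold cross-validation in the training sample;
* "core" clocks refit on the features selected in >95% of repeated
  (default 500) re-splits of the construction procedure;
* a "mega-omics" clock offered every feature of every assay at once; and
* principal-component clocks fit on the first few PCs of an assay.

Features are standardised with training-set statistics only; test rows are
transformed with the stored statistics (prevents train/test leakage).

Note on vocabulary: ``alpha`` here is the L1/L2 mixing parameter and
``lambda`` the penalty strength (the glmnet convention used throughout the
ageing-clock literature); scikit-learn swaps these names internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .containers import OmicsMatrix
from .errors import ConfigError, DataError

#: l1-ratio grid used when the mixing parameter is itself cross-validated.
ALPHA_CV_GRID = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass
class ClockModel:
    """A trained clock: intercept + sparse weights on standardised features.

    ``coefficients`` maps feature_id -> years per SD of that feature; only
    features with non-zero weight are stored. ``feature_stats`` holds the
    training-set mean/SD used to standardise each retained feature at
    prediction time. PC clocks additionally carry a ``pca`` payload
    (loadings and the stats of the underlying features) so new individuals
    can be projected into component space first.
    """

    assay_name: str
    intercept: float
    coefficients: dict
    alpha: float
    lambda_: float
    train_ids: list
    test_ids: list
    train_r: float
    test_r: float | None
    feature_stats: dict            # feature_id -> [mean, sd]
    seed: int | None = None
    pca: dict | None = None

    @property
    def n_selected(self) -> int:
        return len(self.coefficients)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "ClockModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


@dataclass
class StabilityResult:
    """Feature selection frequencies over repeated clock construction."""

    selection_frequency: dict      # feature_id -> proportion of iterations
    iterations: int
    threshold: float
    core_features: list = field(default_factory=list)


def split_cohort(ids, fraction: float = 0.75, complete_ids=None, seed=0):
    """Split individuals into training/testing sets.

    ``|test| = round((1 - fraction) * n)``. When ``complete_ids`` is given,
    test individuals are drawn preferentially from that pool (individuals
    with measures on all omics platforms), so clocks from different assays
    are evaluated in the same people.
    """
    if not 0 < fraction < 1:
        raise ConfigError("fraction must be in (0, 1)")
    ids = sorted(map(str, ids))
    n = len(ids)
    n_test = int(round((1 - fraction) * n))
    rng = np.random.default_rng(seed)
    if complete_ids is not None:
        complete = sorted(set(map(str, complete_ids)) & set(ids))
        rest = sorted(set(ids) - set(complete))
        order = list(rng.permutation(complete)) + list(rng.permutation(rest))
    else:
        order = list(rng.permutation(ids))
    test = sorted(order[:n_test])
    train = sorted(order[n_test:])
    return train, test


def _complete_rows(matrix: OmicsMatrix, ids):
    sub = matrix.data.loc[matrix.data.index.intersection(pd.Index(ids))]
    return sub.dropna(axis=0, how="any")


def _pearson(a, b) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def train_clock(matrix: OmicsMatrix, chron_age: pd.Series, train_ids,
                test_ids=None, alpha=0.5, folds: int = 10,
                n_lambdas: int = 100, seed: int = 0,
                max_iter: int = 5000) -> ClockModel:
    """Fit one elastic-net clock.

    Parameters
    ----------
    alpha
        L1/L2 mixing: 0.5 (default), 1.0 for LASSO, or the string ``"cv"``
        to select the mixing parameter itself by cross-validation over
        :data:`ALPHA_CV_GRID`.
    folds, n_lambdas
        Tenfold CV over a path of ``n_lambdas`` penalty strengths; lambda
        is taken at minimum mean CV squared error.

    Individuals with any missing feature in this assay are excluded from
    training (and from the test correlation). Raises
    :class:`~omiclocks.errors.DataError` when fewer complete training rows
    than ``2 * folds`` remain.
    """
    train_X = _complete_rows(matrix, train_ids)
    if train_X.shape[0] < 2 * folds:
        raise DataError(
            f"{matrix.assay_name}: only {train_X.shape[0]} complete training "
            f"rows; need at least {2 * folds}")
    y_train = chron_age.loc[train_X.index].to_numpy(dtype=float)

    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0, ddof=1)
    usable = sds.index[(sds > 0) & np.isfinite(sds)]
    Z = ((train_X[usable] - means[usable]) / sds[usable]).to_numpy()

    if isinstance(alpha, str):
        if alpha != "cv":
            raise ConfigError(f"unknown alpha setting {alpha!r}")
        l1_ratio = list(ALPHA_CV_GRID)
    else:
        if not 0 < alpha <= 1:
            raise ConfigError("alpha must be in (0, 1] (use 1.0 for LASSO)")
        l1_ratio = float(alpha)

    cv = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    model = ElasticNetCV(l1_ratio=l1_ratio, alphas=n_lambdas, cv=cv,
                         max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # occasional coordinate-descent
        model.fit(Z, y_train)            # convergence chatter at tiny lambda

    coef = pd.Series(model.coef_, index=usable)
    nonzero = coef[coef != 0]
    if nonzero.empty:
        warnings.warn(f"{matrix.assay_name}: all coefficients shrunk to zero")

    keep = list(nonzero.index)
    feature_stats = {f: [float(means[f]), float(sds[f])] for f in keep}
    pred_train = model.intercept_ + Z @ coef.to_numpy()
    train_r = _pearson(pred_train, y_train)

    clock = ClockModel(
        assay_name=matrix.assay_name,
        intercept=float(model.intercept_),
        coefficients={f: float(nonzero[f]) for f in keep},
        alpha=float(model.l1_ratio_) if isinstance(l1_ratio, list)
        else float(l1_ratio),
        lambda_=float(model.alpha_),
        train_ids=[str(i) for i in train_X.index],
        test_ids=[str(i) for i in (test_ids if test_ids is not None else [])],
        train_r=train_r,
        test_r=None,
        feature_stats=feature_stats,
        seed=int(seed),
    )
    if test_ids is not None:
        oca = predict_age(clock, matrix.subset(test_ids))
        both = pd.concat([oca.rename("oca"),
                          chron_age.rename("age")], axis=1, join="inner").dropna()
        clock.test_r = _pearson(both["oca"].to_numpy(), both["age"].to_numpy())
    return clock


def predict_age(model: ClockModel, matrix: OmicsMatrix) -> pd.Series:
    """Estimate age (OCA) for every individual in ``matrix``.

    Individuals missing any model feature get a missing OCA. Raises
    :class:`~omiclocks.errors.DataError` naming any model feature absent
    from the matrix entirely.
    """
    if model.pca is not None:
        matrix = _project_pcs(model, matrix)
    needed = list(model.coefficients)
    absent = [f for f in needed if f not in matrix.feature_ids]
    if absent:
        raise DataError(
            f"clock {model.assay_name}: features absent from matrix: {absent}")
    if not needed:  # all-zero model: OCA = intercept for everyone
        return pd.Series(model.intercept, index=matrix.individual_ids,
                         name="oca")
    X = matrix.data[needed].astype(float)
    stats_ = pd.DataFrame(model.feature_stats, index=["mean", "sd"]).T
    Z = (X - stats_["mean"]) / stats_["sd"]
    w = pd.Series(model.coefficients)
    oca = model.intercept + Z @ w
    oca[X.isna().any(axis=1)] = np.nan
    return oca.rename("oca")


def compute_ocaa(oca: pd.Series, chron_age: pd.Series) -> pd.Series:
    """Omics clock age acceleration: OCA minus chronAge, element-wise."""
    return (oca - chron_age.loc[oca.index]).rename("ocaa")


def clock_age_table(clock_name: str, oca: pd.Series, chron_age: pd.Series,
                    eval_ids=None) -> pd.DataFrame:
    """Long-format table of OCA / OCAA / standardised OCAA.

    ``ocaa_std`` is standardised over the evaluation set (default: all
    individuals with a non-missing OCA).
    """
    ocaa = compute_ocaa(oca, chron_age)
    out = pd.DataFrame({"clock_name": clock_name, "oca": oca, "ocaa": ocaa})
    ids = out.index if eval_ids is None else out.index.intersection(
        pd.Index(eval_ids))
    sub = out.loc[ids, "ocaa"].dropna()
    sd = sub.std(ddof=1)
    out["ocaa_std"] = np.nan
    if sd > 0:
        out.loc[sub.index, "ocaa_std"] = (sub - sub.mean()) / sd
    return out


def stability_select(matrix: OmicsMatrix, chron_age: pd.Series,
                     iterations: int = 500, threshold: float = 0.95,
                     fraction: float = 0.75, alpha=0.5, folds: int = 10,
                     n_lambdas: int = 100, seed: int = 0,
                     final_split=None):
    """Repeat clock construction over fresh splits; refit on stable features.

    Each iteration redraws the train/test split (per-iteration streams are
    derived from the master seed plus the iteration index, so results are
    independent of execution order) and refits the full elastic-net
    procedure. Features selected in more than ``threshold`` of iterations
    form the core set; the core clock is then retrained from scratch
    (including CV for lambda) on that set, using ``final_split`` or a fresh
    split.

    Returns ``(StabilityResult, core ClockModel)``.
    """
    counts = pd.Series(0.0, index=matrix.feature_ids)
    ids = matrix.individual_ids
    for i in range(iterations):
        it_seed = np.random.SeedSequence([int(seed), i])
        tr, te = split_cohort(ids, fraction=fraction, seed=it_seed)
        m = train_clock(matrix, chron_age, tr, test_ids=None, alpha=alpha,
                        folds=folds, n_lambdas=n_lambdas, seed=i)
        counts[list(m.coefficients)] += 1.0
    freq = counts / iterations
    core = list(freq.index[freq > threshold])
    result = StabilityResult(
        selection_frequency={f: float(freq[f]) for f in freq.index},
        iterations=iterations, threshold=threshold, core_features=core)
    if not core:
        raise DataError(
            f"{matrix.assay_name}: no feature selected in more than "
            f"{threshold:.0%} of {iterations} iterations; "
            "consider lowering the threshold")
    if final_split is None:
        final_split = split_cohort(
            ids, fraction=fraction,
            seed=np.random.SeedSequence([int(seed), iterations]))
    tr, te = final_split
    core_matrix = matrix.copy_with(matrix.data[core],
                                   f"core subset ({len(core)} features)")
    core_model = train_clock(core_matrix, chron_age, tr, test_ids=te,
                             alpha=alpha, folds=folds, n_lambdas=n_lambdas,
                             seed=seed)
    core_model.assay_name = f"{matrix.assay_name}_core"
    return result, core_model


def build_mega_matrix(assays) -> OmicsMatrix:
    """Column-wise merge of corrected, standardised assays.

    Rows are the intersection of individuals across all assays (the only
    people in whom every platform was measured); feature ids are prefixed
    by assay name. Duplicate ids after prefixing are an error.
    """
    if not assays:
        raise DataError("no assays to merge")
    ids = assays[0].individual_ids
    for m in assays[1:]:
        ids = ids.intersection(m.individual_ids)
    ids = ids.sort_values()
    parts = []
    for m in assays:
        part = m.data.loc[ids].copy()
        part.columns = [f"{m.assay_name}:{c}" for c in part.columns]
        parts.append(part)
    merged = pd.concat(parts, axis=1)
    if merged.columns.has_duplicates:
        dups = merged.columns[merged.columns.duplicated()].unique()
        raise DataError(f"duplicate feature ids after prefixing: {list(dups)}")
    covs = assays[0].covariates.loc[ids] if assays[0].covariates is not None \
        else None
    return OmicsMatrix("mega", merged, covs,
                       [f"merged {len(assays)} assays, {len(ids)} shared ids"])


def mega_selection_shares(model: ClockModel) -> dict:
    """Share of a mega-omics clock's selected features coming from each assay."""
    if not model.coefficients:
        return {}
    prefixes = [f.split(":", 1)[0] for f in model.coefficients]
    counts = pd.Series(prefixes).value_counts()
    return (counts / counts.sum()).to_dict()


def _project_pcs(model: ClockModel, matrix: OmicsMatrix) -> OmicsMatrix:
    p = model.pca
    absent = [f for f in p["feature_ids"] if f not in matrix.feature_ids]
    if absent:
        raise DataError(
            f"clock {model.assay_name}: features absent from matrix: "
            f"{absent[:5]}{'...' if len(absent) > 5 else ''}")
    X = matrix.data[p["feature_ids"]].dropna(axis=0, how="any")
    Z = (X - np.asarray(p["means"])) / np.asarray(p["sds"])
    scores = Z.to_numpy() @ np.asarray(p["components"]).T
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OmicsMatrix(model.assay_name,
                       pd.DataFrame(scores, index=X.index, columns=cols))


def pc_clock(matrix: OmicsMatrix, n_components: int, chron_age: pd.Series,
             split, seed: int = 0, alpha=0.5, folds: int = 10,
             n_lambdas: int = 100) -> ClockModel:
    """Clock on the first principal components of an assay.

    PCs are computed on complete training rows only; stored loadings project
    test (or any new) individuals into the same component space before the
    elastic-net step.
    """
    train_ids, test_ids = split
    train_X = _complete_rows(matrix, train_ids)
    rank = min(train_X.shape[0] - 1, train_X.shape[1])
    if n_components > rank:
        raise DataError(
            f"{matrix.assay_name}: n_components={n_components} exceeds "
            f"rank {rank}")
    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0, ddof=1).replace(0, 1.0)
    Z = ((train_X - means) / sds).to_numpy()
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    payload = {
        "feature_ids": list(train_X.columns),
        "means": [float(v) for v in means],
        "sds": [float(v) for v in sds],
        "components": pca.components_.tolist(),
    }
    shell = ClockModel(assay_name=f"{matrix.assay_name}_pc{n_components}",
                       intercept=0.0, coefficients={}, alpha=0.0, lambda_=0.0,
                       train_ids=[], test_ids=[], train_r=float("nan"),
                       test_r=None, feature_stats={}, pca=payload)
    score_matrix = _project_pcs(shell, matrix)
    model = train_clock(score_matrix, chron_age, train_ids, test_ids=test_ids,
                        alpha=alpha, folds=folds, n_lambdas=n_lambdas,
                        seed=seed)
    model.assay_name = shell.assay_name
    model.pca = payload
    return model
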