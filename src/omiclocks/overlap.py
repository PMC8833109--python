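"""Partitioning chronAge variance among clocks; the scaled excess-overlap statistic.

Given the age estimates X_1..X_k of k clocks and chronAge Y, the joint
model Y = b0 + b1 X1 + ... + bk Xk partitions Var(Y) into

* unique contributions sr_i^2 (squared semi-partial / part correlation of
  Y with clock i controlling the rest),
* a shared component R^2 - sum_i sr_i^2 explained by two or more clocks,
* and the unexplained remainder 1 - R^2.

For a pair of clocks with univariate explained variances v1, v2 and
observed bivariate R^2 = O, the expected joint variance under the null
that each clock independently samples from a latent set of complete
predictors (ISLSP) is

    E = 1 - (1 - v1)(1 - v2),

bounded below by E_min = max(v1, v2) (second clock adds nothing) and above
by E_max = min(v1 + v2, 1) (fully complementary clocks). The scaled
excess-overlap statistic is

    excess = (E - O) / (E - E_min),

1 for total redundancy (a clock paired with itself), 0 at the ISLSP
expectation, negative when the clocks overlap less than expected and so
track separate aspects of ageing.

Part correlations are computed through the leave-one-out R^2 identity
sr_i^2 = R^2(all) - R^2(all but i), which is numerically stable and
doubles as its own oracle against the classic residualisation formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError

_FLOOR_TOL = 1e-9


@dataclass
class PartitionResult:
    """chronAge variance split into unique / shared / unexplained parts."""

    unique: dict                  # clock -> sr_i^2
    joint_r2: float
    shared: float
    unexplained: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OverlapResult:
    """One clock pair's observed vs expected joint explained variance."""

    clock_a: str
    clock_b: str
    v1: float
    v2: float
    observed: float               # O, bivariate R^2
    expected: float               # E under ISLSP
    e_min: float
    e_max: float
    excess: float                 # (E - O) / (E - E_min); NaN if degenerate

    def to_dict(self) -> dict:
        return asdict(self)


# ---- regression plumbing ------------------------------------------------

def _align(chron_age: pd.Series, oca_df: pd.DataFrame):
    """Complete-case intersection of chronAge with a set of OCA vectors."""
    joined = pd.concat([chron_age.rename("__y__"), oca_df], axis=1,
                       join="inner").dropna()
    return joined["__y__"].to_numpy(float), joined.drop(columns="__y__")


def r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """Centred R^2 of an OLS fit of y on X (intercept included)."""
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float((resid ** 2).sum()) / ss_tot


def univariate_r2(chron_age: pd.Series, oca: pd.Series) -> float:
    """v_i: squared Pearson correlation of chronAge with one clock's OCA."""
    y, X = _align(chron_age, oca.to_frame("x"))
    return float(np.corrcoef(y, X["x"].to_numpy())[0, 1] ** 2)


def _floor(value: float, what: str) -> float:
    if value < 0:
        if value < -_FLOOR_TOL:
            warnings.warn(f"{what} = {value:.3g} floored to 0")
        return 0.0
    return value


# ---- k-clock partition --------------------------------------------------

def unique_variance(chron_age: pd.Series, oca_df: pd.DataFrame) -> pd.Series:
    """sr_i^2 per clock via the leave-one-out R^2 identity.

    Perfectly collinear clock pairs contribute no unique variance; they are
    reported as 0 with a warning.
    """
    if oca_df.shape[1] < 2:
        raise DataError("need at least 2 clocks")
    y, X = _align(chron_age, oca_df)
    corr = X.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if (corr > 1 - 1e-12).any().any():
        pairs = [(a, b) for a in corr.index for b in corr.columns
                 if a < b and corr.loc[a, b] > 1 - 1e-12]
        warnings.warn(f"perfectly collinear clock pairs {pairs}: "
                      "unique variance 0 for both")
    full = r_squared(y, X.to_numpy())
    out = {}
    for clock in X.columns:
        reduced = r_squared(y, X.drop(columns=clock).to_numpy())
        out[clock] = _floor(full - reduced, f"sr^2[{clock}]")
    return pd.Series(out, name="sr2")


def partition_variance(chron_age: pd.Series,
                       oca_df: pd.DataFrame) -> PartitionResult:
    """Partition chronAge variance into unique / shared / unexplained.

    ``shared`` is the variance explained by two or more clocks jointly:
    joint R^2 minus the sum of unique contributions. Components sum to 1
    by construction.
    """
    y, X = _align(chron_age, oca_df)
    k = X.shape[1]
    if len(y) <= k + 1:
        raise DataError(f"n={len(y)} too small for k={k} clocks")
    joint = r_squared(y, X.to_numpy())
    unique = unique_variance(chron_age, oca_df)
    shared = _floor(joint - float(unique.sum()), "shared")
    unexplained = _floor(1.0 - joint, "unexplained")
    return PartitionResult(unique=unique.to_dict(), joint_r2=joint,
                           shared=shared, unexplained=unexplained, n=len(y))


def pairwise_partition(chron_age: pd.Series, oca_i: pd.Series,
                       oca_j: pd.Series, names=("clock_a", "clock_b")
                       ) -> PartitionResult:
    """Two-clock partition; ``shared`` is attributable to both clocks jointly."""
    df = pd.concat([oca_i.rename(names[0]), oca_j.rename(names[1])], axis=1)
    return partition_variance(chron_age, df)


# ---- pairwise overlap ---------------------------------------------------

def expected_overlap(v1: float, v2: float) -> float:
    """E = 1 - (1 - v1)(1 - v2): expected joint R^2 under the ISLSP null."""
    if not (0 <= v1 <= 1 and 0 <= v2 <= 1):
        raise DataError("v1 and v2 must lie in [0, 1]")
    return 1.0 - (1.0 - v1) * (1.0 - v2)


def excess_overlap(v1: float, v2: float, observed: float,
                   clock_a: str = "clock_a", clock_b: str = "clock_b",
                   tol: float = 1e-9) -> OverlapResult:
    """Scaled excess overlap (E - O) / (E - E_min) for one clock pair.

    ``observed`` outside [E_min, E_max] by more than ``tol`` is clamped
    with a warning (sampling noise can push the bivariate R^2 slightly
    past its theoretical bounds). When E == E_min (degenerate, e.g. one
    clock explains nothing) the statistic is undefined and returned as NaN.
    """
    e = expected_overlap(v1, v2)
    e_min = max(v1, v2)
    e_max = min(v1 + v2, 1.0)
    o = observed
    if o < e_min - tol or o > e_max + tol:
        warnings.warn(
            f"{clock_a}~{clock_b}: observed R^2 {o:.6g} outside "
            f"[{e_min:.6g}, {e_max:.6g}]; clamped")
    o = min(max(o, e_min), e_max)
    denom = e - e_min
    if denom <= tol:
        warnings.warn(
            f"{clock_a}~{clock_b}: E == E_min (v1={v1:.3g}, v2={v2:.3g}); "
            "excess overlap undefined")
        excess = float("nan")
    else:
        excess = (e - o) / denom
    return OverlapResult(clock_a, clock_b, float(v1), float(v2), float(o),
                         float(e), float(e_min), float(e_max), float(excess))


#: clocks excluded by default from between-clock comparisons (the grand-union
#: clock spans every assay, so its overlap with any single-assay clock is
#: structural, not informative).
DEFAULT_EXCLUDED = ("mega",)


def _comparison_columns(oca_df: pd.DataFrame, exclude) -> list:
    excl = {e.lower() for e in (exclude or ())}
    return [c for c in oca_df.columns if c.lower() not in excl]


def pairwise_overlap_table(chron_age: pd.Series, oca_df: pd.DataFrame,
                           exclude=DEFAULT_EXCLUDED) -> pd.DataFrame:
    """Excess overlap for every unordered clock pair (long format).

    Each pair is evaluated on its own complete-case intersection of
    individuals. The mega-omics clock is excluded by default.
    """
    cols = _comparison_columns(oca_df, exclude)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            y, X = _align(chron_age, oca_df[[a, b]])
            v1 = float(np.corrcoef(y, X[a])[0, 1] ** 2)
            v2 = float(np.corrcoef(y, X[b])[0, 1] ** 2)
            o = r_squared(y, X.to_numpy())
            rows.append(excess_overlap(v1, v2, o, a, b).to_dict())
    return pd.DataFrame(rows)


def overlap_matrix(pairs: pd.DataFrame, value: str = "excess") -> pd.DataFrame:
    """Square symmetric matrix of a pairwise statistic; unit diagonal on the
    excess scale (a clock overlaps completely with itself)."""
    clocks = sorted(set(pairs["clock_a"]) | set(pairs["clock_b"]))
    out = pd.DataFrame(np.eye(len(clocks)) if value == "excess"
                       else np.zeros((len(clocks), len(clocks))),
                       index=clocks, columns=clocks)
    for _, r in pairs.iterrows():
        out.loc[r["clock_a"], r["clock_b"]] = r[value]
        out.loc[r["clock_b"], r["clock_a"]] = r[value]
    return out


def ocaa_correlation_matrix(ocaa_df: pd.DataFrame,
                            exclude=DEFAULT_EXCLUDED) -> pd.DataFrame:
    """Pairwise Pearson correlations of OCAAs, ordered by hierarchical
    clustering (average linkage on 1 - r) so related clocks sit together."""
    cols = _comparison_columns(ocaa_df, exclude)
    corr = ocaa_df[cols].corr()
    if len(cols) > 2:
        dist = squareform((1 - corr).clip(lower=0).to_numpy(), checks=False)
        order = hierarchy.leaves_list(hierarchy.linkage(dist, "average"))
        cols = [cols[i] for i in order]
        corr = corr.loc[cols, cols]
    return corr


# ---- exact ISLSP experiments --------------------------------------------

def islsp_overlap(bank_X: pd.DataFrame, y: pd.Series, subset_a, subset_b
                  ) -> OverlapResult:
    """Excess overlap for two clocks built from a latent predictor bank.

    Each clock is the best linear combination of its predictor subset
    (for the exact bank construction this is simply the subset sum). Under
    the ISLSP null the information a pair of clocks carries about chronAge
    is the union of their latent predictor subsets, so the observed joint
    variance O is the R^2 of chronAge on the union of the two subsets -
    with overlap at its expected size this equals E exactly, which is what
    makes the ISLSP zero point exact.
    """
    a = list(subset_a)
    b = list(subset_b)
    union = sorted(set(a) | set(b))
    yv = y.to_numpy(float)
    v1 = r_squared(yv, bank_X[a].to_numpy())
    v2 = r_squared(yv, bank_X[b].to_numpy())
    o = r_squared(yv, bank_X[union].to_numpy())
    return excess_overlap(v1, v2, o, "bank_a", "bank_b")


def islsp_null_draws(bank_X: pd.DataFrame, y: pd.Series, size_a: int,
                     size_b: int, n_draws: int = 200, seed=0) -> np.ndarray:
    """Monte-Carlo ISLSP: excess overlap for independently drawn subsets.

    Each draw samples two independent predictor subsets of the given sizes
    and evaluates the excess-overlap statistic; the mean over draws should
    sit at the ISLSP zero point.
    """
    rng = np.random.default_rng(seed)
    cols = list(bank_X.columns)
    out = np.empty(n_draws)
    for i in range(n_draws):
        a = list(rng.choice(cols, size=size_a, replace=False))
        b = list(rng.choice(cols, size=size_b, replace=False))
        out[i] = islsp_overlap(bank_X, y, a, b).excess
    return out
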