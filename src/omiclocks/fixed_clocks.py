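"""Externally supplied fixed-coefficient clocks.

Published ageing clocks ship as a fixed intercept plus per-feature weights
(optionally with a per-feature transform such as squaring). This module
applies any such recipe so published-clock-style OCAs enter the same
downstream analyses as clocks trained in-cohort, and implements the
IgG-glycan age score, which is defined directly as a sex-stratified
regression recipe rather than a penalised model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .errors import ConfigError, DataError

_TRANSFORMS = {
    "identity": lambda x: x,
    "square": lambda x: x ** 2,
}


@dataclass
class FixedClockSpec:
    """A published-style clock: intercept + feature weights (+ transforms)."""

    clock_name: str
    intercept: float
    coefficients: dict                       # feature_id -> weight
    transform: dict = field(default_factory=dict)  # feature_id -> tag

    def validate(self):
        if not self.coefficients:
            raise ConfigError(f"{self.clock_name}: needs at least one coefficient")
        bad = {t for t in self.transform.values() if t not in _TRANSFORMS}
        if bad:
            raise ConfigError(
                f"{self.clock_name}: unknown transform tags {sorted(bad)}; "
                f"allowed: {sorted(_TRANSFORMS)}")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "FixedClockSpec":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


def apply_fixed_clock(spec: FixedClockSpec, matrix: OmicsMatrix) -> pd.Series:
    """OCA = intercept + sum of weight * transform(feature).

    Features absent from the matrix are named in a warning and force a
    missing OCA for everyone; individuals missing any needed value get a
    missing OCA.
    """
    spec.validate()
    absent = [f for f in spec.coefficients if f not in matrix.feature_ids]
    if absent:
        warnings.warn(
            f"{spec.clock_name}: features absent from matrix: {absent}")
        return pd.Series(np.nan, index=matrix.individual_ids, name="oca")
    total = pd.Series(spec.intercept, index=matrix.individual_ids,
                      dtype=float)
    for f, w in spec.coefficients.items():
        tf = _TRANSFORMS[spec.transform.get(f, "identity")]
        total = total + w * tf(matrix.data[f].astype(float))
    return total.rename("oca")


def glycan_age(glycans: pd.DataFrame) -> pd.Series:
    """IgG-glycan age-acceleration score.

    Within each sex, chronological age is regressed on the glycan terms
    GP6, GP6^2, GP14 and GP15 by least squares; the score is fitted age
    minus observed chronAge (positive = accelerated). Being a least-squares
    residual, the score has exactly zero mean within each sex stratum. When
    no ``sex`` column is present (or only one level), a single-group fit
    is used.

    ``glycans`` needs columns GP6, GP14, GP15, chron_age and optionally sex.
    Raises :class:`~omiclocks.errors.DataError` for strata of fewer than
    5 individuals.
    """
    required = ["GP6", "GP14", "GP15", "chron_age"]
    missing = [c for c in required if c not in glycans.columns]
    if missing:
        raise DataError(f"glycan table missing columns: {missing}")
    df = glycans.dropna(subset=required)
    groups = (df.groupby("sex") if "sex" in df.columns and
              df["sex"].nunique() > 1 else [(None, df)])
    score = pd.Series(np.nan, index=glycans.index, name="glycan_age")
    for label, sub in groups:
        if len(sub) < 5:
            raise DataError(
                f"glycan_age: sex stratum {label!r} has only {len(sub)} "
                "individuals; need at least 5")
        X = np.column_stack([
            np.ones(len(sub)),
            sub["GP6"].to_numpy(float),
            sub["GP6"].to_numpy(float) ** 2,
            sub["GP14"].to_numpy(float),
            sub["GP15"].to_numpy(float),
        ])
        y = sub["chron_age"].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        score.loc[sub.index] = X @ beta - y
    return score
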