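"""In-memory containers shared across modules.

The central object is :class:`OmicsMatrix`: one assay's individuals ×
features measurement table together with the per-individual covariates
(sex, batch, smoking, ...) used for pre-correction. Rows are indexed by
``individual_id`` everywhere so tables join on the cohort spine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError


@dataclass
class OmicsMatrix:
    """One omics assay: an individuals × features matrix plus covariates.

    Parameters
    ----------
    assay_name
        Label for the assay (used to prefix features in the mega-omics
        merge and to name output files).
    data
        DataFrame indexed by individual_id with one column per feature.
        May contain NaN for missing measurements.
    covariates
        Optional DataFrame indexed by individual_id with per-individual
        covariates (sex, batch, smoking, ...). Must cover every individual
        present in ``data``.
    """

    assay_name: str
    data: pd.DataFrame
    covariates: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise DataError(f"{self.assay_name}: duplicate individual ids")
        if self.covariates is not None:
            missing = self.data.index.difference(self.covariates.index)
            if len(missing):
                raise DataError(
                    f"{self.assay_name}: covariates missing for "
                    f"{len(missing)} individuals (e.g. {list(missing[:3])})"
                )

    @property
    def individual_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def complete_ids(self) -> pd.Index:
        """Individuals with no missing feature in this assay."""
        return self.data.index[self.data.notna().all(axis=1)]

    def subset(self, individual_ids) -> "OmicsMatrix":
        ids = self.data.index.intersection(pd.Index(individual_ids))
        cov = None if self.covariates is None else self.covariates.loc[ids]
        return OmicsMatrix(self.assay_name, self.data.loc[ids].copy(), cov,
                           list(self.log))

    def copy_with(self, data: pd.DataFrame, note: str | None = None) -> "OmicsMatrix":
        log = list(self.log)
        if note:
            log.append(note)
        return OmicsMatrix(self.assay_name, data, self.covariates, log)
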