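"""Domain types and tabular I/O for censored survival data with high-dimensional covariates.

The central container is :class:`SurvivalDataset`, holding the observed triple
(follow-up time, event indicator, covariate matrix) for each sample, plus an
optional block of clinical covariates and the integration horizon ``tau`` used
by the counting-process machinery downstream.

Expression matrices arrive as TSV (features as rows by default, the microarray
series-matrix convention); outcomes as CSV with ``sample_id,time,status`` and
optional extra clinical columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "FeatureTable",
    "read_expression",
    "write_expression",
    "read_outcomes",
    "write_outcomes",
    "assemble_dataset",
]


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, bad times, ...)."""


class ParseError(ValueError):
    """Input file cannot be parsed into a numeric table."""


@dataclass
class FeatureTable:
    """A samples x features numeric matrix with unique string ids on both axes."""

    matrix: np.ndarray  # shape (n_samples, n_features)
    sample_ids: list[str]
    feature_ids: list[str]
    zero_variance: np.ndarray = field(default=None)  # bool mask over features

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-dimensional")
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValidationError(
                f"id lengths ({len(self.sample_ids)}, {len(self.feature_ids)}) "
                f"do not match matrix shape {self.matrix.shape}"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValidationError(f"duplicate {name} id(s): {sorted(dup)}")
        if not np.all(np.isfinite(self.matrix)):
            bad = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if self.zero_variance is None:
            # flagged, not dropped: constant features carry no signal but callers decide
            self.zero_variance = self.matrix.std(axis=0) == 0.0

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


@dataclass
class SurvivalDataset:
    """Right-censored survival data: (X_i, delta_i, Z_i) for i = 1..n.

    ``time`` is the observed follow-up X_i = min(T_i, C_i) (event or censoring,
    whichever came first), ``status`` the event indicator delta_i = I(T_i <= C_i),
    and ``covariates`` the n x p matrix Z of (typically gene-expression) features.
    ``tau`` is the horizon up to which counting-process integrals run; it
    defaults to the largest observed time.

    ``center`` / ``scale`` record the standardization applied to ``covariates``
    at assembly so that new samples can be mapped onto the training scale.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    feature_ids: list[str]
    clinical: np.ndarray | None = None
    clinical_ids: list[str] | None = None
    tau: float | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = self.time.shape[0]
        if self.status.shape != (n,):
            raise ValidationError("time and status length mismatch")
        if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
            raise ValidationError("covariates must be an (n, p) matrix")
        if len(self.feature_ids) != self.covariates.shape[1]:
            raise ValidationError("feature_ids length != number of covariate columns")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValidationError("all follow-up times must be finite and > 0")
        if not np.all(np.isin(self.status, (0.0, 1.0))):
            raise ValidationError("status must be binary (0/1)")
        if not np.all(np.isfinite(self.covariates)):
            raise ValidationError("covariates contain non-finite entries")
        if self.clinical is not None:
            self.clinical = np.asarray(self.clinical, dtype=float)
            if self.clinical.shape[0] != n:
                raise ValidationError("clinical rows != n")
            if not np.all(np.isfinite(self.clinical)):
                raise ValidationError("clinical covariates contain non-finite entries")
            if self.clinical_ids is None:
                self.clinical_ids = [f"clin_{j}" for j in range(self.clinical.shape[1])]
        if self.tau is None:
            self.tau = float(self.time.max())
        self.tau = float(self.tau)
        if self.tau < float(self.time.min()):
            raise ValidationError(
                f"tau={self.tau} is below the smallest observed time "
                f"{self.time.min()}; nothing would be integrated"
            )
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValidationError("sample_ids length != n")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row-subset (fold, bootstrap replicate, train/test split).

        ``tau`` is re-derived from the subset so integrals never run past the
        subset's own follow-up; standardization metadata is carried along.
        """
        idx = np.asarray(idx)
        return SurvivalDataset(
            time=self.time[idx],
            status=self.status[idx],
            covariates=self.covariates[idx],
            feature_ids=self.feature_ids,
            clinical=None if self.clinical is None else self.clinical[idx],
            clinical_ids=self.clinical_ids,
            tau=None,
            center=self.center,
            scale=self.scale,
            sample_ids=None
            if self.sample_ids is None
            else [self.sample_ids[i] for i in idx],
        )

    def with_covariates(self, covariates, feature_ids) -> "SurvivalDataset":
        """Same outcomes, different design matrix (e.g. clinical-only model)."""
        return SurvivalDataset(
            time=self.time.copy(),
            status=self.status.copy(),
            covariates=np.asarray(covariates, dtype=float),
            feature_ids=list(feature_ids),
            tau=self.tau,
            sample_ids=self.sample_ids,
        )


def read_expression(path, features_as_rows: bool = True) -> FeatureTable:
    """Read a TSV expression matrix.

    With ``features_as_rows`` (default, the series-matrix convention) the first
    column holds feature ids and the header row holds sample ids; the returned
    table is always oriented samples x features.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, header=0, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file, not a valid expression table")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: table has no data rows/columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.where(bad)[0][0]]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = df.index[np.where(coerced.isna())[0][0]]
            raise ValidationError(f"{path}: missing value at row {row!r}, column {col!r}")
        df[col] = coerced
    if features_as_rows:
        return FeatureTable(
            matrix=df.to_numpy().T,
            sample_ids=list(df.columns),
            feature_ids=list(df.index),
        )
    return FeatureTable(
        matrix=df.to_numpy(),
        sample_ids=list(df.index),
        feature_ids=list(df.columns),
    )


def write_expression(table: FeatureTable, path, features_as_rows: bool = True) -> None:
    """Write a :class:`FeatureTable` as TSV; round-trips bit-exactly via repr."""
    df = pd.DataFrame(table.matrix.T, index=table.feature_ids, columns=table.sample_ids)
    if not features_as_rows:
        df = df.T
    # %.17g round-trips any double exactly while keeping decimals short
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_outcomes(path) -> pd.DataFrame:
    """Read the outcome CSV: sample_id, time, status, plus clinical columns."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty outcome file")
    required = {"sample_id", "time", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    dup = _duplicates(df["sample_id"].astype(str))
    if dup:
        raise ValidationError(f"{path}: duplicate sample id(s): {sorted(dup)}")
    return df


def write_outcomes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def assemble_dataset(
    features: FeatureTable,
    outcomes: pd.DataFrame,
    standardize: bool = True,
    tau: float | None = None,
) -> SurvivalDataset:
    """Join expression and outcome tables by sample id into a SurvivalDataset.

    Samples appear in the order of the ``outcomes`` table (its sample ids must
    all exist in ``features``). When ``standardize`` is on (the default —
    penalized fits are scale-sensitive) every covariate column is centered and
    scaled to unit sample standard deviation; constant columns are centered
    only. The centers and scales are retained on the dataset so held-out
    samples can be placed on the identical scale.
    """
    ids = [str(s) for s in outcomes["sample_id"]]
    pos = {s: i for i, s in enumerate(features.sample_ids)}
    missing = [s for s in ids if s not in pos]
    if missing:
        raise ValidationError(f"outcome sample id(s) not in expression data: {missing}")
    order = [pos[s] for s in ids]
    Z = features.matrix[order].copy()

    time = outcomes["time"].to_numpy(dtype=float)
    status = outcomes["status"].to_numpy(dtype=float)
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValidationError("outcome times must be finite and > 0")

    clin_cols = [c for c in outcomes.columns if c not in ("sample_id", "time", "status")]
    clinical = outcomes[clin_cols].to_numpy(dtype=float) if clin_cols else None

    center = scale = None
    if standardize:
        Z, center, scale = standardize_columns(Z)

    return SurvivalDataset(
        time=time,
        status=status,
        covariates=Z,
        feature_ids=list(features.feature_ids),
        clinical=clinical,
        clinical_ids=clin_cols or None,
        tau=tau,
        center=center,
        scale=scale,
        sample_ids=ids,
    )


def standardize_columns(Z: np.ndarray):
    """Center each column; scale non-constant columns to unit sample SD (ddof=1).

    Returns (standardized matrix, centers, scales); constant columns get
    scale 1 so they map to exactly 0 rather than 0/0.
    """
    Z = np.asarray(Z, dtype=float)
    center = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1) if Z.shape[0] > 1 else np.zeros(Z.shape[1])
    scale = np.where(sd > 0, sd, 1.0)
    return (Z - center) / scale, center, scale


def apply_standardization(Z: np.ndarray, center: np.ndarray, scale: np.ndarray):
    """Map new samples onto a previously learned standardization."""
    return (np.asarray(Z, dtype=float) - center) / scale
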