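"""Subject-level datasets for count-outcome regression.

An :class:`AnalysisDataset` carries the polyp-count outcome together with two
design matrices: one for the count (or odds) component and one for the
zero-inflation component.  The two may differ — in observational analyses a
covariate is sometimes adjusted only in the inflation part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["AnalysisDataset", "build_dataset", "topcode_counts"]

logger = logging.getLogger("zicount")

INTERCEPT = "const"


class ValidationError(ValueError):
    """Raised when input data violate the dataset contract."""


def topcode_counts(y: np.ndarray, at: int) -> np.ndarray:
    """Merge counts ``>= at`` into the single value ``at`` (default analysis: 6+)."""
    if at < 1:
        raise ValidationError("topcode threshold must be >= 1")
    return np.minimum(np.asarray(y), at)


def _encode(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Design matrix with intercept; categoricals dummy-coded against the
    first level in sorted order (deterministic without a formula language)."""
    parts = [pd.Series(np.ones(len(df)), index=df.index, name=INTERCEPT)]
    for col in columns:
        s = df[col]
        if s.dtype.kind in "OUb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()).tolist())
            for lev in levels[1:]:
                parts.append((s == lev).astype(float).rename(f"{col}[{lev}]"))
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


@dataclass(frozen=True)
class AnalysisDataset:
    """Outcome counts plus design information for the two model components."""

    outcome: np.ndarray
    count_design: pd.DataFrame
    inflate_design: pd.DataFrame
    group_column: str
    validate: bool = True       # False for counterfactual copies whose group
                                # column is intentionally constant

    def __post_init__(self) -> None:
        if not self.validate:
            return
        y = np.asarray(self.outcome)
        if y.ndim != 1 or len(y) == 0:
            raise ValidationError("outcome must be a non-empty 1-D array")
        if not np.issubdtype(y.dtype, np.integer):
            if not np.allclose(y, np.round(y)):
                bad = np.where(~np.isclose(y, np.round(y)))[0][:10]
                raise ValidationError(f"non-integer outcomes at rows {bad.tolist()}")
            y = np.round(y).astype(int)
            object.__setattr__(self, "outcome", y)
        if (y < 0).any():
            bad = np.where(y < 0)[0][:10]
            raise ValidationError(f"negative outcomes at rows {bad.tolist()}")
        if y.max() < 1:
            raise ValidationError("all-zero outcome: no count signal to model")
        for name, X in (("count", self.count_design), ("inflate", self.inflate_design)):
            if len(X) != len(y):
                raise ValidationError(f"{name}_design length mismatch")
            if X.isna().any().any():
                raise ValidationError(f"{name}_design contains missing values")
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                raise ValidationError(f"{name}_design is rank-deficient")
        for X, label in ((self.count_design, "count"), (self.inflate_design, "inflate")):
            if self.group_column not in X.columns:
                # group may legitimately be absent from one component
                logger.debug("group column %r absent from %s design", self.group_column, label)

    @property
    def n_subjects(self) -> int:
        return len(self.outcome)

    @property
    def group(self) -> np.ndarray:
        X = self.count_design if self.group_column in self.count_design else self.inflate_design
        return X[self.group_column].to_numpy()

    def take(self, indices: np.ndarray) -> "AnalysisDataset":
        """Row subset / resample (used by bootstrap and excess-zero removal)."""
        idx = np.asarray(indices)
        return replace(
            self,
            outcome=self.outcome[idx],
            count_design=self.count_design.iloc[idx].reset_index(drop=True),
            inflate_design=self.inflate_design.iloc[idx].reset_index(drop=True),
        )

    def binary_outcome(self) -> np.ndarray:
        """Outcome dichotomized as any-polyp vs none."""
        return (self.outcome > 0).astype(int)


def build_dataset(
    df: pd.DataFrame,
    outcome: str,
    group: str,
    count_covariates: tuple[str, ...] | list[str] = (),
    inflate_covariates: tuple[str, ...] | list[str] | None = None,
    topcode_at: int | None = None,
    group_in_inflate: bool = True,
) -> AnalysisDataset:
    """Assemble an :class:`AnalysisDataset` from a subject-level data frame.

    Complete-case filtering drops rows with missing values in any referenced
    column (the dropped count is logged, mirroring how missing BMI reduced
    the observational case study from 2,127 to 1,936 subjects).

    Parameters
    ----------
    inflate_covariates : optional
        Covariates for the zero-inflation component.  ``None`` means "same
        as the count component".  Pass ``[]`` for an intercept(+group)-only
        inflation part.
    topcode_at : optional int
        If set, counts at or above this value are merged (the primary
        case-study analyses merge counts of six or more).
    """
    for col in {outcome, group, *count_covariates, *(inflate_covariates or [])}:
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not found in data")
    if inflate_covariates is None:
        inflate_covariates = list(count_covariates)
    used = [outcome, group] + sorted({*count_covariates, *inflate_covariates})
    complete = df[used].dropna()
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("complete-case filter dropped %d of %d records", dropped, len(df))
    y = complete[outcome].to_numpy()
    if not np.allclose(y, np.round(y)) or (y < 0).any():
        bad = complete.index[(y < 0) | ~np.isclose(y, np.round(y))][:10]
        raise ValidationError(f"outcome must be non-negative integers; offending rows {list(bad)}")
    y = np.round(y).astype(int)
    if topcode_at is not None:
        y = topcode_counts(y, topcode_at)
    complete = complete.reset_index(drop=True)
    count_cols = [group] + list(count_covariates)
    inflate_cols = ([group] if group_in_inflate else []) + list(inflate_covariates)
    return AnalysisDataset(
        outcome=y,
        count_design=_encode(complete, count_cols),
        inflate_design=_encode(complete, inflate_cols),
        group_column=group,
    )
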