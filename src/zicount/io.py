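"""Configuration and CSV ingestion for subject-level polyp-count data.

Raw case-study files arrive as CSVs whose column names vary between
studies, so the mapping from file headers to outcome / group / covariate
roles is config-driven (YAML or keyword arguments) rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .data import AnalysisDataset, ValidationError, build_dataset

__all__ = ["RunConfig", "read_dataset", "write_dataset"]


@dataclass
class RunConfig:
    input_path: str
    outcome_column: str
    group_column: str
    count_covariates: list[str] = field(default_factory=list)
    inflate_covariates: list[str] | None = None
    topcode_at: int | None = 6
    model_list: list[str] = field(default_factory=lambda: ["LR", "PR", "NB", "ZIP", "ZHP"])
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.topcode_at is not None and self.topcode_at < 1:
            raise ValidationError("topcode_at must be >= 1 when set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def read_dataset(config: RunConfig) -> AnalysisDataset:
    """Load a CSV per the config: complete-case filtering, dummy coding,
    optional topcoding.  Non-integer or negative outcomes are rejected with
    the offending row numbers."""
    df = pd.read_csv(config.input_path)
    return build_dataset(
        df,
        outcome=config.outcome_column,
        group=config.group_column,
        count_covariates=tuple(config.count_covariates),
        inflate_covariates=(None if config.inflate_covariates is None
                            else tuple(config.inflate_covariates)),
        topcode_at=config.topcode_at,
    )


def write_dataset(data: AnalysisDataset, path: str | Path,
                  outcome_column: str = "count") -> None:
    """Write outcome + design columns back to CSV (round-trips with
    :func:`read_dataset` when the design is numeric)."""
    out = data.count_design.drop(columns=["const"], errors="ignore").copy()
    for col in data.inflate_design.columns:
        if col not in out.columns and col != "const":
            out[col] = data.inflate_design[col]
    out.insert(0, outcome_column, data.outcome)
    out.to_csv(path, index=False)
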