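"""Core in-memory containers shared across the pipeline.

Expression data lives in a thin wrapper around a pandas DataFrame
(features in rows, samples in columns) that tracks whether the values
are raw counts or normalized continuous measurements, because several
stages are only defined for one of the two (size factors need counts,
quantile normalization needs continuous values).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = (
    "sample_id",
    "os_days",
    "os_event",
    "sample_type",
    "stage",
    "age",
    "sex",
    "batch",
    "treatment",
)


class ValidationError(ValueError):
    """Input violates a semantic constraint (negative count, bad event flag...)."""


class FormatError(ValueError):
    """Input file is structurally malformed (duplicate ids, short GMT line...)."""


@dataclass
class ExpressionMatrix:
    """Features x samples numeric grid.

    kind = "counts" enforces non-negative integers; "normalized" allows any
    finite reals.
    """

    values: pd.DataFrame
    kind: str = "normalized"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "normalized"):
            raise ValidationError(f"unknown expression kind: {self.kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.kind == "counts":
            if (arr < 0).any():
                raise ValidationError("counts matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts matrix contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], kind=self.kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], kind=self.kind)


@dataclass
class ClinicalTable:
    """Per-sample survival and covariates.

    Required columns: sample_id, os_days, os_event, sample_type, stage, age,
    sex, batch, treatment. Unknowns are NA. Tumor samples (TP) carry survival;
    normal tissue (NT) rows may have it missing.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        df = self.data
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        ev = df["os_event"].dropna()
        if not ev.isin([0, 1]).all():
            bad = sorted(set(ev[~ev.isin([0, 1])]))
            raise ValidationError(f"os_event values outside {{0,1}}: {bad}")
        days = pd.to_numeric(df["os_days"], errors="coerce")
        if (days.dropna() <= 0).any():
            raise ValidationError("os_days must be positive where present")
        types = df["sample_type"].dropna()
        if not types.isin(["TP", "NT"]).all():
            bad = sorted(set(types[~types.isin(["TP", "NT"])]))
            raise ValidationError(f"sample_type must be TP or NT, got: {bad}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        keep = set(sample_ids)
        return ClinicalTable(self.data[self.data["sample_id"].isin(keep)].copy())

    def tumor_samples(self) -> "ClinicalTable":
        return ClinicalTable(self.data[self.data["sample_type"] == "TP"].copy())

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(time, event, sample_ids) for rows with complete survival."""
        df = self.data.dropna(subset=["os_days", "os_event"])
        return (
            df["os_days"].to_numpy(dtype=float),
            df["os_event"].to_numpy(dtype=int),
            list(df["sample_id"]),
        )


@dataclass(frozen=True)
class ValidatedPair:
    """One experimentally validated miRNA -> target gene relationship."""

    mirna_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.mirna_id or not self.gene_id:
            raise ValidationError("pair ids must be non-empty")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents): name -> set of member gene ids."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def restrict_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = frozenset(universe)
        return GeneSetCollection(
            {name: members & uni for name, members in self.sets.items()},
            dict(self.descriptions),
        )


@dataclass
class GroundTruth:
    """The simulator's planted prognostic structure, used as a recovery oracle."""

    signature_ids: list[str]
    true_beta: dict[str, float]
    true_threshold: dict[str, float]
    de_gene_ids: list[str]
    planted_pairs: list[ValidatedPair]

    def __post_init__(self) -> None:
        if set(self.signature_ids) != set(self.true_beta) or set(
            self.signature_ids
        ) != set(self.true_threshold):
            raise ValidationError("ground truth fields are inconsistent")
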