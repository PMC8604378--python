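"""Domain containers and CSV interchange for study-level effect data.

A :class:`StudyEffect` holds one study's contribution to a meta-analysis:
its log odds ratio ``y`` and the within-study standard error ``sigma``,
optionally backed by the raw 2x2 outcome counts.  A
:class:`ComorbidityDataset` groups the studies that enter a single
meta-analysis (one comorbidity versus HIV monoinfection).

Two CSV schemas are supported:

``effects``
    columns ``comorbidity, study_label, year, country, sample_size,
    outcome_type, log_or, se`` (the last two mandatory along with
    ``comorbidity`` and ``study_label``);

``counts``
    columns ``comorbidity, study_label, events_exposed, nonevents_exposed,
    events_comparator, nonevents_comparator``, from which the effects are
    recomputed.

Files are UTF-8, comma-separated, with a mandatory header row.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .effects import TwoByTwo, Z95, log_odds_ratio

__all__ = [
    "OUTCOME_TYPES",
    "SchemaError",
    "ValidationError",
    "StudyEffect",
    "ComorbidityDataset",
    "read_studies",
    "write_studies",
]

OUTCOME_TYPES = frozenset({"mortality", "hospitalization", "severe_critical"})

_EFFECTS_REQUIRED = ("comorbidity", "study_label", "log_or", "se")
_COUNTS_REQUIRED = (
    "comorbidity",
    "study_label",
    "events_exposed",
    "nonevents_exposed",
    "events_comparator",
    "nonevents_comparator",
)
_OPTIONAL = ("year", "country", "sample_size", "outcome_type")


class SchemaError(ValueError):
    """An input file does not conform to the declared CSV schema."""


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio and its within-study standard error.

    ``sigma`` is the standard error of ``y`` (so ``sigma**2`` is the
    within-study variance the models weight by).  When raw ``counts`` are
    supplied, ``y`` and ``sigma`` must agree with the values recomputed
    from them (Haldane-corrected when a cell is zero) to within 1e-12.
    """

    study_label: str
    y: float
    sigma: float
    year: int | None = None
    country: str | None = None
    sample_size: int | None = None
    outcome_type: str | None = None
    counts: TwoByTwo | None = None

    def __post_init__(self) -> None:
        if not self.study_label:
            raise ValidationError("study_label must be non-empty")
        if not np.isfinite(self.y):
            raise ValidationError(f"{self.study_label}: log odds ratio must be finite")
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise ValidationError(
                f"{self.study_label}: sigma must be a positive finite number, "
                f"got {self.sigma!r}"
            )
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValidationError(f"{self.study_label}: sample_size must be positive")
        if self.outcome_type is not None and self.outcome_type not in OUTCOME_TYPES:
            raise ValidationError(
                f"{self.study_label}: outcome_type {self.outcome_type!r} is not one "
                f"of {sorted(OUTCOME_TYPES)}"
            )
        if self.counts is not None:
            est = log_odds_ratio(self.counts, correction="haldane")
            if abs(est.y - self.y) > 1e-12 or abs(est.sigma - self.sigma) > 1e-12:
                raise ValidationError(
                    f"{self.study_label}: stored effect (y={self.y}, sigma={self.sigma}) "
                    f"does not match the value recomputed from counts "
                    f"(y={est.y}, sigma={est.sigma})"
                )

    @classmethod
    def from_counts(cls, study_label: str, counts: TwoByTwo, **meta) -> "StudyEffect":
        est = log_odds_ratio(counts, correction="haldane")
        if meta.get("sample_size") is None:
            meta["sample_size"] = counts.a + counts.b + counts.c + counts.d
        return cls(study_label=study_label, y=est.y, sigma=est.sigma, counts=counts, **meta)

    @property
    def variance(self) -> float:
        """Within-study variance ``sigma**2``."""
        return self.sigma**2

    @property
    def ci(self) -> tuple[float, float]:
        """95% Wald confidence interval for the study's log odds ratio."""
        return (self.y - Z95 * self.sigma, self.y + Z95 * self.sigma)


@dataclass(frozen=True)
class ComorbidityDataset:
    """An ordered, non-empty collection of studies for one meta-analysis."""

    name: str
    studies: tuple[StudyEffect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) == 0:
            raise ValidationError(f"dataset {self.name!r} has no studies")
        labels = [s.study_label for s in self.studies]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"dataset {self.name!r} has duplicate study labels: {dupes}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[StudyEffect]:
        return iter(self.studies)

    def __getitem__(self, index):
        return self.studies[index]

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def labels(self) -> list[str]:
        return [s.study_label for s in self.studies]

    @property
    def y(self) -> np.ndarray:
        return np.array([s.y for s in self.studies], dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return np.array([s.sigma for s in self.studies], dtype=float)

    @property
    def variances(self) -> np.ndarray:
        return self.sigma**2


def _require_columns(df: pd.DataFrame, required: Sequence[str], schema: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}' for schema '{schema}'")


def _opt(row, name, cast=None):
    if name not in row.index:
        return None
    value = row[name]
    if pd.isna(value):
        return None
    return cast(value) if cast is not None else value


def read_studies(path: str | Path, schema: str = "effects") -> list[ComorbidityDataset]:
    """Read a CSV of per-study data into one dataset per comorbidity.

    Row order within the file is preserved, as is the order of first
    appearance of each comorbidity.  With ``schema="counts"`` the log odds
    ratios and standard errors are recomputed from the 2x2 tables.
    """
    if schema not in ("effects", "counts"):
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _EFFECTS_REQUIRED if schema == "effects" else _COUNTS_REQUIRED, schema)

    grouped: dict[str, list[StudyEffect]] = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        meta = dict(
            year=_opt(row, "year", int),
            country=_opt(row, "country", str),
            sample_size=_opt(row, "sample_size", int),
            outcome_type=_opt(row, "outcome_type", str),
        )
        try:
            if schema == "effects":
                study = StudyEffect(
                    study_label=str(row["study_label"]),
                    y=float(row["log_or"]),
                    sigma=float(row["se"]),
                    **meta,
                )
            else:
                counts = TwoByTwo(
                    int(row["events_exposed"]),
                    int(row["nonevents_exposed"]),
                    int(row["events_comparator"]),
                    int(row["nonevents_comparator"]),
                )
                study = StudyEffect.from_counts(str(row["study_label"]), counts, **meta)
        except ValueError as exc:
            raise ValidationError(f"{path.name}, row {line}: {exc}") from exc
        grouped.setdefault(str(row["comorbidity"]), []).append(study)
    return [ComorbidityDataset(name=name, studies=tuple(studies)) for name, studies in grouped.items()]


def write_studies(
    datasets: Sequence[ComorbidityDataset], path: str | Path, schema: str = "effects"
) -> None:
    """Write datasets to CSV at full float precision.

    ``schema="effects"`` writes the log-OR/SE columns; ``schema="counts"``
    writes the raw 2x2 tables and requires every study to carry ``counts``.
    """
    if schema not in ("effects", "counts"):
        raise ValueError(f"unknown schema {schema!r}")
    rows = []
    for ds in datasets:
        for s in ds:
            row = dict(comorbidity=ds.name, study_label=s.study_label)
            if schema == "effects":
                row.update(
                    year=s.year,
                    country=s.country,
                    sample_size=s.sample_size,
                    outcome_type=s.outcome_type,
                    log_or=repr(s.y),
                    se=repr(s.sigma),
                )
            else:
                if s.counts is None:
                    raise ValidationError(
                        f"{s.study_label}: counts schema requires raw 2x2 counts"
                    )
                row.update(
                    events_exposed=s.counts.a,
                    nonevents_exposed=s.counts.b,
                    events_comparator=s.counts.c,
                    nonevents_comparator=s.counts.d,
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
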