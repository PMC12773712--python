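"""Variable curation and encoding for a participants x fields table.

Turns a raw typed table (continuous, integer and factor columns, plus a
long-format event-code file) into a fully numeric, fully observed design
matrix, applying the scan's curation rules:

* repeated measures: keep the first instance of each field;
* exclude factors with more than 50 levels (unless exempted) and columns
  missing in more than 15% of participants; special/negative codes are
  mapped to missing upstream of these checks;
* mean-impute continuous and integer columns;
* one 0/1 indicator per factor level observed above 0.2% frequency
  (missing is its own level and generates no indicator);
* one 0/1 indicator per event code above 0.2% frequency dated strictly
  before a cutoff;
* optional seeded down-sampling of controls.

Every input column receives exactly one disposition in the
:class:`EncodingReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import Dataset

__all__ = [
    "RawTable",
    "EncodingReport",
    "select_first_instance",
    "filter_variables",
    "impute_continuous",
    "encode_factors",
    "encode_event_codes",
    "downsample_controls",
    "build_dataset",
]

MAX_MISSING = 0.15
MAX_LEVELS = 50
MIN_FREQ = 0.002

#: metadata columns: type in {continuous, integer, factor}, field (base
#: field id shared by repeated measures), instance (int), exempt_levels
#: (bool, lifts the factor-level cap)
META_COLUMNS = ("type", "field", "instance", "exempt_levels")


@dataclass
class RawTable:
    """One row per participant; ``meta`` describes each data column."""

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("one row per participant required")
        missing_meta = set(self.data.columns) - set(self.meta.index)
        if missing_meta:
            raise ValueError(f"columns without metadata: {sorted(missing_meta)}")
        for c in META_COLUMNS:
            if c not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {c!r}")
        bad = set(self.meta.loc[list(self.data.columns), "type"]) - {
            "continuous", "integer", "factor"
        }
        if bad:
            raise ValueError(f"unknown column types: {sorted(bad)}")

    def subset(self, columns: list[str]) -> "RawTable":
        return RawTable(self.data[columns], self.meta.loc[columns].copy())


@dataclass
class EncodingReport:
    """Per-input-column disposition plus imputation summaries."""

    dispositions: list[tuple[str, str, str]] = field(default_factory=list)
    imputation: dict[str, float] = field(default_factory=dict)

    def record(self, column: str, disposition: str, detail: str = "") -> None:
        self.dispositions.append((column, disposition, detail))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dispositions, columns=["column", "disposition", "detail"]
        )


def select_first_instance(raw: RawTable, report: EncodingReport | None = None) -> RawTable:
    """Keep the lowest-instance column of every field."""
    first: dict[str, str] = {}
    for col in raw.data.columns:
        f = raw.meta.loc[col, "field"]
        if f not in first or raw.meta.loc[col, "instance"] < raw.meta.loc[first[f], "instance"]:
            first[f] = col
    keep = [c for c in raw.data.columns if first[raw.meta.loc[c, "field"]] == c]
    if report is not None:
        for c in raw.data.columns:
            if c not in keep:
                report.record(c, "excluded", "repeated measure: not first instance")
    return raw.subset(keep)


def filter_variables(
    raw: RawTable,
    max_missing: float = MAX_MISSING,
    max_levels: int = MAX_LEVELS,
    report: EncodingReport | None = None,
) -> RawTable:
    """Drop columns missing in more than ``max_missing`` of participants and
    factors with more than ``max_levels`` observed levels (exemptions allowed).

    Both rules are strict inequalities: a column missing in exactly 15% of
    participants, or a factor with exactly 50 levels, is kept.
    """
    keep = []
    for col in raw.data.columns:
        miss = raw.data[col].isna().mean()
        if miss > max_missing:
            if report is not None:
                report.record(col, "excluded", f"missing fraction {miss:.3f} > {max_missing}")
            continue
        if raw.meta.loc[col, "type"] == "factor" and not raw.meta.loc[col, "exempt_levels"]:
            n_levels = raw.data[col].dropna().nunique()
            if n_levels > max_levels:
                if report is not None:
                    report.record(col, "excluded", f"{n_levels} levels > {max_levels}")
                continue
        keep.append(col)
    return raw.subset(keep)


def impute_continuous(raw: RawTable, report: EncodingReport | None = None) -> RawTable:
    """Replace missing continuous/integer entries by the column mean of
    nonmissing values (no rounding for integer columns)."""
    data = raw.data.copy()
    for col in data.columns:
        if raw.meta.loc[col, "type"] not in ("continuous", "integer"):
            continue
        series = pd.to_numeric(data[col])
        if series.isna().all():
            raise ValueError(f"column {col!r} is entirely missing; exclude upstream")
        if series.isna().any():
            m = float(series.mean())
            data[col] = series.fillna(m)
            if report is not None:
                report.imputation[col] = m
        else:
            data[col] = series
    return RawTable(data, raw.meta.copy())


def encode_factors(
    raw: RawTable,
    min_freq: float = MIN_FREQ,
    report: EncodingReport | None = None,
) -> pd.DataFrame:
    """One 0/1 indicator per factor level above the frequency floor.

    Frequencies are computed over all retained participants; missing is a
    separate level that never generates an indicator.  All levels of a
    factor qualify independently, so a binary factor yields two (mutually
    complementary) indicators.
    """
    n = len(raw.data)
    out: dict[str, np.ndarray] = {}
    for col in raw.data.columns:
        if raw.meta.loc[col, "type"] != "factor":
            continue
        series = raw.data[col]
        counts = series.value_counts(dropna=True)
        kept_levels = [lv for lv, c in counts.items() if c / n > min_freq]
        for lv in sorted(kept_levels, key=str):
            out[f"{col}:{lv}"] = (series == lv).to_numpy(dtype=float)
        if report is not None:
            report.record(
                col,
                "expanded",
                f"{len(kept_levels)} of {counts.size} levels above {min_freq:.1%}",
            )
    return pd.DataFrame(out, index=raw.data.index)


def encode_event_codes(
    events: pd.DataFrame,
    participants: pd.Index,
    min_freq: float = MIN_FREQ,
    cutoff_date: str | pd.Timestamp = "2020-01-01",
    report: EncodingReport | None = None,
) -> pd.DataFrame:
    """Indicator per event code above the frequency floor, counting only
    events dated strictly before the cutoff.

    ``events`` is long-format with columns (participant, code, date);
    undated events are excluded with a warning.  Frequencies use the
    retained participant set as denominator.
    """
    for c in ("participant", "code", "date"):
        if c not in events.columns:
            raise ValueError(f"events table lacks column {c!r}")
    ev = events.copy()
    undated = ev["date"].isna()
    if undated.any():
        warnings.warn(f"{int(undated.sum())} undated event(s) excluded", stacklevel=2)
        ev = ev[~undated]
    ev = ev[pd.to_datetime(ev["date"]) < pd.Timestamp(cutoff_date)]
    ev = ev[ev["participant"].isin(participants)]
    n = len(participants)
    out: dict[str, np.ndarray] = {}
    for code, grp in ev.groupby("code"):
        carriers = grp["participant"].unique()
        if len(carriers) / n > min_freq:
            out[str(code)] = participants.isin(carriers).astype(float)
            if report is not None:
                report.record(str(code), "event-code", f"{len(carriers)} carriers")
        elif report is not None:
            report.record(
                str(code), "excluded", f"frequency {len(carriers) / n:.4%} <= {min_freq:.1%}"
            )
    return pd.DataFrame(out, index=participants)


def downsample_controls(data: Dataset, n_controls: int, seed: int) -> Dataset:
    """Keep every case and a uniform seeded subsample of controls."""
    controls = np.where(data.y == 0)[0]
    cases = np.where(data.y == 1)[0]
    if n_controls > controls.size:
        raise ValueError(f"only {controls.size} controls available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(controls, size=n_controls, replace=False)
    idx = np.sort(np.concatenate([cases, chosen]))
    return Dataset(data.X[idx], data.y[idx], list(data.names))


def build_dataset(
    raw: RawTable,
    outcome: pd.Series,
    events: pd.DataFrame | None = None,
    *,
    max_missing: float = MAX_MISSING,
    max_levels: int = MAX_LEVELS,
    min_freq: float = MIN_FREQ,
    cutoff_date: str | pd.Timestamp = "2020-01-01",
) -> tuple[Dataset, EncodingReport]:
    """Full curation pipeline: first-instance selection, exclusion rules,
    mean imputation, factor and event-code encoding -> model-ready Dataset.

    ``outcome`` must be a 0/1 series aligned to the participants; it is
    not part of the design.
    """
    report = EncodingReport()
    raw = select_first_instance(raw, report)
    raw = filter_variables(raw, max_missing, max_levels, report)
    raw = impute_continuous(raw, report)

    numeric_cols = [
        c for c in raw.data.columns if raw.meta.loc[c, "type"] in ("continuous", "integer")
    ]
    for c in numeric_cols:
        report.record(c, "kept", "numeric covariate")
    blocks = [raw.data[numeric_cols].astype(float)]
    blocks.append(encode_factors(raw, min_freq, report))
    if events is not None:
        blocks.append(
            encode_event_codes(events, raw.data.index, min_freq, cutoff_date, report)
        )
    X = pd.concat([b for b in blocks if b.shape[1]], axis=1)
    y = outcome.loc[X.index].to_numpy(dtype=float)
    data = Dataset(X.to_numpy(dtype=float), y, list(X.columns))
    return data, report
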