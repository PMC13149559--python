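"""Cohort-based outlier splicing detection with Tukey fences.

Per junction, a background distribution of percent-spliced (PS) values is
summarised by its quartiles; a query sample's PS is an outlier when it
falls strictly outside the fences Q1 - 1.5*IQR / Q3 + 1.5*IQR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .junctions import PSMatrix, SpliceJunction

__all__ = [
    "BackgroundDistribution",
    "OutlierCall",
    "build_background",
    "call_outliers",
    "cohort_usage_summary",
    "QUANTILE_RULES",
]

FENCE_FACTOR = 1.5

QUANTILE_RULES = ("linear", "tukey_hinges", "nearest")


def _quartiles(values: np.ndarray, rule: str) -> tuple[float, float]:
    if rule == "linear":
        q1, q3 = np.quantile(values, [0.25, 0.75])
    elif rule == "nearest":
        q1, q3 = np.quantile(values, [0.25, 0.75], method="nearest")
    elif rule == "tukey_hinges":
        ordered = np.sort(values)
        n = ordered.size
        half = (n + 1) // 2  # lower half includes the median when n is odd
        q1 = float(np.median(ordered[:half]))
        q3 = float(np.median(ordered[n - half :]))
    else:
        raise ValueError(f"unknown quantile rule {rule!r}; choose from {QUANTILE_RULES}")
    return float(q1), float(q3)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Quartile summary of a junction's cohort PS values."""

    junction: SpliceJunction
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    n_used: int
    evaluable: bool

    def __post_init__(self) -> None:
        if self.evaluable:
            if not self.q1 <= self.q3:
                raise ValueError("q1 must not exceed q3")
            if self.lower_fence > self.q1 or self.upper_fence < self.q3:
                raise ValueError("fences must bracket the quartiles")


@dataclass(frozen=True)
class OutlierCall:
    """Verdict for one junction in one query sample.

    ``direction`` is ``up`` / ``down`` for values strictly outside the
    fences, ``none`` inside or exactly on them, ``not_evaluable`` when the
    query PS is missing or the background could not be built.
    """

    junction: SpliceJunction
    sample: str
    ps: float  # NaN when missing
    direction: str
    lower_fence: float
    upper_fence: float

    def __post_init__(self) -> None:
        if self.direction == "up" and not self.ps > self.upper_fence:
            raise ValueError("direction=up requires ps > upper_fence")
        if self.direction == "down" and not self.ps < self.lower_fence:
            raise ValueError("direction=down requires ps < lower_fence")


def build_background(
    cohort: PSMatrix,
    min_samples: int = 20,
    quantile_rule: str = "linear",
    missing_as_zero: bool = False,
) -> list[BackgroundDistribution]:
    """Summarise every junction's cohort PS distribution.

    Missing PS values are dropped by default (``missing_as_zero=True``
    counts an unobserved junction as PS 0 instead).  A junction with
    fewer than ``min_samples`` usable values is flagged not evaluable.
    """
    if len(cohort.samples) == 0:
        raise ValueError("empty cohort")
    if len(cohort.samples) < min_samples:
        raise ValueError(
            f"cohort has {len(cohort.samples)} samples; min_samples={min_samples}"
        )
    out: list[BackgroundDistribution] = []
    for junction in cohort.junctions:
        values = cohort.ps.loc[junction].to_numpy(dtype=float)
        if missing_as_zero:
            values = np.nan_to_num(values, nan=0.0)
        values = values[np.isfinite(values)]
        if values.size < min_samples:
            out.append(
                BackgroundDistribution(
                    junction, np.nan, np.nan, np.nan, np.nan, np.nan,
                    int(values.size), evaluable=False,
                )
            )
            continue
        q1, q3 = _quartiles(values, quantile_rule)
        iqr = q3 - q1
        out.append(
            BackgroundDistribution(
                junction,
                q1,
                q3,
                iqr,
                q1 - FENCE_FACTOR * iqr,
                q3 + FENCE_FACTOR * iqr,
                int(values.size),
                evaluable=True,
            )
        )
    return out


def call_outliers(
    sample_ps: pd.Series,
    background: Sequence[BackgroundDistribution],
    sample: str | None = None,
) -> list[OutlierCall]:
    """Compare one sample's PS values with background fences.

    ``sample_ps`` is a PS-matrix column indexed by junction.  Junctions
    present in the query but absent from the background (and vice versa)
    are reported as ``not_evaluable`` rather than silently dropped.
    Comparisons use strict inequality, so a value exactly on a fence is
    not an outlier.
    """
    sample = sample if sample is not None else str(sample_ps.name)
    calls: list[OutlierCall] = []
    seen: set[SpliceJunction] = set()
    for bg in background:
        seen.add(bg.junction)
        ps = float(sample_ps.get(bg.junction, np.nan))
        if not bg.evaluable or not np.isfinite(ps):
            calls.append(
                OutlierCall(bg.junction, sample, ps, "not_evaluable",
                            bg.lower_fence, bg.upper_fence)
            )
            continue
        if ps > bg.upper_fence:
            direction = "up"
        elif ps < bg.lower_fence:
            direction = "down"
        else:
            direction = "none"
        calls.append(
            OutlierCall(bg.junction, sample, ps, direction,
                        bg.lower_fence, bg.upper_fence)
        )
    for junction in sample_ps.index:
        if junction not in seen:
            calls.append(
                OutlierCall(junction, sample, float(sample_ps[junction]),
                            "not_evaluable", np.nan, np.nan)
            )
    return calls


def call_outliers_from_matrix(
    cohort: PSMatrix,
    query: PSMatrix,
    query_sample: str,
    min_samples: int = 20,
    quantile_rule: str = "linear",
    missing_as_zero: bool = False,
) -> list[OutlierCall]:
    """Build the background from ``cohort`` and call ``query_sample``.

    The query sample must not be part of the background cohort.
    """
    if query_sample in cohort.samples:
        raise ValueError(
            f"query sample {query_sample!r} is part of the background cohort"
        )
    background = build_background(cohort, min_samples, quantile_rule, missing_as_zero)
    return call_outliers(query.sample_column(query_sample), background, query_sample)


def cohort_usage_summary(
    cohort: PSMatrix, junction: SpliceJunction
) -> dict[str, float]:
    """Fraction of cohort samples using a junction, and its maximum PS.

    A sample *uses* the junction when its PS is defined and > 0; a
    missing PS counts as not using.  ``max_ps`` is NaN when every value
    is missing.
    """
    if junction not in cohort.ps.index:
        raise KeyError(f"junction {junction.name} not in PS matrix")
    values = cohort.ps.loc[junction].to_numpy(dtype=float)
    defined = values[np.isfinite(values)]
    n = values.size
    fraction = float((defined > 0).sum()) / n if n else np.nan
    max_ps = float(defined.max()) if defined.size else np.nan
    return {"fraction_samples_using": fraction, "max_ps": max_ps}


def background_to_frame(background: Iterable[BackgroundDistribution]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "junction": bg.junction.name,
                "q1": bg.q1,
                "q3": bg.q3,
                "iqr": bg.iqr,
                "lower_fence": bg.lower_fence,
                "upper_fence": bg.upper_fence,
                "n_used": bg.n_used,
                "evaluable": bg.evaluable,
            }
            for bg in background
        ]
    )


def calls_to_frame(calls: Iterable[OutlierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "junction": c.junction.name,
                "sample": c.sample,
                "ps": c.ps,
                "direction": c.direction,
                "lower_fence": c.lower_fence,
                "upper_fence": c.upper_fence,
            }
            for c in calls
        ]
    )


def write_background_tsv(
    background: Iterable[BackgroundDistribution], path: str | Path
) -> None:
    background_to_frame(background).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_calls_tsv(calls: Iterable[OutlierCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, na_rep="NA")
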