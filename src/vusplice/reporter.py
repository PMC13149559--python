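"""Splicing-reporter PSI quantification and group statistics.

Fragment-analysis peaks are assigned to the exon-included and exon-skipped
amplicon sizes; PSI = 100 * included / (included + skipped) per replicate.
Condition effects are tested with a one-way fixed-effects ANOVA and
Dunnett's many-to-one post-hoc comparisons, whose family-wise adjustment
is computed from a seeded Monte-Carlo estimate of the joint max-|t| null
distribution (works for unbalanced designs without table lookup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FragmentPeak",
    "ReporterReplicate",
    "PSIResult",
    "DunnettResult",
    "assign_peaks",
    "compute_psi",
    "quantify_replicates",
    "one_way_anova",
    "dunnett_test",
]


@dataclass(frozen=True)
class FragmentPeak:
    size_nt: float
    signal: float

    def __post_init__(self) -> None:
        if self.size_nt <= 0:
            raise ValueError("peak size must be positive")
        if self.signal < 0:
            raise ValueError("peak signal must be non-negative")


@dataclass(frozen=True)
class ReporterReplicate:
    condition: str
    replicate: str
    peaks: tuple[FragmentPeak, ...]


@dataclass(frozen=True)
class PSIResult:
    """Per-condition PSI summary on the 0-100 scale."""

    condition: str
    psi_values: tuple[float, ...]
    mean: float
    sd: float


@dataclass(frozen=True)
class DunnettResult:
    comparison: str  # "<condition> vs <control>"
    mean_difference: float
    t_statistic: float
    p_unadjusted: float
    p_adjusted: float
    f_statistic: float
    anova_p: float
    mc_reps: int
    seed: int


class PeakAssignmentError(ValueError):
    pass


def assign_peaks(
    replicate: ReporterReplicate,
    included_size: float,
    skipped_size: float,
    tolerance_nt: float = 5.0,
) -> dict[str, object]:
    """Sum peak signal per isoform by nearest expected amplicon size.

    A peak is assigned to the expected size it is nearest to, provided it
    lies within ``tolerance_nt``; peaks outside both windows are returned
    unassigned.  The two expected sizes must differ by more than twice the
    tolerance so the windows cannot overlap.
    """
    if abs(included_size - skipped_size) <= 2 * tolerance_nt:
        raise PeakAssignmentError(
            f"amplicon sizes {included_size} and {skipped_size} closer than "
            f"2 x tolerance ({tolerance_nt} nt): assignment windows overlap"
        )
    included_signal = 0.0
    skipped_signal = 0.0
    unassigned: list[FragmentPeak] = []
    for peak in replicate.peaks:
        d_inc = abs(peak.size_nt - included_size)
        d_skip = abs(peak.size_nt - skipped_size)
        if d_inc <= tolerance_nt and d_inc <= d_skip:
            included_signal += peak.signal
        elif d_skip <= tolerance_nt:
            skipped_signal += peak.signal
        else:
            unassigned.append(peak)
    return {
        "included_signal": included_signal,
        "skipped_signal": skipped_signal,
        "unassigned": tuple(unassigned),
    }


def compute_psi(included_signal: float, skipped_signal: float) -> float:
    """PSI percent = 100 * inc / (inc + skip); NaN when both signals are 0."""
    total = included_signal + skipped_signal
    if total <= 0:
        return float("nan")
    return 100.0 * included_signal / total


def quantify_replicates(
    replicates: Iterable[ReporterReplicate],
    included_size: float,
    skipped_size: float,
    tolerance_nt: float = 5.0,
) -> tuple[list[PSIResult], pd.DataFrame]:
    """Per-replicate PSI and per-condition mean +/- SD.

    Returns the condition summaries and a tidy per-replicate frame
    (condition, replicate, psi, unassigned peak count).
    """
    rows = []
    for rep in replicates:
        assigned = assign_peaks(rep, included_size, skipped_size, tolerance_nt)
        psi = compute_psi(assigned["included_signal"], assigned["skipped_signal"])
        rows.append(
            {
                "condition": rep.condition,
                "replicate": rep.replicate,
                "psi": psi,
                "n_unassigned": len(assigned["unassigned"]),
            }
        )
    frame = pd.DataFrame(rows)
    results = []
    for condition, group in frame.groupby("condition", sort=False):
        values = group["psi"].dropna().to_numpy()
        results.append(
            PSIResult(
                condition,
                tuple(float(v) for v in values),
                float(values.mean()) if values.size else float("nan"),
                float(values.std(ddof=1)) if values.size > 1 else float("nan"),
            )
        )
    return results, frame


def _group_arrays(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 values")
        out[label] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> dict[str, float | bool]:
    """Classical one-way fixed-effects F test from the SS decomposition.

    Degenerate inputs (zero within- and between-group variance) return
    F = 0, p = 1 with ``degenerate`` set.
    """
    arrays = _group_arrays(groups)
    if len(arrays) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    all_values = np.concatenate(list(arrays.values()))
    grand_mean = all_values.mean()
    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_values.size - len(arrays)
    if ss_within == 0 and ss_between == 0:
        return {"F": 0.0, "p": 1.0, "df_between": df_between,
                "df_within": df_within, "degenerate": True}
    if ss_within == 0:
        return {"F": float("inf"), "p": 0.0, "df_between": df_between,
                "df_within": df_within, "degenerate": True}
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return {"F": float(f_stat), "p": p, "df_between": df_between,
            "df_within": df_within, "degenerate": False}


def _max_abs_t_null(
    ns: Sequence[int], n_control: int, df: int, mc_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of max_i |T_i| under the joint Dunnett null.

    T_i = (Zbar_i - Zbar_0) / (S * sqrt(1/n_i + 1/n_0)) with one shared
    control mean and one shared pooled-variance factor S ~ sqrt(chi2_df/df).
    """
    k = len(ns)
    z_treat = rng.standard_normal((mc_reps, k)) / np.sqrt(np.asarray(ns, float))
    z_control = rng.standard_normal((mc_reps, 1)) / np.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, size=(mc_reps, 1)) / df)
    scale = np.sqrt(1.0 / np.asarray(ns, float) + 1.0 / n_control)
    t = (z_treat - z_control) / (s * scale)
    return np.abs(t).max(axis=1)


def dunnett_test(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> list[DunnettResult]:
    """Two-sided many-to-one comparisons against a control group.

    Per-comparison t statistics use the variance pooled across *all*
    groups (ANOVA residual).  The family-wise adjusted p for comparison
    *i* is the add-one Monte-Carlo estimate of P(max_j |T_j| >= |t_i|)
    under the joint null, clipped from below by the unadjusted p so the
    single-step coherence (adjusted >= unadjusted) holds exactly.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    control = arrays.pop(control_label)
    if control.size < 2:
        raise ValueError("control group must have >= 2 values")
    if not arrays:
        raise ValueError("need at least one treatment group")
    for label, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 values")
    if mc_reps < 10_000:
        warnings.warn(
            f"mc_reps={mc_reps} < 10000: adjusted p-values will be noisy",
            stacklevel=2,
        )

    anova = one_way_anova({control_label: control, **arrays})
    all_groups = [control, *arrays.values()]
    n_total = sum(a.size for a in all_groups)
    df = n_total - len(all_groups)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in all_groups)
    pooled_var = ss_within / df if df > 0 else float("nan")

    labels = list(arrays)
    ns = [arrays[label].size for label in labels]
    diffs = np.array([arrays[label].mean() - control.mean() for label in labels])
    scale = np.sqrt(pooled_var) * np.sqrt(
        1.0 / np.asarray(ns, float) + 1.0 / control.size
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(scale > 0, diffs / scale, np.where(diffs == 0, 0.0, np.inf))
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)

    rng = np.random.default_rng(seed)
    max_t = _max_abs_t_null(ns, control.size, df, mc_reps, rng)
    results = []
    for i, label in enumerate(labels):
        exceed = int((max_t >= abs(t_obs[i])).sum())
        p_adj = (exceed + 1) / (mc_reps + 1)
        p_adj = min(1.0, max(p_adj, float(p_unadj[i])))
        results.append(
            DunnettResult(
                comparison=f"{label} vs {control_label}",
                mean_difference=float(diffs[i]),
                t_statistic=float(t_obs[i]),
                p_unadjusted=float(p_unadj[i]),
                p_adjusted=float(p_adj),
                f_statistic=float(anova["F"]),
                anova_p=float(anova["p"]),
                mc_reps=mc_reps,
                seed=seed,
            )
        )
    return results


# --------------------------------------------------------------------------
# I/O

def read_peak_csv(path: str | Path) -> list[ReporterReplicate]:
    """Read a CSV with columns condition, replicate, size_nt, signal."""
    df = pd.read_csv(path)
    required = {"condition", "replicate", "size_nt", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    replicates = []
    for (condition, replicate), group in df.groupby(
        ["condition", "replicate"], sort=False
    ):
        peaks = tuple(
            FragmentPeak(float(row.size_nt), float(row.signal))
            for row in group.itertuples()
        )
        replicates.append(ReporterReplicate(str(condition), str(replicate), peaks))
    return replicates


def write_peak_csv(replicates: Iterable[ReporterReplicate], path: str | Path) -> None:
    rows = [
        {
            "condition": rep.condition,
            "replicate": rep.replicate,
            "size_nt": peak.size_nt,
            "signal": peak.signal,
        }
        for rep in replicates
        for peak in rep.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def psi_results_to_frame(results: Iterable[PSIResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition": r.condition,
                "n": len(r.psi_values),
                "mean_psi": r.mean,
                "sd_psi": r.sd,
            }
            for r in results
        ]
    )


def dunnett_results_to_frame(results: Iterable[DunnettResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": r.comparison,
                "mean_difference": r.mean_difference,
                "t": r.t_statistic,
                "p_unadjusted": r.p_unadjusted,
                "p_adjusted": r.p_adjusted,
                "F": r.f_statistic,
                "anova_p": r.anova_p,
                "mc_reps": r.mc_reps,
                "seed": r.seed,
            }
            for r in results
        ]
    )
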