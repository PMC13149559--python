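"""Dihydroceramide/ceramide (DHCer/Cer) ratio analysis.

The DHCer/Cer ratio per acyl chain reads out DES1 desaturase activity:
substrate over product.  Technical replicates are averaged within a
sample first (avoiding pseudo-replication), ratios are expressed as fold
elevation over the control-group mean (controls are 1 by construction),
and group differences use a pooled two-tailed Student's t test at the
conventional 0.05 cutoff.  No multiple-testing correction is applied
across lipid species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LipidSpecies",
    "LipidPanel",
    "SpeciesRatioResult",
    "dhcer_cer_ratios",
    "fold_over_control",
    "student_t_two_tailed",
    "analyze_panel",
    "summarize_panel",
]

BACKBONE_CLASSES = ("DHCer", "Cer")
_CHAIN_RE = re.compile(r"^C(\d+):(\d+)$")


@dataclass(frozen=True)
class LipidSpecies:
    """One measured species: backbone class x acyl chain, e.g. DHCer C24:1."""

    backbone_class: str
    chain: str

    def __post_init__(self) -> None:
        if self.backbone_class not in BACKBONE_CLASSES:
            raise ValueError(f"backbone class must be one of {BACKBONE_CLASSES}")
        if not _CHAIN_RE.match(self.chain):
            raise ValueError(f"chain {self.chain!r} must match C<carbons>:<double bonds>")

    @property
    def carbons(self) -> int:
        return int(_CHAIN_RE.match(self.chain).group(1))

    @property
    def double_bonds(self) -> int:
        return int(_CHAIN_RE.match(self.chain).group(2))


class LipidPanel:
    """Tidy concentration table.

    Columns: sample, group (proband/control), backbone_class, chain,
    replicate, concentration.  Concentrations are >= 0; every
    (sample, class, chain) has at least one technical replicate.
    """

    COLUMNS = ("sample", "group", "backbone_class", "chain", "replicate",
               "concentration")

    def __init__(self, measurements: pd.DataFrame):
        missing = set(self.COLUMNS) - set(measurements.columns)
        if missing:
            raise ValueError(f"lipid panel missing columns {sorted(missing)}")
        if (measurements["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        bad = set(measurements["backbone_class"]) - set(BACKBONE_CLASSES)
        if bad:
            raise ValueError(f"unknown backbone class(es): {sorted(bad)}")
        for chain in measurements["chain"].unique():
            LipidSpecies("Cer", chain)  # validates the chain label
        self.measurements = measurements.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LipidPanel":
        df = pd.read_csv(path)
        rename = {"class": "backbone_class"}
        return cls(df.rename(columns=rename))

    def to_csv(self, path: str | Path) -> None:
        self.measurements.to_csv(path, index=False)

    @property
    def groups(self) -> dict[str, str]:
        return dict(
            self.measurements.drop_duplicates("sample")[["sample", "group"]].values
        )

    def sample_means(self) -> pd.DataFrame:
        """Average technical replicates within each (sample, class, chain)."""
        return (
            self.measurements.groupby(
                ["sample", "group", "backbone_class", "chain"], sort=False
            )["concentration"]
            .mean()
            .reset_index()
        )


@dataclass(frozen=True)
class SpeciesRatioResult:
    chain: str
    sample_ratios: dict[str, float]
    control_mean_ratio: float
    proband_folds: dict[str, float]
    t_statistic: float
    df: int
    p_value: float
    significant: bool
    group_mean_sd: dict[str, tuple[float, float]]
    flags: tuple[str, ...] = ()


def dhcer_cer_ratios(panel: LipidPanel) -> pd.DataFrame:
    """Per-sample per-chain DHCer/Cer ratio of replicate-mean concentrations.

    Returns columns sample, group, chain, ratio, flag.  A zero or missing
    Cer (or missing DHCer) leaves the ratio NaN with an explicit flag —
    never silently dropped.
    """
    means = panel.sample_means()
    wide = means.pivot_table(
        index=["sample", "group", "chain"],
        columns="backbone_class",
        values="concentration",
        aggfunc="first",
    ).reset_index()
    rows = []
    for row in wide.itertuples():
        dhcer = getattr(row, "DHCer", np.nan)
        cer = getattr(row, "Cer", np.nan)
        flag = ""
        if not np.isfinite(dhcer):
            ratio, flag = np.nan, "missing_DHCer"
        elif not np.isfinite(cer):
            ratio, flag = np.nan, "missing_Cer"
        elif cer == 0:
            ratio, flag = np.nan, "zero_Cer"
        else:
            ratio = dhcer / cer
        rows.append(
            {"sample": row.sample, "group": row.group, "chain": row.chain,
             "ratio": ratio, "flag": flag}
        )
    return pd.DataFrame(rows)


def fold_over_control(
    ratios: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Fold of each sample's ratio over the control-group mean ratio.

    The control group's own mean fold is 1 by construction.  A chain with
    no defined control ratio (or control mean 0) yields NaN folds.
    """
    out = ratios.copy()
    out["fold"] = np.nan
    for chain, group in ratios.groupby("chain"):
        controls = group.loc[group["group"] == control_group, "ratio"].dropna()
        if controls.empty:
            continue
        control_mean = controls.mean()
        if control_mean == 0:
            continue
        out.loc[group.index, "fold"] = group["ratio"] / control_mean
    return out


def student_t_two_tailed(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> dict[str, float | bool]:
    """Two-tailed Student's t (pooled variance; Welch optional).

    Zero pooled variance with equal means gives t = 0, p = 1 with a
    degenerate flag; with unequal means, |t| is infinite and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    df = a.size + b.size - 2
    pooled_var = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if not welch and pooled_var == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": df, "p": 1.0, "degenerate": True}
        return {"t": float(np.sign(a.mean() - b.mean()) * np.inf), "df": df,
                "p": 0.0, "degenerate": True}
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        t = (a.mean() - b.mean()) / np.sqrt(pooled_var * (1 / a.size + 1 / b.size))
        p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p), "degenerate": False}


def analyze_panel(
    panel: LipidPanel,
    control_group: str = "control",
    proband_group: str = "proband",
    alpha: float = 0.05,
    welch: bool = False,
    test_on: str = "ratio",
) -> list[SpeciesRatioResult]:
    """Full per-chain analysis: ratios, folds, and proband-vs-control test.

    ``test_on`` selects the tested quantity: ``"ratio"`` compares
    per-sample DHCer/Cer ratios (default), ``"concentration"`` compares
    DHCer concentrations; each output row is labelled accordingly.
    """
    if test_on not in {"ratio", "concentration"}:
        raise ValueError("test_on must be 'ratio' or 'concentration'")
    ratios = dhcer_cer_ratios(panel)
    folds = fold_over_control(ratios, control_group)
    means = panel.sample_means()
    results = []
    chains = sorted(
        ratios["chain"].unique(),
        key=lambda c: (LipidSpecies("Cer", c).carbons,
                       LipidSpecies("Cer", c).double_bonds),
    )
    for chain in chains:
        chain_rows = folds[folds["chain"] == chain]
        flags = tuple(f for f in chain_rows["flag"] if f)
        if test_on == "ratio":
            tested = chain_rows
            values = tested.set_index("sample")["ratio"]
        else:
            tested = means[(means["chain"] == chain)
                           & (means["backbone_class"] == "DHCer")]
            values = tested.set_index("sample")["concentration"]
            tested = tested.rename(columns={"concentration": "ratio"})
        control_vals = values[
            tested.set_index("sample")["group"] == control_group
        ].dropna()
        proband_vals = values[
            tested.set_index("sample")["group"] == proband_group
        ].dropna()
        if control_vals.size >= 2 and proband_vals.size >= 2:
            test = student_t_two_tailed(proband_vals, control_vals, welch=welch)
        else:
            test = {"t": np.nan, "df": np.nan, "p": np.nan, "degenerate": True}
        control_ratios = chain_rows.loc[
            chain_rows["group"] == control_group, "ratio"
        ].dropna()
        proband_folds = {
            row.sample: float(row.fold)
            for row in chain_rows.itertuples()
            if row.group == proband_group
        }
        group_stats = {}
        for grp, sub in values.groupby(tested.set_index("sample")["group"]):
            clean = sub.dropna()
            group_stats[grp] = (
                float(clean.mean()) if clean.size else np.nan,
                float(clean.std(ddof=1)) if clean.size > 1 else np.nan,
            )
        p = test["p"]
        results.append(
            SpeciesRatioResult(
                chain=chain,
                sample_ratios={
                    row.sample: float(row.ratio) for row in chain_rows.itertuples()
                },
                control_mean_ratio=(
                    float(control_ratios.mean()) if control_ratios.size else np.nan
                ),
                proband_folds=proband_folds,
                t_statistic=float(test["t"]),
                df=int(test["df"]) if np.isfinite(test["df"]) else 0,
                p_value=float(p) if p is not None else np.nan,
                significant=bool(np.isfinite(p) and p < alpha),
                group_mean_sd=group_stats,
                flags=flags,
            )
        )
    return results


def summarize_panel(
    panel: LipidPanel,
    results: Iterable[SpeciesRatioResult],
    control_group: str = "control",
) -> pd.DataFrame:
    """Report rows: per chain x backbone class x group mean +/- SD of the
    sample-level concentrations, plus folds and significance.

    Rows are ordered by class, carbon count, then unsaturation; an SD is
    NaN when a group has a single sample (n = 1).
    """
    means = panel.sample_means()
    result_by_chain = {r.chain: r for r in results}
    rows = []
    for backbone in BACKBONE_CLASSES:
        sub = means[means["backbone_class"] == backbone]
        chains = sorted(
            sub["chain"].unique(),
            key=lambda c: (LipidSpecies("Cer", c).carbons,
                           LipidSpecies("Cer", c).double_bonds),
        )
        for chain in chains:
            for grp, grp_sub in sub[sub["chain"] == chain].groupby("group"):
                conc = grp_sub["concentration"]
                res = result_by_chain.get(chain)
                folds = (
                    ";".join(f"{s}={f:.4g}" for s, f in sorted(res.proband_folds.items()))
                    if res else ""
                )
                rows.append(
                    {
                        "backbone_class": backbone,
                        "chain": chain,
                        "group": grp,
                        "n": int(conc.size),
                        "mean": float(conc.mean()),
                        "sd": float(conc.std(ddof=1)) if conc.size > 1 else np.nan,
                        "proband_folds": folds,
                        "p_value": res.p_value if res else np.nan,
                        "significant": res.significant if res else False,
                    }
                )
    return pd.DataFrame(rows)
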