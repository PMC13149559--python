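"""Pipeline configuration, validation, and stage orchestration.

A single structured (YAML) config drives the stages in dependency order:
simulate -> ps -> outliers -> isoforms -> reporter -> lipids -> aso.
All randomness flows from the config seed; rerunning with the same
config and seed reproduces every report payload byte-identically.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import yaml

from . import __version__
from .aso import design_walk, read_target_fasta, write_designs_tsv
from .isoforms import (
    classify_isoform,
    isoform_fractions,
    parse_gtf_transcripts,
    read_abundance_tsv,
)
from .junctions import (
    JunctionCountTable,
    merge_samples,
    parse_star_sj,
    build_exclusion_sets,
    percent_spliced,
)
from .lipids import LipidPanel, analyze_panel, summarize_panel
from .outliers import (
    build_background,
    call_outliers,
    calls_to_frame,
    write_background_tsv,
    write_calls_tsv,
)
from .reporter import (
    dunnett_results_to_frame,
    dunnett_test,
    psi_results_to_frame,
    quantify_replicates,
    read_peak_csv,
    write_peak_csv,
)
from .simulate import (
    CohortSimConfig,
    LipidSimConfig,
    ReporterSimConfig,
    simulate_abundance_table,
    simulate_junction_cohort,
    simulate_lipid_panel,
    simulate_reporter_run,
    write_cohort_fixture,
)

STAGES = ("simulate", "ps", "outliers", "isoforms", "reporter", "lipids", "aso")

# Participant-one isoform profile used as the simulate-stage default.
DEFAULT_FRACTIONS = {
    "canonical": 0.06,
    "exon2_skip": 0.69,
    "cryptic_site": 0.12,
    "other": 0.13,
}


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _positive_int(minimum: int = 1) -> Callable[[Any], str | None]:
    def check(value: Any) -> str | None:
        if not isinstance(value, int) or isinstance(value, bool) or value < minimum:
            return f"must be an integer >= {minimum}"
        return None

    return check


def _number(minimum: float | None = None, maximum: float | None = None):
    def check(value: Any) -> str | None:
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            return "must be a number"
        if minimum is not None and value < minimum:
            return f"must be >= {minimum}"
        if maximum is not None and value > maximum:
            return f"must be <= {maximum}"
        return None

    return check


def _choice(*options: str):
    def check(value: Any) -> str | None:
        if value not in options:
            return f"must be one of {options}"
        return None

    return check


def _boolean(value: Any) -> str | None:
    return None if isinstance(value, bool) else "must be true or false"


def _optional_path(value: Any) -> str | None:
    return None if value is None or isinstance(value, str) else "must be a path or null"


def _string(value: Any) -> str | None:
    return None if isinstance(value, str) else "must be a string"


# section -> key -> (default, validator)
_SCHEMA: dict[str, dict[str, tuple[Any, Callable[[Any], str | None]]]] = {
    "": {
        "output_dir": ("vusplice_out", _string),
        "seed": (0, _positive_int(0)),
        "stages": (list(STAGES), None),  # validated separately
    },
    "simulate": {
        "n_background": (670, _positive_int(1)),
        "n_exons": (3, _positive_int(3)),
        "depth_mean": (2000.0, _number(minimum=1e-9)),
        "depth_dispersion": (10.0, _number(minimum=1e-9)),
        "background_skip_mean": (0.02, _number(0.0, 1.0)),
        "background_skip_concentration": (50.0, _number(minimum=1e-9)),
        "patient_skip": (0.56, _number(0.0, 1.0)),
        "reporter_reference_psi": (0.9, _number(0.0, 1.0)),
        "reporter_variant_psi": (0.0, _number(0.0, 1.0)),
        "reporter_noise_cv": (0.1, _number(minimum=0.0)),
        "lipid_cv": (0.1, _number(minimum=0.0)),
        "lipid_fold": (42.0, _number(minimum=1e-9)),
        "aso_target_length": (120, _positive_int(18)),
    },
    "ps": {
        "sj_dir": (None, _optional_path),
        "include_multimappers": (False, _boolean),
    },
    "outliers": {
        "query_sample": ("patient", _string),
        "min_samples": (20, _positive_int(2)),
        "quantile_rule": ("linear", _choice("linear", "tukey_hinges", "nearest")),
        "missing_as_zero": (False, _boolean),
    },
    "isoforms": {
        "abundance_tsv": (None, _optional_path),
        "gtf": (None, _optional_path),
        "canonical_transcript": (None, lambda v: _optional_path(v)),
    },
    "reporter": {
        "peaks_csv": (None, _optional_path),
        "included_size_nt": (412.0, _number(minimum=1e-9)),
        "skipped_size_nt": (269.0, _number(minimum=1e-9)),
        "tolerance_nt": (5.0, _number(minimum=0.0)),
        "control": ("reference", _string),
        "mc_reps": (100_000, _positive_int(100)),
    },
    "lipids": {
        "panel_csv": (None, _optional_path),
        "control_group": ("control", _string),
        "welch": (False, _boolean),
        "test_on": ("ratio", _choice("ratio", "concentration")),
    },
    "aso": {
        "target_fasta": (None, _optional_path),
        "k": (18, _positive_int(1)),
        "step": (1, _positive_int(1)),
    },
}


@dataclass
class PipelineConfig:
    """Validated stage parameters; ``settings[section][key]``."""

    settings: dict[str, dict[str, Any]]

    @property
    def output_dir(self) -> Path:
        return Path(self.settings[""]["output_dir"])

    @property
    def seed(self) -> int:
        return int(self.settings[""]["seed"])

    @property
    def stages(self) -> list[str]:
        return list(self.settings[""]["stages"])

    def section(self, name: str) -> dict[str, Any]:
        return self.settings[name]


def default_config() -> PipelineConfig:
    return PipelineConfig(
        {
            section: {key: default for key, (default, _) in keys.items()}
            for section, keys in _SCHEMA.items()
        }
    )


def _suggest(key: str, known: Mapping[str, Any]) -> str:
    matches = difflib.get_close_matches(key, list(known), n=1)
    return f" (did you mean {matches[0]!r}?)" if matches else ""


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Parse and validate a config mapping or YAML file.

    Every parameter is range-checked and unknown keys are rejected with a
    nearest-name suggestion; all problems are aggregated into one
    :class:`ConfigError`.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            raw = yaml.safe_load(handle) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])

    errors: list[str] = []
    config = default_config()
    top_known = {**_SCHEMA[""], **{s: None for s in STAGES}}
    for key, value in raw.items():
        if key in _SCHEMA[""]:
            if key == "stages":
                if not isinstance(value, list) or not value:
                    errors.append("stages: must be a non-empty list")
                    continue
                unknown = [s for s in value if s not in STAGES]
                if unknown:
                    errors.append(f"stages: unknown stage(s) {unknown}")
                    continue
                config.settings[""]["stages"] = [s for s in STAGES if s in value]
            else:
                _, validator = _SCHEMA[""][key]
                problem = validator(value) if validator else None
                if problem:
                    errors.append(f"{key}: {problem}")
                else:
                    config.settings[""][key] = value
        elif key in STAGES:
            if not isinstance(value, dict):
                errors.append(f"{key}: must be a mapping of stage parameters")
                continue
            for sub_key, sub_value in value.items():
                if sub_key not in _SCHEMA[key]:
                    errors.append(
                        f"{key}.{sub_key}: unknown key{_suggest(sub_key, _SCHEMA[key])}"
                    )
                    continue
                _, validator = _SCHEMA[key][sub_key]
                problem = validator(sub_value) if validator else None
                if problem:
                    errors.append(f"{key}.{sub_key}: {problem}")
                else:
                    config.settings[key][sub_key] = sub_value
        else:
            errors.append(f"{key}: unknown key{_suggest(key, top_known)}")

    min_samples = config.settings["outliers"]["min_samples"]
    if isinstance(min_samples, int) and min_samples < 2:
        errors.append("outliers.min_samples: must be >= 2")
    if errors:
        raise ConfigError(errors)
    return config


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order.

    Returns the consolidated run report (also written to
    ``<output_dir>/report.json``).  A stage failure aborts the run with a
    :class:`StageError` naming the stage; outputs of completed stages are
    retained on disk.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.settings,
        "stages": {},
        "warnings": [],
    }
    state: dict[str, Any] = {}
    for stage in config.stages:
        runner = _STAGE_RUNNERS[stage]
        try:
            report["stages"][stage] = runner(config, state, report)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            _write_report(report, out)
            raise StageError(stage, exc) from exc
    _write_report(report, out)
    return report


def _write_report(report: dict[str, Any], out: Path) -> None:
    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=str)


def _stage_simulate(config, state, report):
    out = config.output_dir / "simulated"
    out.mkdir(parents=True, exist_ok=True)
    sim = config.section("simulate")
    seed = config.seed
    cohort_cfg = CohortSimConfig(
        seed=seed,
        n_background=sim["n_background"],
        n_exons=sim["n_exons"],
        depth_mean=sim["depth_mean"],
        depth_dispersion=sim["depth_dispersion"],
        background_skip_mean=sim["background_skip_mean"],
        background_skip_concentration=sim["background_skip_concentration"],
        patient_skip=sim["patient_skip"],
    )
    background, patient = simulate_junction_cohort(cohort_cfg)
    sj_dir = out / "sj"
    write_cohort_fixture(background, patient, sj_dir)
    state["sj_dir"] = sj_dir

    from .isoforms import write_abundance_tsv

    abundances = simulate_abundance_table(
        DEFAULT_FRACTIONS, total_tpm=100.0, noise_cv=0.0, seed=seed
    )
    abundance_path = out / "abundance.tsv"
    write_abundance_tsv(abundances, abundance_path)
    state["abundance_tsv"] = abundance_path

    replicates = []
    for i, (condition, psi) in enumerate(
        (("reference", sim["reporter_reference_psi"]),
         ("variant", sim["reporter_variant_psi"]))
    ):
        run = simulate_reporter_run(
            ReporterSimConfig(
                seed=seed + 1 + i,
                psi_true=psi,
                noise_cv=sim["reporter_noise_cv"],
            )
        )
        replicates.extend(
            r.__class__(condition, r.replicate, r.peaks) for r in run
        )
    peaks_path = out / "reporter_peaks.csv"
    write_peak_csv(replicates, peaks_path)
    state["peaks_csv"] = peaks_path

    panel = simulate_lipid_panel(
        LipidSimConfig(
            seed=seed + 3,
            cv=sim["lipid_cv"],
            fold_effect=None if sim["lipid_fold"] == 42.0 else {
                chain: sim["lipid_fold"]
                for chain in LipidSimConfig().chains
            },
        )
    )
    panel_path = out / "lipid_panel.csv"
    panel.to_csv(panel_path)
    state["panel_csv"] = panel_path

    import numpy as np

    rng = np.random.default_rng(seed + 4)
    target = "".join(rng.choice(list("ACGT"), size=sim["aso_target_length"]))
    target_path = out / "aso_target.fa"
    with open(target_path, "w") as handle:
        handle.write(">simulated_target\n" + target + "\n")
    state["target_fasta"] = target_path

    return {
        "n_background": len(background.samples),
        "n_junctions": len(background.junctions),
        "outputs": [str(p) for p in (sj_dir, abundance_path, peaks_path,
                                     panel_path, target_path)],
    }


def _stage_ps(config, state, report):
    params = config.section("ps")
    sj_dir = Path(params["sj_dir"]) if params["sj_dir"] else state.get("sj_dir")
    if sj_dir is None:
        raise ValueError("ps stage needs ps.sj_dir or a prior simulate stage")
    tables = [
        parse_star_sj(path, sample=path.name.replace(".SJ.out.tab", ""),
                      include_multimappers=params["include_multimappers"])
        for path in sorted(Path(sj_dir).glob("*.SJ.out.tab"))
    ]
    if not tables:
        raise ValueError(f"no *.SJ.out.tab files in {sj_dir}")
    merged = merge_samples(tables)
    exclusion = build_exclusion_sets(merged.junctions)
    ps = percent_spliced(merged, exclusion)
    ps_path = config.output_dir / "ps_matrix.tsv"
    ps.to_tsv(ps_path)
    state["ps_matrix"] = ps
    return {
        "n_samples": len(ps.samples),
        "n_junctions": len(ps.junctions),
        "output": str(ps_path),
    }


def _stage_outliers(config, state, report):
    params = config.section("outliers")
    ps = state.get("ps_matrix")
    if ps is None:
        raise ValueError("outliers stage needs a prior ps stage")
    query = params["query_sample"]
    if query not in ps.samples:
        raise ValueError(f"query sample {query!r} not in PS matrix")
    cohort_cols = [s for s in ps.samples if s != query]
    from .junctions import PSMatrix

    cohort = PSMatrix(ps.ps[cohort_cols])
    background = build_background(
        cohort, params["min_samples"], params["quantile_rule"],
        params["missing_as_zero"],
    )
    calls = call_outliers(ps.sample_column(query), background, query)
    bg_path = config.output_dir / "background.tsv"
    calls_path = config.output_dir / "outlier_calls.tsv"
    write_background_tsv(background, bg_path)
    write_calls_tsv(calls, calls_path)
    not_evaluable = [c.junction.name for c in calls if c.direction == "not_evaluable"]
    if not_evaluable:
        report["warnings"].append(
            f"outliers: {len(not_evaluable)} junction(s) not evaluable"
        )
    frame = calls_to_frame(calls)
    return {
        "query_sample": query,
        "calls": frame.to_dict(orient="records"),
        "outputs": [str(bg_path), str(calls_path)],
    }


def _stage_isoforms(config, state, report):
    params = config.section("isoforms")
    path = params["abundance_tsv"] or state.get("abundance_tsv")
    if path is None:
        raise ValueError("isoforms stage needs isoforms.abundance_tsv or simulate")
    abundances = read_abundance_tsv(path)
    fractions = isoform_fractions(abundances)
    summary: dict[str, Any] = {"fractions": fractions}
    if params["gtf"] and params["canonical_transcript"]:
        models = {m.transcript_id: m for m in parse_gtf_transcripts(params["gtf"])}
        canonical = models.get(params["canonical_transcript"])
        if canonical is None:
            raise ValueError(
                f"canonical transcript {params['canonical_transcript']!r} not in GTF"
            )
        summary["classifications"] = {
            tx: {
                "category": c.category,
                "skipped_exons": list(c.skipped_exons),
                "detail": c.detail,
            }
            for tx, model in models.items()
            if tx != canonical.transcript_id
            for c in [classify_isoform(model, canonical)]
        }
    out_path = config.output_dir / "isoforms.json"
    with open(out_path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    summary["output"] = str(out_path)
    return summary


def _stage_reporter(config, state, report):
    params = config.section("reporter")
    path = params["peaks_csv"] or state.get("peaks_csv")
    if path is None:
        raise ValueError("reporter stage needs reporter.peaks_csv or simulate")
    replicates = read_peak_csv(path)
    results, frame = quantify_replicates(
        replicates, params["included_size_nt"], params["skipped_size_nt"],
        params["tolerance_nt"],
    )
    unassigned = int(frame["n_unassigned"].sum())
    if unassigned:
        report["warnings"].append(f"reporter: {unassigned} unassigned peak(s)")
    groups = {r.condition: list(r.psi_values) for r in results}
    stats_rows = []
    if params["control"] in groups and len(groups) >= 2:
        dunnett = dunnett_test(
            groups, params["control"], mc_reps=params["mc_reps"], seed=config.seed
        )
        stats_rows = dunnett_results_to_frame(dunnett).to_dict(orient="records")
    psi_path = config.output_dir / "reporter_psi.tsv"
    psi_results_to_frame(results).to_csv(psi_path, sep="\t", index=False)
    stats_path = config.output_dir / "reporter_stats.tsv"
    import pandas as pd

    pd.DataFrame(stats_rows).to_csv(stats_path, sep="\t", index=False)
    return {
        "psi": psi_results_to_frame(results).to_dict(orient="records"),
        "comparisons": stats_rows,
        "outputs": [str(psi_path), str(stats_path)],
    }


def _stage_lipids(config, state, report):
    params = config.section("lipids")
    path = params["panel_csv"] or state.get("panel_csv")
    if path is None:
        raise ValueError("lipids stage needs lipids.panel_csv or simulate")
    panel = LipidPanel.from_csv(path)
    results = analyze_panel(
        panel,
        control_group=params["control_group"],
        welch=params["welch"],
        test_on=params["test_on"],
    )
    summary = summarize_panel(panel, results, params["control_group"])
    out_path = config.output_dir / "lipid_report.tsv"
    summary.to_csv(out_path, sep="\t", index=False)
    return {
        "tested_on": params["test_on"],
        "species": [
            {
                "chain": r.chain,
                "proband_folds": r.proband_folds,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ],
        "output": str(out_path),
    }


def _stage_aso(config, state, report):
    params = config.section("aso")
    path = params["target_fasta"] or state.get("target_fasta")
    if path is None:
        raise ValueError("aso stage needs aso.target_fasta or simulate")
    target = read_target_fasta(path)
    designs = design_walk(target, k=params["k"], step=params["step"])
    out_path = config.output_dir / "aso_designs.tsv"
    write_designs_tsv(designs, out_path)
    return {"n_designs": len(designs), "output": str(out_path)}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "ps": _stage_ps,
    "outliers": _stage_outliers,
    "isoforms": _stage_isoforms,
    "reporter": _stage_reporter,
    "lipids": _stage_lipids,
    "aso": _stage_aso,
}
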