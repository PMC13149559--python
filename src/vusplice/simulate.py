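"""Synthetic data generators for every pipeline input.

The generators emulate the study conditions the pipeline targets: a
GTEx-like background cohort of 670 whole-blood junction-count samples in
which exon skipping of a three-exon gene is rare (mean skip fraction
0.02), one patient sample in which the exon-1-3 skip junction carries 56%
of junction usage, splicing-reporter runs with nine biological
replicates, and a plasma sphingolipid panel of 2 probands vs 9 controls
measured in technical triplicate with a 42-fold DHCer/Cer ratio effect.

Generative choices: per-sample junction-spanning depth is negative
binomial, the skip fraction psi is Beta-distributed across background
samples (fixed for the patient), skip reads are Binomial(N, psi) and the
remainder is split evenly across the inclusion-path junctions;
signal/concentration noise is multiplicative log-normal parameterised by
its coefficient of variation.  Every generator is deterministic given
its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .isoforms import IsoformAbundance
from .junctions import JunctionCountTable, SpliceJunction
from .lipids import BACKBONE_CLASSES, LipidPanel, LipidSpecies
from .reporter import FragmentPeak, ReporterReplicate

__all__ = [
    "CohortSimConfig",
    "ReporterSimConfig",
    "LipidSimConfig",
    "simulate_junction_cohort",
    "simulate_abundance_table",
    "simulate_reporter_run",
    "simulate_lipid_panel",
    "gene_junctions",
]

# Gene-model layout used for simulated junction coordinates.
_EXON_LEN = 100
_INTRON_LEN = 100
_GENE_START = 1000
_CONTIG = "chr1"


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")


def _check_prob(name: str, value: float) -> None:
    _check_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class CohortSimConfig:
    """Background cohort + patient junction-count simulation parameters."""

    seed: int = 0
    n_background: int = 670
    n_exons: int = 3
    depth_mean: float = 2000.0
    depth_dispersion: float = 10.0
    background_skip_mean: float = 0.02
    background_skip_concentration: float = 50.0
    patient_skip: float = 0.56

    def __post_init__(self) -> None:
        if self.n_background < 1 or self.n_exons < 3:
            raise ValueError("need >= 1 background sample and >= 3 exons")
        _check_finite("depth_mean", self.depth_mean)
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        _check_prob("background_skip_mean", self.background_skip_mean)
        _check_prob("patient_skip", self.patient_skip)
        if self.background_skip_concentration <= 0:
            raise ValueError("background_skip_concentration must be > 0")


@dataclass(frozen=True)
class ReporterSimConfig:
    """Splicing-reporter fragment-analysis simulation parameters."""

    seed: int = 0
    n_replicates: int = 9
    psi_true: float = 0.9
    total_signal_mean: float = 10_000.0
    noise_cv: float = 0.1
    included_size_nt: float = 412.0
    skipped_size_nt: float = 269.0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        _check_prob("psi_true", self.psi_true)
        if self.included_size_nt == self.skipped_size_nt:
            raise ValueError("amplicon sizes must be distinct")
        if self.total_signal_mean <= 0 or self.noise_cv < 0:
            raise ValueError("total_signal_mean > 0 and noise_cv >= 0 required")


@dataclass(frozen=True)
class LipidSimConfig:
    """Plasma sphingolipid panel simulation parameters.

    ``fold_effect`` maps each chain to the proband DHCer/Cer ratio fold F
    over controls; it is realised symmetrically (DHCer means scaled up by
    sqrt(F), Cer means scaled down by sqrt(F)) so the configured ratio
    fold is exact in the no-noise limit.
    """

    seed: int = 0
    n_controls: int = 9
    n_probands: int = 2
    chains: tuple[str, ...] = (
        "C14:0", "C16:0", "C20:0", "C22:0", "C24:0", "C24:1", "C26:0",
    )
    control_mean: Mapping[str, Mapping[str, float]] | None = None  # class->chain->mean
    cv: float = 0.1
    fold_effect: Mapping[str, float] | None = None  # chain -> ratio fold
    n_technical_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_probands < 1:
            raise ValueError("need >= 1 control and >= 1 proband")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_technical_replicates < 1:
            raise ValueError("n_technical_replicates must be >= 1")
        for chain in self.chains:
            LipidSpecies("Cer", chain)
        if self.fold_effect is not None:
            unknown = set(self.fold_effect) - set(self.chains)
            if unknown:
                raise ValueError(f"fold_effect for unknown species: {sorted(unknown)}")
            if any(f <= 0 for f in self.fold_effect.values()):
                raise ValueError("fold_effect values must be > 0")
        if self.control_mean is not None:
            for cls, per_chain in self.control_mean.items():
                if cls not in BACKBONE_CLASSES:
                    raise ValueError(f"unknown backbone class {cls!r}")
                if any(m <= 0 for m in per_chain.values()):
                    raise ValueError("control means must be > 0")

    def resolved_control_mean(self) -> dict[str, dict[str, float]]:
        if self.control_mean is not None:
            return {c: dict(v) for c, v in self.control_mean.items()}
        # plausible plasma scale: Cer an order of magnitude above DHCer
        return {
            "DHCer": {chain: 0.1 for chain in self.chains},
            "Cer": {chain: 1.0 for chain in self.chains},
        }

    def resolved_fold_effect(self) -> dict[str, float]:
        if self.fold_effect is not None:
            return dict(self.fold_effect)
        return {chain: 42.0 for chain in self.chains}


def gene_junctions(n_exons: int = 3) -> dict[str, SpliceJunction]:
    """Junctions of the simulated gene: consecutive pairs plus the e1-e3 skip.

    Exons are ``_EXON_LEN`` nt separated by ``_INTRON_LEN`` nt introns on
    the + strand of ``chr1``.
    """
    if n_exons < 3:
        raise ValueError("gene model needs >= 3 exons")
    starts = [_GENE_START + i * (_EXON_LEN + _INTRON_LEN) for i in range(n_exons)]
    junctions: dict[str, SpliceJunction] = {}
    for i in range(n_exons - 1):
        junctions[f"e{i + 1}-e{i + 2}"] = SpliceJunction(
            _CONTIG, starts[i] + _EXON_LEN, starts[i + 1], "+"
        )
    junctions["e1-e3"] = SpliceJunction(_CONTIG, starts[0] + _EXON_LEN, starts[2], "+")
    return junctions


def _sample_depth(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if not math.isfinite(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_junction_cohort(
    config: CohortSimConfig,
) -> tuple[JunctionCountTable, JunctionCountTable]:
    """Simulate background-cohort and patient junction-count tables.

    Per sample: depth N ~ NegBin(depth_mean, depth_dispersion); skip
    fraction psi ~ Beta(mean=background_skip_mean, concentration) for
    background samples and fixed at ``patient_skip`` for the patient;
    e1-e3 skip reads ~ Binomial(N, psi); the remainder is split evenly
    (multinomially) across the inclusion-path junctions.
    """
    rng = np.random.default_rng(config.seed)
    junctions = gene_junctions(config.n_exons)
    inclusion_names = [n for n in junctions if n != "e1-e3"]

    def draw_sample(psi: float, depth: int) -> dict[str, int]:
        skip = rng.binomial(depth, psi)
        remaining = depth - skip
        shares = rng.multinomial(
            remaining, [1.0 / len(inclusion_names)] * len(inclusion_names)
        )
        counts = dict(zip(inclusion_names, (int(c) for c in shares)))
        counts["e1-e3"] = int(skip)
        return counts

    a = config.background_skip_mean * config.background_skip_concentration
    b = (1 - config.background_skip_mean) * config.background_skip_concentration

    depths = _sample_depth(
        rng, config.depth_mean, config.depth_dispersion, config.n_background + 1
    )
    degenerate_beta = (
        not math.isfinite(config.background_skip_concentration) or a == 0 or b == 0
    )
    records = []
    for i in range(config.n_background):
        psi = config.background_skip_mean if degenerate_beta else float(rng.beta(a, b))
        counts = draw_sample(psi, int(depths[i]))
        sample = f"background_{i + 1:04d}"
        records.extend(
            (junctions[name], sample, count) for name, count in counts.items()
        )
    background = JunctionCountTable.from_records(records)

    patient_counts = draw_sample(config.patient_skip, int(depths[-1]))
    patient = JunctionCountTable.from_records(
        [(junctions[name], "patient", count) for name, count in patient_counts.items()]
    )
    return background, patient


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def simulate_abundance_table(
    fractions: Mapping[str, float],
    total_tpm: float,
    noise_cv: float,
    seed: int = 0,
    gene_id: str = "GENE1",
) -> list[IsoformAbundance]:
    """TPM_i = total_tpm * fraction_i * lognormal(cv); exact at cv = 0."""
    if total_tpm < 0:
        raise ValueError("total_tpm must be >= 0")
    total_fraction = sum(fractions.values())
    if abs(total_fraction - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total_fraction}")
    rng = np.random.default_rng(seed)
    noise = _lognormal_factor(rng, noise_cv, size=len(fractions))
    return [
        IsoformAbundance(tx, gene_id, total_tpm * frac * float(n))
        for (tx, frac), n in zip(fractions.items(), noise)
    ]


def simulate_reporter_run(config: ReporterSimConfig) -> list[ReporterReplicate]:
    """One reporter experiment: per replicate, an included-size peak with
    signal proportional to psi_true and a skipped-size peak proportional
    to 1 - psi_true, each under log-normal noise.  Peaks with zero
    expected signal are omitted entirely.
    """
    rng = np.random.default_rng(config.seed)
    replicates = []
    for i in range(config.n_replicates):
        peaks = []
        for size, weight in (
            (config.included_size_nt, config.psi_true),
            (config.skipped_size_nt, 1.0 - config.psi_true),
        ):
            if weight == 0:
                continue
            signal = (
                config.total_signal_mean
                * weight
                * float(_lognormal_factor(rng, config.noise_cv))
            )
            peaks.append(FragmentPeak(size, signal))
        replicates.append(ReporterReplicate("simulated", f"rep{i + 1}", tuple(peaks)))
    return replicates


def simulate_lipid_panel(config: LipidSimConfig) -> LipidPanel:
    """Simulate control and proband sphingolipid concentrations.

    Controls draw log-normal concentrations around the per-species
    control mean; probands have DHCer means multiplied and Cer means
    divided by sqrt(fold_effect) so the DHCer/Cer ratio fold over
    controls equals fold_effect (exactly, at cv = 0).  Technical
    replicates are independent draws.
    """
    rng = np.random.default_rng(config.seed)
    control_mean = config.resolved_control_mean()
    fold = config.resolved_fold_effect()
    rows = []
    samples = [(f"control_{i + 1}", "control", 1.0) for i in range(config.n_controls)]
    samples += [(f"proband_{i + 1}", "proband", 1.0) for i in range(config.n_probands)]
    for sample, group, _ in samples:
        for backbone in BACKBONE_CLASSES:
            for chain in config.chains:
                mean = control_mean[backbone][chain]
                if group == "proband":
                    f = math.sqrt(fold.get(chain, 1.0))
                    mean = mean * f if backbone == "DHCer" else mean / f
                noise = _lognormal_factor(
                    rng, config.cv, size=config.n_technical_replicates
                )
                for rep in range(config.n_technical_replicates):
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "backbone_class": backbone,
                            "chain": chain,
                            "replicate": rep + 1,
                            "concentration": mean * float(noise[rep]),
                        }
                    )
    return LipidPanel(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Fixture-directory writer

def write_cohort_fixture(
    background: JunctionCountTable,
    patient: JunctionCountTable,
    directory: str | Path,
) -> list[Path]:
    """Write one STAR SJ.out.tab-dialect file per sample into a directory."""
    from .junctions import write_star_sj

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for table in (background, patient):
        for sample in table.samples:
            single = JunctionCountTable(table.counts[[sample]])
            path = directory / f"{sample}.SJ.out.tab"
            write_star_sj(single, path)
            paths.append(path)
    return paths
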