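"""Antisense-oligonucleotide (ASO) walk design.

An ASO walk tiles a target pre-mRNA region with k-mer windows; each ASO
is the reverse complement of its window, synthesized as modified DNA —
by default 2'-O-methoxyethyl (2'MOE) sugars at every position on a full
phosphorothioate backbone for nuclease resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

__all__ = ["AsoDesign", "design_walk", "DEFAULT_K"]

DEFAULT_K = 18  # nt
DEFAULT_SUGAR = "2MOE"
DEFAULT_BACKBONE = "phosphorothioate"

_ALPHABET = set("ACGTUN")


@dataclass(frozen=True)
class AsoDesign:
    """One tiled ASO: reverse complement of target[start : start + k]."""

    start_offset: int
    length: int
    sequence: str  # DNA alphabet
    sugar_chemistry: tuple[str, ...]
    backbone: str = DEFAULT_BACKBONE
    contains_n: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("ASO sequence length must equal k")
        if len(self.sugar_chemistry) != self.length:
            raise ValueError("one sugar-chemistry label per position required")


def reverse_complement_dna(sequence: str) -> str:
    """Reverse complement in the DNA alphabet; U is treated as T."""
    return str(Seq(sequence.upper().replace("U", "T")).reverse_complement())


def design_walk(
    target: str,
    k: int = DEFAULT_K,
    step: int = 1,
    sugar: str = DEFAULT_SUGAR,
    backbone: str = DEFAULT_BACKBONE,
) -> list[AsoDesign]:
    """Tile ``target`` with windows at offsets 0, step, 2*step, ...

    Windows are emitted while ``offset + k <= len(target)``; each design's
    sequence is the reverse complement of its window (DNA alphabet, so an
    RNA target's U pairs as A).  Windows containing N are emitted but
    flagged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    target = target.strip().upper()
    bad = set(target) - _ALPHABET
    if bad:
        raise ValueError(f"target contains non-nucleotide characters: {sorted(bad)}")
    if len(target) < k:
        raise ValueError(f"target length {len(target)} shorter than k={k}")
    designs = []
    for offset in range(0, len(target) - k + 1, step):
        window = target[offset : offset + k]
        designs.append(
            AsoDesign(
                start_offset=offset,
                length=k,
                sequence=reverse_complement_dna(window),
                sugar_chemistry=(sugar,) * k,
                backbone=backbone,
                contains_n="N" in window,
            )
        )
    return designs


def designs_to_frame(designs: Iterable[AsoDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_offset": d.start_offset,
                "length": d.length,
                "sequence": d.sequence,
                "sugar_chemistry": d.sugar_chemistry[0] if d.sugar_chemistry else "",
                "backbone": d.backbone,
                "contains_n": d.contains_n,
            }
            for d in designs
        ]
    )


def write_designs_tsv(designs: Iterable[AsoDesign], path: str | Path) -> None:
    designs_to_frame(designs).to_csv(path, sep="\t", index=False)


def write_designs_fasta(designs: Iterable[AsoDesign], path: str | Path) -> None:
    with open(path, "w") as handle:
        for d in designs:
            handle.write(
                f">aso_{d.start_offset} len={d.length} sugar={d.sugar_chemistry[0]} "
                f"backbone={d.backbone}\n{d.sequence}\n"
            )


def read_target_fasta(path: str | Path) -> str:
    """Read a single-record FASTA target sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq)
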