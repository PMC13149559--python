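"""Splice-junction count tables and percent-spliced (PS) quantification.

A splice junction is the intron interval removed by a splicing event,
stored 0-based half-open.  The percent-spliced value of a junction in a
sample is its read count divided by the summed counts of itself and every
*exclusion* junction — any other junction whose intron interval overlaps
it, i.e. a mutually exclusive splicing outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SpliceJunction",
    "JunctionCountTable",
    "PSMatrix",
    "parse_star_sj",
    "write_star_sj",
    "parse_junction_tsv",
    "merge_samples",
    "build_exclusion_sets",
    "percent_spliced",
]

_STRANDS = {"+", "-", "."}
_STAR_STRAND_CODE = {"0": ".", "1": "+", "2": "-"}
_STAR_STRAND_TO_CODE = {".": "0", "+": "1", "-": "2"}


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron interval: ``contig:[start, end)`` with optional strand.

    ``start`` is the 0-based first intronic base; ``end`` is one past the
    last intronic base (half-open).  Strand ``.`` means unknown.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("junction contig must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"junction interval invalid: start={self.start} end={self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {{+, -, .}}, got {self.strand!r}")

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"


class JunctionCountTable:
    """Junction x sample matrix of non-negative read counts.

    Wraps a pandas DataFrame whose index holds :class:`SpliceJunction`
    objects and whose columns are sample ids.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise ValueError("duplicate junctions in count table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("junction counts must be non-negative")
        self.counts = counts.astype(np.int64) if counts.size else counts

    @property
    def junctions(self) -> list[SpliceJunction]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, JunctionCountTable) and self.counts.equals(
            other.counts
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[SpliceJunction, str, int]],
    ) -> "JunctionCountTable":
        """Build from ``(junction, sample, count)`` triples; absent cells are 0."""
        rows: dict[SpliceJunction, dict[str, int]] = {}
        samples: dict[str, None] = {}
        for junction, sample, count in records:
            rows.setdefault(junction, {})[sample] = count
            samples.setdefault(sample)
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
        df = df.reindex(columns=list(samples)).fillna(0).astype(np.int64)
        return cls(df)


class PSMatrix:
    """Junction x sample percent-spliced values in [0, 1]; NaN = undefined.

    A value is undefined exactly when the PS denominator (the junction's
    count plus all exclusion counts) is zero in that sample.
    """

    def __init__(self, ps: pd.DataFrame):
        values = ps.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("PS values must lie in [0, 1]")
        self.ps = ps.astype(float)

    @property
    def junctions(self) -> list[SpliceJunction]:
        return list(self.ps.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ps.columns)

    def sample_column(self, sample: str) -> pd.Series:
        if sample not in self.ps.columns:
            raise KeyError(f"sample {sample!r} not in PS matrix")
        return self.ps[sample]

    def to_tsv(self, path: str | Path) -> None:
        out = self.ps.copy()
        out.index = [j.name for j in out.index]
        out.to_csv(path, sep="\t", index_label="junction", na_rep="NA")


class SJParseError(ValueError):
    """Raised when a junction file line cannot be parsed."""


def parse_star_sj(
    path: str | Path,
    sample: str | None = None,
    include_multimappers: bool = False,
) -> JunctionCountTable:
    """Read one STAR ``SJ.out.tab``-dialect file into a single-sample table.

    Columns (tab-separated): contig, 1-based first intron base, 1-based
    last intron base, strand code (0 unknown / 1 ``+`` / 2 ``-``), intron
    motif, annotation flag, unique-mapping reads, multi-mapping reads,
    maximum overhang.  By default only unique-mapping reads are counted.
    """
    path = Path(path)
    sample = sample if sample is not None else path.stem
    records: list[tuple[SpliceJunction, str, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise SJParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                contig = fields[0]
                start = int(fields[1]) - 1  # 1-based inclusive -> 0-based
                end = int(fields[2])  # 1-based inclusive -> half-open
                strand = _STAR_STRAND_CODE[fields[3]]
                count = int(fields[6])
                if include_multimappers:
                    count += int(fields[7])
            except (ValueError, KeyError) as exc:
                raise SJParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((SpliceJunction(contig, start, end, strand), sample, count))
    if not records:
        return JunctionCountTable(pd.DataFrame(columns=[sample], dtype=np.int64))
    return JunctionCountTable.from_records(records)


def write_star_sj(table: JunctionCountTable, path: str | Path) -> None:
    """Write a single-sample table in the STAR ``SJ.out.tab`` dialect."""
    if len(table.samples) != 1:
        raise ValueError("write_star_sj requires a single-sample table")
    sample = table.samples[0]
    with open(path, "w") as handle:
        for junction in table.junctions:
            count = int(table.counts.at[junction, sample])
            handle.write(
                "\t".join(
                    [
                        junction.contig,
                        str(junction.start + 1),
                        str(junction.end),
                        _STAR_STRAND_TO_CODE[junction.strand],
                        "0",  # motif: unknown
                        "0",  # annotation flag
                        str(count),
                        "0",  # multi-mapping reads
                        "0",  # max overhang
                    ]
                )
                + "\n"
            )


def parse_junction_tsv(path: str | Path) -> JunctionCountTable:
    """Read the generic long-format junction TSV.

    Columns: contig, start0, end0, strand, sample, count.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"contig": str, "strand": str, "sample": str},
    )
    required = {"contig", "start0", "end0", "strand", "sample", "count"}
    missing = required - set(df.columns)
    if missing:
        raise SJParseError(f"{path}: missing columns {sorted(missing)}")
    records = [
        (
            SpliceJunction(row.contig, int(row.start0), int(row.end0), row.strand),
            row.sample,
            int(row.count),
        )
        for row in df.itertuples()
    ]
    return JunctionCountTable.from_records(records)


def write_junction_tsv(table: JunctionCountTable, path: str | Path) -> None:
    rows = []
    for junction in table.junctions:
        for sample in table.samples:
            rows.append(
                {
                    "contig": junction.contig,
                    "start0": junction.start,
                    "end0": junction.end,
                    "strand": junction.strand,
                    "sample": sample,
                    "count": int(table.counts.at[junction, sample]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def merge_samples(tables: Iterable[JunctionCountTable]) -> JunctionCountTable:
    """Union single-sample tables into one multi-sample table.

    A junction absent from a sample's file gets count 0 there.  Sample ids
    must be distinct.
    """
    frames = [t.counts for t in tables]
    if not frames:
        raise ValueError("no tables to merge")
    seen: set[str] = set()
    for frame in frames:
        for sample in frame.columns:
            if sample in seen:
                raise ValueError(f"duplicate sample id {sample!r}")
            seen.add(sample)
    merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    return JunctionCountTable(merged)


def strands_compatible(a: str, b: str) -> bool:
    """Opposite explicit strands are incompatible; unknown matches both."""
    return a == "." or b == "." or a == b


def build_exclusion_sets(
    junctions: Iterable[SpliceJunction],
) -> dict[SpliceJunction, frozenset[SpliceJunction]]:
    """Map each junction to the set of junctions that exclude it.

    ``j'`` excludes ``j`` iff they differ, share a contig, have compatible
    strands, and their intron intervals intersect with nonzero length
    under half-open semantics (sharing only a boundary is not overlap).
    The relation is symmetric.
    """
    junctions = list(junctions)
    by_contig: dict[str, list[SpliceJunction]] = {}
    for j in junctions:
        by_contig.setdefault(j.contig, []).append(j)

    exclusion: dict[SpliceJunction, set[SpliceJunction]] = {j: set() for j in junctions}
    for group in by_contig.values():
        group.sort(key=lambda j: (j.start, j.end))
        # sweep: compare each junction with later ones starting before its end
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.start >= a.end:
                    break
                if a is b or not strands_compatible(a.strand, b.strand):
                    continue
                exclusion[a].add(b)
                exclusion[b].add(a)
    return {j: frozenset(s) for j, s in exclusion.items()}


def percent_spliced(
    table: JunctionCountTable,
    exclusion: Mapping[SpliceJunction, frozenset[SpliceJunction]],
) -> PSMatrix:
    """PS(j, s) = count(j, s) / (count(j, s) + sum of exclusion counts).

    Undefined (NaN) where the denominator is zero.
    """
    counts = table.counts
    index = {j: i for i, j in enumerate(counts.index)}
    values = counts.to_numpy(dtype=float)
    ps = np.full_like(values, np.nan)
    for j, row in index.items():
        excl_rows = [index[e] for e in exclusion.get(j, frozenset()) if e in index]
        denom = values[row] + (
            values[excl_rows].sum(axis=0) if excl_rows else 0.0
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            ps[row] = np.where(denom > 0, values[row] / denom, np.nan)
    return PSMatrix(pd.DataFrame(ps, index=counts.index, columns=counts.columns))
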