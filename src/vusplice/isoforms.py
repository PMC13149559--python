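"""Isoform abundance fractions, structural classification, and protein consequence.

Isoforms are compared by their intron chains (splice-junction sets), so a
transcript that differs from the canonical model only in terminal-exon
length is still a structural match.  Protein consequences are obtained by
splicing the candidate's exonic sequence, translating from the canonical
start codon, and diffing the peptides, reported in HGVS p. style.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "TranscriptModel",
    "IsoformAbundance",
    "IsoformClassification",
    "ProteinConsequence",
    "parse_gtf_transcripts",
    "write_gtf",
    "isoform_fractions",
    "classify_isoform",
    "predict_protein_consequence",
]

Interval = tuple[int, int]  # 0-based half-open genomic interval


def _check_chain(intervals: Sequence[Interval], what: str) -> list[Interval]:
    chain = sorted(tuple(map(int, iv)) for iv in intervals)
    for start, end in chain:
        if not start < end:
            raise ValueError(f"{what} interval invalid: [{start}, {end})")
    for (s0, e0), (s1, e1) in zip(chain, chain[1:]):
        if s1 < e0:
            raise ValueError(f"{what} intervals overlap: [{s0},{e0}) and [{s1},{e1})")
    return chain


@dataclass(frozen=True)
class TranscriptModel:
    """Exon chain (and optional CDS) of one transcript on one contig."""

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("transcript strand must be + or -")
        object.__setattr__(self, "exons", tuple(_check_chain(self.exons, "exon")))
        if self.cds:
            cds = tuple(_check_chain(self.cds, "CDS"))
            for c in cds:
                if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                    raise ValueError(f"CDS interval {c} not contained in any exon")
            object.__setattr__(self, "cds", cds)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])
        )

    @property
    def start_codon_position(self) -> int | None:
        """Genomic coordinate of the first base of the start codon."""
        if not self.cds:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1

    def spliced_sequence(
        self, genome: Mapping[str, str], intervals: Sequence[Interval] | None = None
    ) -> str:
        """Concatenate interval sequences in transcript (5'->3') order."""
        if self.contig not in genome:
            raise KeyError(f"contig {self.contig!r} missing from genome")
        contig_seq = genome[self.contig]
        intervals = list(self.exons if intervals is None else intervals)
        parts = [contig_seq[s:e] for s, e in intervals]
        mrna = "".join(parts).upper()
        if self.strand == "-":
            mrna = str(Seq(mrna).reverse_complement())
        return mrna

    def genomic_to_transcript(self, position: int) -> int | None:
        """Map a genomic coordinate into spliced-mRNA coordinates (0-based)."""
        offset = 0
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for start, end in exons:
            if start <= position < end:
                within = position - start if self.strand == "+" else end - 1 - position
                return offset + within
            offset += end - start
        return None


@dataclass(frozen=True)
class IsoformAbundance:
    transcript_id: str
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"TPM must be >= 0, got {self.tpm}")


@dataclass(frozen=True)
class IsoformClassification:
    """Structural verdict versus the canonical transcript.

    Categories: ``canonical_match`` (identical intron chain),
    ``exon_skipping`` (one or more whole canonical exons spliced out),
    ``altered_splice_site`` (one intron boundary shifted), ``other``.
    """

    transcript_id: str
    category: str
    skipped_exons: tuple[int, ...] = ()  # 1-based canonical exon ordinals
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category == "exon_skipping" and not self.skipped_exons:
            raise ValueError("exon_skipping requires at least one skipped ordinal")


@dataclass(frozen=True)
class ProteinConsequence:
    hgvs_p: str
    kind: str  # synonymous_structure | in_frame_deletion | frameshift | start_lost | other

    def __post_init__(self) -> None:
        if self.kind == "frameshift" and not re.match(
            r"p\.[A-Z][a-z]{2}\d+[A-Z][a-z]{2}fs\*(\d+|\?)$", self.hgvs_p
        ):
            raise ValueError(f"malformed frameshift description: {self.hgvs_p}")


# --------------------------------------------------------------------------
# GTF I/O

class GTFParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF 2.2 file.

    ``exon`` features are grouped per transcript and sorted by coordinate;
    ``CDS`` features are attached when present.  Every exon/CDS line must
    carry ``gene_id`` and ``transcript_id`` attributes.
    """
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, contig, strand)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(f"{path}:{lineno}: expected 9 columns")
            contig, _, feature, start, end, _, strand, _, attrs = fields
            if feature not in {"exon", "CDS"}:
                continue
            attributes = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attributes or "transcript_id" not in attributes:
                raise GTFParseError(
                    f"{path}:{lineno}: exon/CDS line lacks gene_id or transcript_id"
                )
            tx = attributes["transcript_id"]
            interval = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            prior = meta.setdefault(tx, (attributes["gene_id"], contig, strand))
            if prior != (attributes["gene_id"], contig, strand):
                raise GTFParseError(
                    f"{path}:{lineno}: inconsistent gene/contig/strand for {tx}"
                )
            (exons if feature == "exon" else cds).setdefault(tx, []).append(interval)
    models = []
    for tx, (gene, contig, strand) in meta.items():
        if tx not in exons:
            raise GTFParseError(f"transcript {tx} has CDS but no exon features")
        models.append(
            TranscriptModel(
                tx, gene, contig, strand,
                tuple(sorted(exons[tx])),
                tuple(sorted(cds.get(tx, []))),
            )
        )
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as handle:
        for model in models:
            attrs = f'gene_id "{model.gene_id}"; transcript_id "{model.transcript_id}";'
            for feature, chain in (("exon", model.exons), ("CDS", model.cds)):
                for start, end in chain:
                    handle.write(
                        "\t".join(
                            [
                                model.contig, "vusplice", feature,
                                str(start + 1), str(end), ".",
                                model.strand, ".", attrs,
                            ]
                        )
                        + "\n"
                    )


# --------------------------------------------------------------------------
# Abundance fractions

def isoform_fractions(
    abundances: Iterable[IsoformAbundance],
) -> dict[str, dict[str, float]]:
    """Per-gene transcript fractions: tpm_i / sum of the gene's TPMs.

    Genes whose total TPM is zero map to an empty dict (undefined).
    """
    totals: dict[str, float] = {}
    per_gene: dict[str, dict[str, float]] = {}
    for ab in abundances:
        per_gene.setdefault(ab.gene_id, {})
        if ab.transcript_id in per_gene[ab.gene_id]:
            raise ValueError(f"duplicate transcript {ab.transcript_id}")
        per_gene[ab.gene_id][ab.transcript_id] = ab.tpm
        totals[ab.gene_id] = totals.get(ab.gene_id, 0.0) + ab.tpm
    return {
        gene: (
            {tx: tpm / totals[gene] for tx, tpm in txs.items()}
            if totals[gene] > 0
            else {}
        )
        for gene, txs in per_gene.items()
    }


# --------------------------------------------------------------------------
# Structural classification

def classify_isoform(
    candidate: TranscriptModel, canonical: TranscriptModel
) -> IsoformClassification:
    """Classify a candidate's intron chain against the canonical chain."""
    if candidate.contig != canonical.contig or candidate.strand != canonical.strand:
        raise ValueError("candidate and canonical must share contig and strand")
    cand, ref = candidate.introns, canonical.introns
    if cand == ref:
        return IsoformClassification(candidate.transcript_id, "canonical_match")

    skipped = _match_as_exon_skip(cand, ref)
    if skipped is not None:
        # genomic exon ordinals -> transcript (5'->3') ordinals on minus strand
        n_exons = len(canonical.exons)
        if canonical.strand == "-":
            skipped = tuple(sorted(n_exons + 1 - o for o in skipped))
        return IsoformClassification(
            candidate.transcript_id,
            "exon_skipping",
            skipped_exons=skipped,
            detail=f"skipped canonical exon(s) {list(skipped)}",
        )

    shift = _match_as_boundary_shift(cand, ref)
    if shift is not None:
        return IsoformClassification(
            candidate.transcript_id,
            "altered_splice_site",
            detail=f"intron boundary shifted to {candidate.contig}:{shift}",
        )
    return IsoformClassification(candidate.transcript_id, "other")


def _match_as_exon_skip(
    cand: Sequence[Interval], ref: Sequence[Interval]
) -> tuple[int, ...] | None:
    """Skipped genomic exon ordinals if ``cand`` merges consecutive ref introns."""
    if not cand or len(cand) >= len(ref):
        return None
    starts = {iv[0]: i for i, iv in enumerate(ref)}
    ends = {iv[1]: i for i, iv in enumerate(ref)}
    skipped: list[int] = []
    covered: list[int] = []
    for start, end in cand:
        i = starts.get(start)
        j = ends.get(end)
        if i is None or j is None or j < i:
            return None
        covered.extend(range(i, j + 1))
        # merging ref introns i..j removes the exons between them
        skipped.extend(range(i + 2, j + 2))  # exon ordinal = intron index + 2
    if covered != list(range(len(ref))) or not skipped:
        return None
    return tuple(skipped)


def _match_as_boundary_shift(
    cand: Sequence[Interval], ref: Sequence[Interval]
) -> int | None:
    """New boundary coordinate if exactly one intron end moved, else None."""
    if len(cand) != len(ref):
        return None
    diffs = [(c, r) for c, r in zip(cand, ref) if c != r]
    if len(diffs) != 1:
        return None
    (c, r) = diffs[0]
    if c[0] == r[0] and c[1] != r[1]:
        return c[1]
    if c[1] == r[1] and c[0] != r[0]:
        return c[0]
    return None


# --------------------------------------------------------------------------
# Protein consequence

def _translate(seq: str) -> str:
    """Translate to the first stop codon (stop excluded), standard code."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def _has_stop(seq: str) -> bool:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return "*" in Seq(trimmed).translate()


def predict_protein_consequence(
    canonical: TranscriptModel,
    candidate: TranscriptModel,
    genome: Mapping[str, str],
) -> ProteinConsequence:
    """Diff the candidate's predicted peptide against the canonical peptide.

    The candidate's exonic sequence is spliced and translated from the
    canonical start codon's genomic position.  Outcomes:

    - identical peptide -> ``synonymous_structure`` ``p.(=)``
    - a contiguous residue run deleted with frame and flanks preserved ->
      ``in_frame_deletion`` (``p.X10_Y19del`` style, most C-terminal
      placement of the deleted run)
    - peptides diverge at some residue with a downstream frame change ->
      ``frameshift`` ``p.<Ref><pos><Alt>fs*<n>`` where *n* counts the
      first changed residue as 1 and points at the new stop
    - start codon absent from the candidate -> ``start_lost``
    - anything else (stop gain/loss, delins at the junction) -> ``other``
    """
    if not canonical.cds:
        raise ValueError("canonical transcript has no CDS")
    ref_cds = canonical.spliced_sequence(genome, canonical.cds)
    ref_pep = _translate(ref_cds)
    if "*" not in str(Seq(ref_cds[: len(ref_cds) - len(ref_cds) % 3]).translate()):
        raise ValueError("canonical CDS does not terminate at a stop codon")

    start_genomic = canonical.start_codon_position
    offset = candidate.genomic_to_transcript(start_genomic)
    if offset is None:
        return ProteinConsequence("p.Met1?", "start_lost")
    mrna = candidate.spliced_sequence(genome)
    coding = mrna[offset:]
    if not coding.startswith("ATG"):
        return ProteinConsequence("p.Met1?", "start_lost")
    alt_pep = _translate(coding)
    alt_terminated = _has_stop(coding)

    if alt_pep == ref_pep and alt_terminated:
        return ProteinConsequence("p.(=)", "synonymous_structure")

    prefix = _common_prefix(ref_pep, alt_pep)

    d = len(ref_pep) - len(alt_pep)
    if d > 0 and alt_terminated and ref_pep[prefix + d :] == alt_pep[prefix:]:
        # clean in-frame deletion of ref residues prefix+1 .. prefix+d
        first, last = prefix + 1, prefix + d
        if first == last:
            hgvs = f"p.{seq3(ref_pep[first - 1])}{first}del"
        else:
            hgvs = (
                f"p.{seq3(ref_pep[first - 1])}{first}"
                f"_{seq3(ref_pep[last - 1])}{last}del"
            )
        return ProteinConsequence(hgvs, "in_frame_deletion")

    pos = prefix  # 0-based index of first divergent residue
    if pos == len(ref_pep):
        # reference stop lost; extension
        ext = seq3(alt_pep[pos]) if pos < len(alt_pep) else ""
        return ProteinConsequence(f"p.*{pos + 1}{ext}ext*?", "other")
    if pos == len(alt_pep):
        if alt_terminated:
            # premature stop at the first changed position
            return ProteinConsequence(f"p.{seq3(ref_pep[pos])}{pos + 1}*", "other")
        return ProteinConsequence(f"p.{seq3(ref_pep[pos])}{pos + 1}?", "other")

    ref_aa = seq3(ref_pep[pos])
    alt_aa = seq3(alt_pep[pos])
    stop = str(len(alt_pep) - pos + 1) if alt_terminated else "?"
    return ProteinConsequence(f"p.{ref_aa}{pos + 1}{alt_aa}fs*{stop}", "frameshift")


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


# --------------------------------------------------------------------------
# Abundance table I/O

def read_abundance_tsv(path: str | Path) -> list[IsoformAbundance]:
    """Read a TSV with columns transcript_id, gene_id, TPM."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("transcript_id", "gene_id", "tpm"):
        if needed not in cols:
            raise ValueError(f"{path}: missing column {needed!r}")
    return [
        IsoformAbundance(
            str(row[cols["transcript_id"]]),
            str(row[cols["gene_id"]]),
            float(row[cols["tpm"]]),
        )
        for _, row in df.iterrows()
    ]


def write_abundance_tsv(
    abundances: Iterable[IsoformAbundance], path: str | Path
) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {"transcript_id": a.transcript_id, "gene_id": a.gene_id, "TPM": a.tpm}
            for a in abundances
        ]
    ).to_csv(path, sep="\t", index=False)
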