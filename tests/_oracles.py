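"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — interval
scans, a dict-based codon table, string splicing — so it shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np

# --------------------------------------------------------------------------
# Percent-spliced brute force

def brute_force_ps(junctions, counts):
    """PS per junction per sample by re-scanning all junctions for overlap.

    ``junctions``: list of (contig, start, end, strand) tuples;
    ``counts``: dict junction-tuple -> list of per-sample counts.
    Returns dict junction-tuple -> list of PS (None when denominator 0).
    """
    n_samples = len(next(iter(counts.values())))
    result = {}
    for j in junctions:
        partners = []
        for other in junctions:
            if other == j:
                continue
            if other[0] != j[0]:
                continue
            sa, sb = j[3], other[3]
            if sa in "+-" and sb in "+-" and sa != sb:
                continue
            # nonzero-length intersection of half-open intervals
            if max(j[1], other[1]) < min(j[2], other[2]):
                partners.append(other)
        ps_row = []
        for s in range(n_samples):
            denom = counts[j][s] + sum(counts[p][s] for p in partners)
            ps_row.append(counts[j][s] / denom if denom > 0 else None)
        result[j] = ps_row
    return result


# --------------------------------------------------------------------------
# Codon-by-codon translation and consequence diff

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[base] for base in reversed(seq))


def translate_to_stop(seq: str) -> tuple[str, bool]:
    """(peptide, saw_stop) translating codon by codon from position 0."""
    peptide = []
    for i in range(0, len(seq) - 2, 3):
        aa = CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(peptide), True
        peptide.append(aa)
    return "".join(peptide), False


def consequence_oracle(ref_cds: str, alt_coding: str) -> tuple[str, str]:
    """(hgvs_p, kind) from the reference CDS and the candidate's coding
    sequence (candidate mRNA from the start codon onward).

    Conventions: deletions are placed 3'-most (longest common prefix),
    fs*n counts the first changed residue as 1.
    """
    ref_pep, _ = translate_to_stop(ref_cds)
    if not alt_coding.startswith("ATG"):
        return "p.Met1?", "start_lost"
    alt_pep, alt_stop = translate_to_stop(alt_coding)
    if alt_pep == ref_pep and alt_stop:
        return "p.(=)", "synonymous_structure"

    prefix = 0
    limit = min(len(ref_pep), len(alt_pep))
    while prefix < limit and ref_pep[prefix] == alt_pep[prefix]:
        prefix += 1

    d = len(ref_pep) - len(alt_pep)
    if d > 0 and alt_stop and ref_pep[prefix + d :] == alt_pep[prefix:]:
        first, last = prefix + 1, prefix + d
        if first == last:
            return f"p.{AA3[ref_pep[first - 1]]}{first}del", "in_frame_deletion"
        return (
            f"p.{AA3[ref_pep[first - 1]]}{first}_{AA3[ref_pep[last - 1]]}{last}del",
            "in_frame_deletion",
        )

    if prefix == len(ref_pep):
        ext = AA3[alt_pep[prefix]] if prefix < len(alt_pep) else ""
        return f"p.*{prefix + 1}{ext}ext*?", "other"
    if prefix == len(alt_pep):
        if alt_stop:
            return f"p.{AA3[ref_pep[prefix]]}{prefix + 1}*", "other"
        return f"p.{AA3[ref_pep[prefix]]}{prefix + 1}?", "other"

    stop = str(len(alt_pep) - prefix + 1) if alt_stop else "?"
    return (
        f"p.{AA3[ref_pep[prefix]]}{prefix + 1}{AA3[alt_pep[prefix]]}fs*{stop}",
        "frameshift",
    )


# --------------------------------------------------------------------------
# Random toy gene construction

def random_coding_exons(rng: np.random.Generator, n_exons: int) -> list[str]:
    """Exon sequences whose concatenation is ATG + stop-free codons + TAA,
    split at random (not necessarily codon-aligned) boundaries, plus a
    3' tail containing stops in every reading frame."""
    n_codons = int(rng.integers(12, 40))
    sense = [c for c, aa in CODON_TABLE.items() if aa not in "*M"]
    cds = "ATG" + "".join(rng.choice(sense) for _ in range(n_codons)) + "TAA"
    tail = "TAAGTAACGTAATTAAC" * 3  # stops reachable from any frame shift
    full = cds + tail
    cuts = sorted(rng.choice(np.arange(4, len(cds) - 4), size=n_exons - 1,
                             replace=False))
    bounds = [0, *map(int, cuts), len(full)]
    return [full[a:b] for a, b in zip(bounds, bounds[1:])], len(cds)


def build_toy_gene(rng: np.random.Generator, n_exons: int, strand: str):
    """Return (genome dict, exon intervals, cds intervals, exon seqs, cds_len).

    Intervals are genomic 0-based half-open on contig 'toy'; for the minus
    strand the transcript-order exon sequences are laid out right to left
    and reverse-complemented into the genome.
    """
    exon_seqs, cds_len = random_coding_exons(rng, n_exons)
    intron = lambda: "GT" + "".join(rng.choice(list("ACGT"),
                                    size=int(rng.integers(20, 60)))) + "AG"
    pad = "".join(rng.choice(list("ACGT"), size=10))
    pieces, intervals = [pad], []
    pos = len(pad)
    order = exon_seqs if strand == "+" else [revcomp(s) for s in exon_seqs[::-1]]
    for i, seq in enumerate(order):
        intervals.append((pos, pos + len(seq)))
        pieces.append(seq)
        pos += len(seq)
        if i < len(order) - 1:
            ivs = intron()
            pieces.append(ivs)
            pos += len(ivs)
    pieces.append(pad)
    genome = {"toy": "".join(pieces)}

    # CDS intervals: first cds_len transcript bases mapped onto exons
    tx_intervals = intervals if strand == "+" else intervals[::-1]
    cds_intervals, remaining = [], cds_len
    for start, end in tx_intervals:
        take = min(remaining, end - start)
        if take <= 0:
            break
        if strand == "+":
            cds_intervals.append((start, start + take))
        else:
            cds_intervals.append((end - take, end))
        remaining -= take
    return genome, intervals, sorted(cds_intervals), exon_seqs, cds_len
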