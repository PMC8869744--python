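"""Small-RNA annotation: read matching, genomic clusters, seed families.

Covers four tasks around the miRNA complement of a genome: assigning
sequenced small-RNA reads to known mature miRNAs under the permissive
end-variation rule; detecting genomic miRNA clusters (loci colocalized
within 10 kb, chained single-linkage per scaffold); grouping matures into
families by their nucleotide 2-8 seed (let-7: GAGGUAG); and classifying
lncRNAs that host or lie antisense to pre-miRNA loci (lncmiRHGs).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genomics import GenomicInterval, TranscriptModel, chain_intervals, to_rna

DEFAULT_MAX_GAP = 10_000
DEFAULT_END_TOLERANCE = 3
DEFAULT_MAX_MISMATCHES = 1

#: curated family names for well-known seeds; others are labelled by seed
CURATED_SEEDS = {
    "GAGGUAG": "let-7",
    "CCCUGAG": "miR-125b",
    "ACCCGUA": "miR-100",
}

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("U"): "U",
    frozenset("AG"): "R", frozenset("CU"): "Y", frozenset("GU"): "K",
    frozenset("AC"): "M", frozenset("CG"): "S", frozenset("AU"): "W",
    frozenset("CGU"): "B", frozenset("AGU"): "D", frozenset("ACU"): "H",
    frozenset("ACG"): "V", frozenset("ACGU"): "N",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed-table convention."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ReadAssignment:
    reference_id: str
    mismatches: int
    overlap: int


def match_read_to_mirna(
    read: str,
    references: dict[str, str],
    *,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> ReadAssignment | None:
    """Assign a small-RNA read to the best-matching mature miRNA.

    The read may be extended or trimmed by up to ``end_tolerance`` nt at
    each end relative to the reference; the overlapping region may carry
    at most ``max_mismatches`` internal mismatches. Best assignment =
    fewest mismatches, ties broken by longest overlap then lexicographic
    reference id. Returns None when nothing qualifies.
    """
    r = to_rna(read)
    if not 18 <= len(r) <= 28:
        raise ValueError(f"read length {len(r)} outside 18-28 nt")
    best: tuple[int, int, str] | None = None  # (mismatches, -overlap, id)
    for ref_id in sorted(references):
        ref = to_rna(references[ref_id])
        for offset in range(-end_tolerance, end_tolerance + 1):
            # offset = position of read start relative to reference start
            end_shift = offset + len(r) - len(ref)
            if abs(end_shift) > end_tolerance:
                continue
            lo = max(0, offset)
            hi = min(len(ref), offset + len(r))
            if hi - lo < 1:
                continue
            mism = sum(
                1 for k in range(lo, hi) if ref[k] != r[k - offset]
            )
            if mism > max_mismatches:
                continue
            cand = (mism, -(hi - lo), ref_id)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return ReadAssignment(best[2], best[0], -best[1])


def assign_reads(reads: list[str], references: dict[str, str], **kwargs) -> pd.DataFrame:
    rows = []
    for read in reads:
        try:
            a = match_read_to_mirna(read, references, **kwargs)
        except ValueError as e:
            rows.append({"read": read, "reference": None, "mismatches": None,
                         "status": str(e)})
            continue
        if a is None:
            rows.append({"read": read, "reference": None, "mismatches": None,
                         "status": "unassigned"})
        else:
            rows.append({"read": read, "reference": a.reference_id,
                         "mismatches": a.mismatches, "status": "assigned"})
    return pd.DataFrame(rows, columns=["read", "reference", "mismatches", "status"])


@dataclass
class MiRNACluster:
    id: str
    members: list[str]  # ordered by genomic position
    span: GenomicInterval

    def __len__(self) -> int:
        return len(self.members)


def detect_clusters(
    loci: list[TranscriptModel], max_gap: int = DEFAULT_MAX_GAP
) -> list[MiRNACluster]:
    """Single-linkage genomic clusters of miRNA loci within ``max_gap``.

    Loci are chained per scaffold when the end-to-start gap (floored at 0
    for overlaps) is at most ``max_gap``; the chain is transitive, strand
    is ignored, and singleton chains are discarded.
    """
    spans = [t.span for t in loci]
    clusters = []
    for chain in chain_intervals(spans, max_gap):
        if len(chain) < 2:
            continue
        members = [loci[i] for i in chain]
        span = GenomicInterval(
            members[0].scaffold,
            min(m.start for m in members),
            max(m.end for m in members),
        )
        clusters.append((span, [m.id for m in members]))
    clusters.sort(key=lambda c: (c[0].scaffold, c[0].start))
    return [
        MiRNACluster(f"cluster_{i + 1}", ids, span)
        for i, (span, ids) in enumerate(clusters)
    ]


def clustered_fraction(
    loci: list[TranscriptModel], clusters: list[MiRNACluster]
) -> tuple[int, int, float]:
    """(number of clusters, clustered loci, percentage to 0.1)."""
    if not loci:
        raise ValueError("no miRNA loci")
    n_clustered = sum(len(c) for c in clusters)
    return len(clusters), n_clustered, clustered_percentage(len(loci), n_clustered)


def clustered_percentage(total: int, clustered: int) -> float:
    """Percentage of clustered loci, half-up to one decimal (51.8 style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * clustered / total, 1)


def seed_family(matures: dict[str, str]) -> pd.DataFrame:
    """Group matures by their identical nucleotide 2-8 seed.

    Returns a frame indexed by miRNA id with columns seed and family;
    curated seeds carry their conventional names (let-7, miR-125b,
    miR-100), the rest are labelled by the seed string itself.
    """
    rows = []
    for mid in sorted(matures):
        seq = to_rna(matures[mid])
        if len(seq) < 8:
            raise ValueError(f"{mid}: sequence shorter than 8 nt has no seed")
        seed = seq[1:8]
        rows.append({"mirna": mid, "seed": seed,
                     "family": CURATED_SEEDS.get(seed, seed)})
    return pd.DataFrame(rows, columns=["mirna", "seed", "family"]).set_index("mirna")


def position_frequency_matrix(matures: list[str]) -> tuple[pd.DataFrame, str]:
    """Per-position nucleotide frequencies and majority consensus.

    Sequences are left-aligned (position 1 = 5' end) and padded at the 3'
    end; frequencies at each position are over the sequences long enough
    to reach it, so columns sum to 1. Ties in the consensus become IUPAC
    ambiguity codes.
    """
    if not matures:
        raise ValueError("no sequences")
    seqs = [to_rna(s) for s in matures]
    width = max(len(s) for s in seqs)
    records = []
    consensus = []
    for pos in range(width):
        chars = [s[pos] for s in seqs if len(s) > pos]
        counts = pd.Series(chars).value_counts()
        freq = {b: counts.get(b, 0) / len(chars) for b in "ACGU"}
        records.append(freq)
        top = counts.max()
        winners = frozenset(counts.index[counts == top])
        consensus.append(_IUPAC.get(winners, "N"))
    pfm = pd.DataFrame(records, index=pd.RangeIndex(1, width + 1, name="position"))
    return pfm, "".join(consensus)


def classify_host_relation(lnc: TranscriptModel, locus: TranscriptModel) -> str:
    """Relation of an lncRNA to a pre-miRNA locus.

    host_exonic: precursor fully inside an lncRNA exon, same strand;
    host_intronic: fully inside the lncRNA genomic span but not exonic,
    same strand; antisense: any overlap on the opposite strand; none
    otherwise.
    """
    pre = locus.span
    if lnc.scaffold != pre.scaffold:
        return "none"
    overlap = lnc.span.start <= pre.end and pre.start <= lnc.span.end
    if lnc.strand != locus.strand:
        return "antisense" if overlap else "none"
    for e in lnc.exons:
        if e.start <= pre.start and pre.end <= e.end:
            return "host_exonic"
    if lnc.span.start <= pre.start and pre.end <= lnc.span.end:
        return "host_intronic"
    return "none"
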