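"""Genomic interval and transcript containers shared by all pipeline stages.

Coordinates are 1-based and inclusive throughout (GFF3 convention); any
0-based half-open export happens at the writer, never in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA alphabet)."""
    return seq.translate(COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.scaffold}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """End-to-start distance to a downstream interval, floored at 0."""
        return max(0, other.start - self.end)


@dataclass
class TranscriptModel:
    """A multi-exon transcript anchored on one scaffold and strand.

    biotype is one of {coding, lnc_candidate, lncRNA, pre_miRNA}.
    """

    id: str
    gene_id: str
    scaffold: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "coding"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = 0
        for e in self.exons:
            if e.scaffold != self.scaffold or e.strand != self.strand:
                raise ValueError(f"{self.id}: exon scaffold/strand mismatch")
            if e.start <= prev_end:
                raise ValueError(f"{self.id}: overlapping or unsorted exons")
            prev_end = e.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.scaffold, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end > 1:
                out.append(
                    GenomicInterval(self.scaffold, a.end + 1, b.start - 1, self.strand)
                )
        return out

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Exonic sequence 5'->3' on the transcript strand."""
        seq = "".join(
            genome[self.scaffold][e.start - 1 : e.end] for e in self.exons
        )
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class GenomeAnnotation:
    """Gene -> transcript -> exon hierarchy for one assembly."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def add(self, tx: TranscriptModel) -> None:
        if tx.id in self.transcripts:
            raise ValueError(f"duplicate transcript id {tx.id}")
        self.transcripts[tx.id] = tx

    def by_biotype(self, biotype: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.biotype == biotype]

    @property
    def coding(self) -> list[TranscriptModel]:
        return self.by_biotype("coding")

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)


def chain_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int
) -> list[list[int]]:
    """Single-linkage chains of intervals within max_gap, per scaffold.

    Returns lists of indices into the input ordering, each chain sorted by
    start. A chain may have a single member; callers discard singletons when
    the semantics demand >= 2.
    """
    ivs = list(intervals)
    order = sorted(range(len(ivs)), key=lambda i: (ivs[i].scaffold, ivs[i].start, ivs[i].end))
    chains: list[list[int]] = []
    cur: list[int] = []
    cur_end = 0
    cur_scaffold = None
    for i in order:
        iv = ivs[i]
        if cur and iv.scaffold == cur_scaffold and max(0, iv.start - cur_end) <= max_gap:
            cur.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                chains.append(cur)
            cur = [i]
            cur_end = iv.end
            cur_scaffold = iv.scaffold
    if cur:
        chains.append(cur)
    return chains
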