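"""lncRNA candidate filtering and positional classification.

Candidates survive the intersection of structural and coding-potential
criteria (length > 200 nt, >= 2 exons, CPC < 0, CNCI < 0, CPAT < 0.85,
longest ORF <= 100 aa, no BLASTX or Pfam homology). Survivors are then
assigned one of four positional categories relative to protein-coding
genes: intergenic (lincRNA), intronic, antisense, or sense.

The external scorers (CPC, CNCI, CPAT, BLASTX, Pfam) are consumed as a
precomputed table; the BLASTX/Pfam booleans are expected to already embed
the usual homology gate (E-value < 1e-10, coverage > 85%, identity > 95%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .genomics import GenomicInterval, TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: order in which conflicting positional evidence is resolved
CATEGORY_PRECEDENCE = ("antisense", "sense", "intronic", "lincRNA")

FILTER_CRITERIA = ("length", "exons", "cpc", "cnci", "cpat", "orf", "blastx", "pfam")


@dataclass(frozen=True)
class CodingPotentialRecord:
    transcript_id: str
    cpc_score: float
    cnci_score: float
    cpat_prob: float
    longest_orf_aa: int
    blastx_hit: bool
    pfam_hit: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpat_prob <= 1.0:
            raise ValueError("cpat_prob must be in [0, 1]")
        if self.longest_orf_aa < 0:
            raise ValueError("longest_orf_aa must be >= 0")


def find_longest_orf(sequence: str) -> int:
    """Length in amino acids (stop excluded) of the longest forward-frame ORF.

    ORFs start at ATG and require an in-frame stop; codons containing N
    break the frame and cannot extend an ORF. Returns 0 when no complete
    ORF exists. The transcript is assumed already stranded, so only the
    three forward frames are scanned.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    best = 0
    for frame in range(3):
        open_start: int | None = None  # codon index of the earliest unclosed ATG
        n_codons = (len(seq) - frame) // 3
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
            if "N" in codon:
                open_start = None
                continue
            if codon in STOP_CODONS:
                if open_start is not None:
                    best = max(best, ci - open_start)
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = ci
    return best


def filter_lncrna_candidates(
    transcripts: list[TranscriptModel],
    records: pd.DataFrame,
    *,
    min_length: int = 200,
    min_exons: int = 2,
    cpat_max: float = 0.85,
    orf_max_aa: int = 100,
) -> tuple[set[str], dict[str, list[str]]]:
    """Apply the full candidate filter; return the pass set and reason codes.

    ``records`` is indexed by transcript id with the CodingPotentialRecord
    columns. A transcript passes iff length > min_length, exon count >=
    min_exons, CPC < 0, CNCI < 0, CPAT < cpat_max, longest ORF <=
    orf_max_aa, and neither homology flag is set. Failures carry every
    violated criterion.
    """
    passed: set[str] = set()
    reasons: dict[str, list[str]] = {}
    for tx in transcripts:
        if tx.id not in records.index:
            raise KeyError(f"no coding-potential record for transcript {tx.id}")
        rec = records.loc[tx.id]
        fails = []
        if tx.length <= min_length:
            fails.append("length")
        if tx.n_exons < min_exons:
            fails.append("exons")
        if not rec["cpc_score"] < 0:
            fails.append("cpc")
        if not rec["cnci_score"] < 0:
            fails.append("cnci")
        if not rec["cpat_prob"] < cpat_max:
            fails.append("cpat")
        if not rec["longest_orf_aa"] <= orf_max_aa:
            fails.append("orf")
        if rec["blastx_hit"]:
            fails.append("blastx")
        if rec["pfam_hit"]:
            fails.append("pfam")
        if fails:
            reasons[tx.id] = fails
        else:
            passed.add(tx.id)
    return passed, reasons


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(ea.start <= eb.end and eb.start <= ea.end
               for ea in a.exons for eb in b.exons
               if ea.scaffold == eb.scaffold)


def classify_lncrna(
    lnc: TranscriptModel,
    coding: list[TranscriptModel],
    *,
    intronic_same_strand: bool = False,
) -> str:
    """Positional category of an lncRNA relative to protein-coding genes.

    antisense: exon-overlaps a coding gene on the opposite strand;
    sense: exon-overlaps on the same strand; intronic: genomic span fully
    inside one intron of a coding gene (strand-agnostic unless
    ``intronic_same_strand``); lincRNA otherwise. When several genes give
    conflicting evidence, precedence is antisense > sense > intronic >
    lincRNA — exon-level evidence outranks intron containment.
    """
    span = lnc.span
    found = set()
    for gene in coding:
        if gene.scaffold != lnc.scaffold:
            continue
        if _exonic_overlap(lnc, gene):
            found.add("antisense" if gene.strand != lnc.strand else "sense")
            continue
        if intronic_same_strand and gene.strand != lnc.strand:
            continue
        for intron in gene.introns():
            if intron.start <= span.start and span.end <= intron.end:
                found.add("intronic")
                break
    for cat in CATEGORY_PRECEDENCE[:-1]:
        if cat in found:
            return cat
    return "lincRNA"


def classify_all(
    lncs: list[TranscriptModel],
    coding: list[TranscriptModel],
    **kwargs,
) -> pd.DataFrame:
    """Classify every lncRNA; the result is a partition (one row each)."""
    rows = [
        {"transcript_id": t.id, "category": classify_lncrna(t, coding, **kwargs)}
        for t in lncs
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "category"]).set_index(
        "transcript_id"
    )


#: the four evidence methods of the identification Venn diagram
VENN_METHODS = ("CPC", "CNCI", "CPAT", "homology")


def venn_partition(
    records: pd.DataFrame, *, cpat_max: float = 0.85, orf_max_aa: int = 100
) -> dict[tuple[str, ...], int]:
    """Counts of transcripts in each region of the four-method Venn diagram.

    Methods: CPC (cpc_score < 0), CNCI (cnci_score < 0), CPAT (cpat_prob
    below threshold, ORF within limit, no Pfam hit), homology (no BLASTX
    hit). Returns all 15 non-empty-subset regions keyed by the sorted
    method tuple; region counts sum to the number of transcripts passing
    at least one method.
    """
    passes = {
        "CPC": records["cpc_score"] < 0,
        "CNCI": records["cnci_score"] < 0,
        "CPAT": (records["cpat_prob"] < cpat_max)
        & (records["longest_orf_aa"] <= orf_max_aa)
        & ~records["pfam_hit"].astype(bool),
        "homology": ~records["blastx_hit"].astype(bool),
    }
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, 5):
        for subset in itertools.combinations(VENN_METHODS, r):
            in_subset = pd.Series(True, index=records.index)
            for m in VENN_METHODS:
                in_subset &= passes[m] if m in subset else ~passes[m]
            out[subset] = int(in_subset.sum())
    return out
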