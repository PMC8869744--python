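"""miRNA seed-match target prediction and lncRNA cis/trans target rules.

Seed sites follow the canonical taxonomy: the target is scanned for the
reverse complement of miRNA nucleotides 2-7 (the 6mer core); a match to
position 8 upgrades the site to 7mer-m8, an adenosine opposite position 1
to 7mer-A1, and both together to an 8mer. Site strength is gated by a
pairing-count duplex score (a self-contained stand-in for a thermodynamic
energy, with the same "keep sites below -10" semantics): the best ungapped
pairing of the miRNA 3' end against the 10 nt of target context 5' of the
site contributes -2 per Watson-Crick pair and -1 per G:U wobble, plus a
fixed site-type bonus (8mer -8, 7mer-m8 -6, 7mer-A1 -5, 6mer -3).

cis-targets of an lncRNA are coding genes within 100 kb of its genomic
span (closed boundary); trans-targets are genes whose expression profile
has |Pearson r| > 0.95 with the lncRNA on log2(TPM + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomics import TranscriptModel, revcomp, to_dna, to_rna

logger = logging.getLogger(__name__)

SITE_TYPE_BONUS = {"8mer": -8.0, "7mer-m8": -6.0, "7mer-A1": -5.0, "6mer": -3.0}

DEFAULT_SCORE_GATE = -10.0
DEFAULT_CIS_WINDOW = 100_000
DEFAULT_TRANS_R = 0.95

_PAIR_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_PAIR_GU = {("G", "T"), ("T", "G")}  # G:U wobble in DNA alphabet
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence; the seed is nucleotides 2-8."""

    id: str
    sequence: str  # stored as RNA
    family: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_rna(self.sequence))
        if not 18 <= len(self.sequence) <= 28:
            raise ValueError(f"{self.id}: mature length must be 18-28 nt")

    @property
    def seed(self) -> str:
        return self.sequence[1:8]


@dataclass
class SeedMatch:
    """One predicted site: 1-based start of the 6mer core in the target."""

    mirna_id: str
    target_id: str
    start: int
    site_type: str
    duplex_score: float | None = None


def find_seed_matches(mirna: MatureMiRNA, target: str,
                      target_id: str = "") -> list[SeedMatch]:
    """All seed sites of one miRNA in one target sequence, sorted by position.

    Scans for the reverse complement of seed nucleotides 2-7 and classifies
    each hit by the position-8 match and the A opposite position 1.
    """
    t = to_dna(target)
    m = to_dna(mirna.sequence)
    core = revcomp(m[1:7])  # target-sense 6mer
    p8c = _COMP[m[7]]
    out: list[SeedMatch] = []
    for i in range(len(t) - 5):
        if t[i : i + 6] != core:
            continue
        m8 = i > 0 and t[i - 1] == p8c
        a1 = i + 6 < len(t) and t[i + 6] == "A"
        if m8 and a1:
            st = "8mer"
        elif m8:
            st = "7mer-m8"
        elif a1:
            st = "7mer-A1"
        else:
            st = "6mer"
        out.append(SeedMatch(mirna.id, target_id, i + 1, st))
    return out


def _pairing_strength(m3: str, context: str) -> float:
    """Best ungapped antiparallel pairing score (2 per WC, 1 per wobble)."""
    c_rev = context[::-1]  # align 5'->3' miRNA tail against 3'->5' target
    best = 0
    if not m3 or not c_rev:
        return 0.0
    for shift in range(-(len(m3) - 1), len(c_rev)):
        s = 0
        for j, base in enumerate(m3):
            k = shift + j
            if 0 <= k < len(c_rev):
                pair = (base, c_rev[k])
                if pair in _PAIR_WC:
                    s += 2
                elif pair in _PAIR_GU:
                    s += 1
        best = max(best, s)
    return float(best)


def duplex_score(mirna: MatureMiRNA, window: str, site_type: str) -> float:
    """Proxy duplex score for a site given its target window.

    ``window`` must cover the site preceded by (up to) 10 nt of the target
    context that pairs the miRNA 3' end; lower scores mean stronger sites.
    """
    w = to_dna(window)
    if len(w) < 6:
        raise ValueError("window shorter than the seed")
    if site_type not in SITE_TYPE_BONUS:
        raise ValueError(f"unknown site type {site_type!r}")
    site_len = 6 + (site_type in ("8mer", "7mer-m8"))
    context = w[: max(0, len(w) - site_len)][-10:]
    m3 = to_dna(mirna.sequence)[8:]
    return -_pairing_strength(m3, context) + SITE_TYPE_BONUS[site_type]


def score_sites(mirna: MatureMiRNA, target: str, matches: list[SeedMatch]) -> list[SeedMatch]:
    """Attach duplex scores to seed matches found in ``target``."""
    t = to_dna(target)
    scored = []
    for m in matches:
        i = m.start - 1  # 0-based core start
        site_start = i - 1 if m.site_type in ("8mer", "7mer-m8") else i
        window = t[max(0, site_start - 10) : i + 6]
        scored.append(replace(m, duplex_score=duplex_score(mirna, window, m.site_type)))
    return scored


def predict_targets(
    mirna: MatureMiRNA,
    targets: dict[str, str],
    *,
    score_gate: float = DEFAULT_SCORE_GATE,
) -> list[SeedMatch]:
    """Seed-scan every target and keep sites scoring below the gate."""
    kept: list[SeedMatch] = []
    for tid in sorted(targets):
        matches = find_seed_matches(mirna, targets[tid], tid)
        for m in score_sites(mirna, targets[tid], matches):
            if m.duplex_score < score_gate:
                kept.append(m)
    return kept


def context_percentile_filter(
    sites: list[SeedMatch], keep_fraction: float = 0.5
) -> list[SeedMatch]:
    """Keep the better-scoring fraction of sites per miRNA.

    A rank-based stand-in for a context-score percentile cutoff; with the
    default 0.5 the better half (ceil) of each miRNA's sites survives.
    """
    by_mirna: dict[str, list[SeedMatch]] = {}
    for s in sites:
        by_mirna.setdefault(s.mirna_id, []).append(s)
    kept: list[SeedMatch] = []
    for group in by_mirna.values():
        group = sorted(group, key=lambda s: (s.duplex_score, s.target_id, s.start))
        kept.extend(group[: math.ceil(len(group) * keep_fraction)])
    return sorted(kept, key=lambda s: (s.mirna_id, s.target_id, s.start))


def sites_to_frame(sites: list[SeedMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna": s.mirna_id, "target": s.target_id, "pos": s.start,
             "site_type": s.site_type, "duplex_score": s.duplex_score}
            for s in sites
        ],
        columns=["mirna", "target", "pos", "site_type", "duplex_score"],
    )


def cis_targets(
    lnc: TranscriptModel,
    genes: list[TranscriptModel],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[str]:
    """Coding genes within ``window`` bases of the lncRNA span (closed).

    A gene starting exactly ``window`` bases downstream still counts. The
    lncRNA's own host gene (same gene id) is excluded.
    """
    lo, hi = lnc.start - window, lnc.end + window
    out = [
        g.id
        for g in genes
        if g.scaffold == lnc.scaffold
        and g.start <= hi
        and g.end >= lo
        and g.gene_id != lnc.gene_id
    ]
    return sorted(out)


def trans_targets(
    lnc_tpm: pd.DataFrame,
    mrna_tpm: pd.DataFrame,
    r_threshold: float = DEFAULT_TRANS_R,
) -> pd.DataFrame:
    """lncRNA-mRNA pairs with |Pearson r| above threshold on log2(TPM+1).

    Zero-variance features are skipped (logged). Returns a frame with
    columns lncrna, mrna, r sorted by ids.
    """
    if list(lnc_tpm.columns) != list(mrna_tpm.columns):
        raise ValueError("lncRNA and mRNA matrices must share samples")
    if lnc_tpm.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    lx = np.log2(lnc_tpm.to_numpy(dtype=float) + 1.0)
    mx = np.log2(mrna_tpm.to_numpy(dtype=float) + 1.0)

    def _standardize(x: np.ndarray, names: pd.Index, label: str):
        sd = x.std(axis=1, ddof=1)
        ok = sd > 0
        for name in names[~ok]:
            logger.info("trans_targets: skipping zero-variance %s %s", label, name)
        z = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        return z, names[ok]

    lz, lnames = _standardize(lx, lnc_tpm.index, "lncRNA")
    mz, mnames = _standardize(mx, mrna_tpm.index, "mRNA")
    if len(lnames) == 0 or len(mnames) == 0:
        return pd.DataFrame(columns=["lncrna", "mrna", "r"])
    r = (lz @ mz.T) / (lx.shape[1] - 1)
    r = np.clip(r, -1.0, 1.0)
    li, mi = np.nonzero(np.abs(r) > r_threshold)
    out = pd.DataFrame(
        {"lncrna": lnames[li], "mrna": mnames[mi], "r": r[li, mi]}
    )
    return out.sort_values(["lncrna", "mrna"], ignore_index=True)
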