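"""Planted-truth simulator for the gonad ceRNA inference pipeline.

Emulates the study design the pipeline targets: a small multi-scaffold
genome carrying protein-coding genes, lncRNAs in the four positional
classes, and pre-miRNA loci arranged in genomic clusters; two groups
(ovary vs testis, three replicates each) of negative-binomial counts with
planted sex-biased fold changes; ceRNA triplets whose lncRNA and mRNA
carry an 8mer seed site for the shared miRNA and are driven by a shared
latent factor so their co-expression survives the downstream Pearson gate.

Everything is deterministic for a fixed seed; planted structure is
returned as a :class:`SimTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .genomics import GenomeAnnotation, GenomicInterval, TranscriptModel, revcomp

#: independent criteria emulated by the coding-potential score table
N_SCORE_CRITERIA = 6

#: positional mixture for planted lncRNAs (lincRNA share absorbs rounding)
LNC_CLASS_MIX = {"antisense": 0.25, "intronic": 0.12, "sense": 0.08}

#: slot spacing keeps every pair of features from different slots > 10 kb apart
_MIN_SLOT_GAP, _MAX_SLOT_GAP = 12_000, 20_000

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimSizingError(ValueError):
    """Raised when the requested features do not fit on the toy genome."""


@dataclass
class SimConfig:
    n_scaffolds: int = 3
    scaffold_length: int = 1_500_000
    n_genes: int = 60
    n_lncrnas: int = 40
    n_mirnas: int = 24
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.05
    de_fraction: float = 0.3
    de_log2fc: float = 4.0
    cluster_spec: list[tuple[int, int]] = field(
        default_factory=lambda: [(3, 2000), (2, 5000), (4, 3000)]
    )
    triplet_spec: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_scaffolds", "scaffold_length", "n_genes", "n_lncrnas",
                     "n_mirnas", "n_samples_per_group"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for count, gap in self.cluster_spec:
            if count < 2:
                raise ValueError("planted clusters need >= 2 members")
            if gap > 10_000:
                raise ValueError("planted intra-cluster gap must be <= 10 kb")
        if sum(c for c, _ in self.cluster_spec) > self.n_mirnas:
            raise ValueError("cluster_spec asks for more miRNA loci than n_mirnas")
        if self.triplet_spec < 0:
            raise ValueError("triplet_spec must be >= 0")
        if self.triplet_spec > 0 and self.triplet_spec > min(
            self.n_genes, self.n_lncrnas, self.n_mirnas
        ):
            raise ValueError("triplet_spec exceeds available features")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic annotation."""

    de_features: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    planted_clusters: list[list[str]] = field(default_factory=list)
    true_lncrnas: set[str] = field(default_factory=set)
    mrna_ids: list[str] = field(default_factory=list)
    lncrna_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)
    mature_sequences: dict[str, str] = field(default_factory=dict)
    lnc_classes: dict[str, str] = field(default_factory=dict)
    planted_hosts: list[tuple[str, str, str]] = field(default_factory=list)
    seed: int = 0


class _Placer:
    """Sequential slot allocator: one feature group per slot, > 10 kb apart."""

    def __init__(self, scaffolds: list[str], length: int, rng: np.random.Generator):
        self.cursors = {s: 1 for s in scaffolds}
        self.length = length
        self.rng = rng
        self.scaffolds = scaffolds

    def place(self, span: int) -> tuple[str, int]:
        gap = int(self.rng.integers(_MIN_SLOT_GAP, _MAX_SLOT_GAP + 1))
        for s in self.scaffolds:
            start = self.cursors[s] + gap
            if start + span + 1000 <= self.length:
                self.cursors[s] = start + span
                return s, start
        fullest = self.scaffolds[-1] if self.scaffolds else "<none>"
        raise SimSizingError(
            f"scaffold {fullest} too short ({self.length} bp) to place a "
            f"feature of span {span} bp; increase scaffold_length"
        )


def _random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        f"scaffold_{i + 1}": _BASES[rng.integers(0, 4, size=config.scaffold_length)].copy()
        for i in range(config.n_scaffolds)
    }


def _make_exons(scaffold: str, strand: str, start: int, exon_lens: list[int],
                intron_lens: list[int]) -> list[GenomicInterval]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(scaffold, pos, pos + el - 1, strand))
        if i < len(intron_lens):
            pos = pos + el + intron_lens[i]
    return exons


def generate_annotation(
    config: SimConfig,
) -> tuple[GenomeAnnotation, dict, SimTruth]:
    """Build the toy genome, its annotation, and the planted truth.

    Returns ``(annotation, sequences, truth)`` where ``sequences`` maps
    ``genome`` (scaffold -> str), ``transcripts`` (id -> spliced sequence),
    ``mature_mirna`` (locus id -> 22-nt RNA string) and ``utr3``
    (mRNA id -> last-exon sequence, the planted 3'-UTR).
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(config, rng)
    ann = GenomeAnnotation(scaffold_lengths={s: config.scaffold_length for s in genome})
    truth = SimTruth(seed=config.seed)
    placer = _Placer(list(genome), config.scaffold_length, rng)

    # ---- attached-lncRNA bookkeeping -------------------------------------
    n_intronic = min(round(LNC_CLASS_MIX["intronic"] * config.n_lncrnas), config.n_genes)
    n_anti = min(round(LNC_CLASS_MIX["antisense"] * config.n_lncrnas),
                 max(0, config.n_genes - n_intronic))
    n_sense = min(round(LNC_CLASS_MIX["sense"] * config.n_lncrnas),
                  max(0, config.n_genes - n_intronic - n_anti))

    # ---- protein-coding genes --------------------------------------------
    genes: list[TranscriptModel] = []
    for i in range(config.n_genes):
        n_ex = int(rng.integers(1, 21))
        if i < n_intronic and n_ex < 2:
            n_ex = 2
        exon_lens = [int(x) for x in rng.integers(100, 301, size=n_ex)]
        intron_lens = [int(x) for x in rng.integers(200, 2001, size=max(0, n_ex - 1))]
        if i < n_intronic and intron_lens:
            intron_lens[0] = 3000  # guarantees room for an intronic lncRNA
        strand = "+" if i >= config.n_genes - config.triplet_spec else str(rng.choice(["+", "-"]))
        span = sum(exon_lens) + sum(intron_lens)
        scaffold, start = placer.place(span)
        tx = TranscriptModel(
            id=f"mrna_{i:04d}", gene_id=f"gene_{i:04d}", scaffold=scaffold,
            strand=strand, exons=_make_exons(scaffold, strand, start, exon_lens, intron_lens),
            biotype="coding",
        )
        genes.append(tx)
        ann.add(tx)
        truth.mrna_ids.append(tx.id)

    # ---- miRNA loci: planted clusters, then isolated ----------------------
    mir_loci: list[TranscriptModel] = []
    mir_idx = 0

    def _add_locus(scaffold: str, start: int, length: int, strand: str) -> TranscriptModel:
        nonlocal mir_idx
        tx = TranscriptModel(
            id=f"mir_{mir_idx:04d}", gene_id=f"mir_{mir_idx:04d}", scaffold=scaffold,
            strand=strand,
            exons=[GenomicInterval(scaffold, start, start + length - 1, strand)],
            biotype="pre_miRNA",
        )
        mir_idx += 1
        mir_loci.append(tx)
        ann.add(tx)
        truth.mirna_ids.append(tx.id)
        return tx

    for ci, (count, intra_gap) in enumerate(config.cluster_spec):
        lens = [int(x) for x in rng.integers(80, 101, size=count)]
        span = sum(lens) + intra_gap * (count - 1)
        strand = "+" if ci == 0 else str(rng.choice(["+", "-"]))
        scaffold, start = placer.place(span)
        members = []
        pos = start
        for L in lens:
            members.append(_add_locus(scaffold, pos, L, strand))
            pos = pos + L + intra_gap  # gap = next.start - cur.end
        truth.planted_clusters.append([m.id for m in members])
    n_isolated = config.n_mirnas - sum(c for c, _ in config.cluster_spec)
    isolated: list[TranscriptModel] = []
    for _ in range(n_isolated):
        L = int(rng.integers(80, 101))
        scaffold, start = placer.place(L)
        isolated.append(_add_locus(scaffold, start, L, str(rng.choice(["+", "-"]))))

    # ---- lncRNAs ----------------------------------------------------------
    lncs: list[TranscriptModel] = []
    lnc_idx = 0

    def _add_lnc(exons: list[GenomicInterval], category: str) -> TranscriptModel:
        nonlocal lnc_idx
        tx = TranscriptModel(
            id=f"lnc_{lnc_idx:04d}", gene_id=f"lnc_{lnc_idx:04d}",
            scaffold=exons[0].scaffold, strand=exons[0].strand, exons=exons,
            biotype="lnc_candidate",
        )
        lnc_idx += 1
        lncs.append(tx)
        ann.add(tx)
        truth.lncrna_ids.append(tx.id)
        truth.true_lncrnas.add(tx.id)
        truth.lnc_classes[tx.id] = category
        return tx

    n_hosts = 0
    if config.n_lncrnas >= 2 and truth.planted_clusters:
        # host lncRNA whose first exon covers the whole first planted cluster
        members = [ann.transcripts[m] for m in truth.planted_clusters[0]]
        sc = members[0].scaffold
        strand = members[0].strand
        lo, hi = members[0].start - 100, members[-1].end + 100
        host = _add_lnc(
            [GenomicInterval(sc, lo, hi, strand),
             GenomicInterval(sc, hi + 200, hi + 400, strand)],
            "lincRNA",
        )
        for m in members:
            truth.planted_hosts.append((host.id, m.id, "host_exonic"))
        n_hosts += 1
        if isolated:
            tgt = isolated[0]
            anti_strand = "-" if tgt.strand == "+" else "+"
            anti = _add_lnc(
                [GenomicInterval(tgt.scaffold, tgt.start - 50, tgt.end + 50, anti_strand),
                 GenomicInterval(tgt.scaffold, tgt.end + 250, tgt.end + 400, anti_strand)],
                "lincRNA",
            )
            truth.planted_hosts.append((anti.id, tgt.id, "antisense"))
            n_hosts += 1

    n_free = config.n_lncrnas - n_hosts
    n_intronic = min(n_intronic, n_free)
    n_anti = min(n_anti, max(0, n_free - n_intronic))
    n_sense = min(n_sense, max(0, n_free - n_intronic - n_anti))
    n_linc = n_free - n_intronic - n_anti - n_sense
    gene_cursor = 0

    for _ in range(n_intronic):
        host = genes[gene_cursor]
        gene_cursor += 1
        intron = host.introns()[0]
        strand = str(rng.choice(["+", "-"]))
        exons = [
            GenomicInterval(host.scaffold, intron.start + 100, intron.start + 350, strand),
            GenomicInterval(host.scaffold, intron.start + 600, intron.start + 900, strand),
        ]
        _add_lnc(exons, "intronic")
    for _ in range(n_anti):
        host = genes[gene_cursor]
        gene_cursor += 1
        strand = "-" if host.strand == "+" else "+"
        e1 = host.exons[0]
        exons = [
            GenomicInterval(host.scaffold, e1.start, e1.start + max(len(e1) - 1, 149), strand),
            GenomicInterval(host.scaffold, e1.end + max(len(e1), 300), e1.end + max(len(e1), 300) + 200, strand),
        ]
        _add_lnc(exons, "antisense")
    for _ in range(n_sense):
        host = genes[gene_cursor]
        gene_cursor += 1
        e1 = host.exons[0]
        exons = [
            GenomicInterval(host.scaffold, e1.start, e1.start + max(len(e1) - 1, 149), host.strand),
            GenomicInterval(host.scaffold, e1.end + max(len(e1), 300), e1.end + max(len(e1), 300) + 200, host.strand),
        ]
        _add_lnc(exons, "sense")
    for i in range(n_linc):
        n_ex = int(rng.integers(2, 5))
        exon_lens = [int(x) for x in rng.integers(150, 401, size=n_ex)]
        intron_lens = [int(x) for x in rng.integers(200, 801, size=n_ex - 1)]
        strand = "+" if i >= n_linc - config.triplet_spec else str(rng.choice(["+", "-"]))
        span = sum(exon_lens) + sum(intron_lens)
        scaffold, start = placer.place(span)
        _add_lnc(_make_exons(scaffold, strand, start, exon_lens, intron_lens), "lincRNA")

    # ---- mature miRNAs -----------------------------------------------------
    genome_str = {s: arr.tobytes().decode() for s, arr in genome.items()}
    for locus in mir_loci:
        pre_seq = locus.spliced_sequence(genome_str)
        truth.mature_sequences[locus.id] = pre_seq[10:32].replace("T", "U")

    # ---- scrub chance seed cores so planted sites are the only truth ------
    # Any accidental match to a simulated miRNA's 6mer seed core inside a
    # scanned target sequence (spliced lncRNA, mRNA 3'-UTR exon) is
    # degraded by one substitution; recovery of planted 8mer sites by the
    # seed scanner is then unambiguous. Scanning happens on the spliced,
    # transcript-sense sequence so junction-spanning matches are caught.
    cores = {revcomp(seq.replace("U", "T")[1:7]) for seq in truth.mature_sequences.values()}
    _SWAP = {b"A": b"C", b"C": b"A", b"G": b"T", b"T": b"G"}

    def _tx_index_to_genome(tx: TranscriptModel, k: int) -> tuple[str, int]:
        """0-based spliced-transcript index -> (scaffold, 0-based genome index)."""
        if tx.strand == "-":
            k = tx.length - 1 - k
        for e in tx.exons:
            if k < len(e):
                return e.scaffold, e.start - 1 + k
            k -= len(e)
        raise IndexError(k)

    scrub_targets: list[TranscriptModel] = list(lncs)
    for g in genes:
        utr_exon = g.exons[-1] if g.strand == "+" else g.exons[0]
        scrub_targets.append(TranscriptModel(
            id=f"{g.id}.utr3", gene_id=g.gene_id, scaffold=g.scaffold,
            strand=g.strand, exons=[utr_exon], biotype="coding",
        ))
    for _ in range(8):
        genome_str = {s: arr.tobytes().decode() for s, arr in genome.items()}
        hits: set[tuple[str, int]] = set()  # scaffold, 0-based genome index
        for tx in scrub_targets:
            seq = tx.spliced_sequence(genome_str)
            for core in cores:
                pos = seq.find(core)
                while pos != -1:
                    hits.add(_tx_index_to_genome(tx, pos + 3))
                    pos = seq.find(core, pos + 1)
        if not hits:
            break
        for sc, idx in hits:
            genome[sc][idx] = _SWAP[genome[sc][idx].item()]
    genome_str = {s: arr.tobytes().decode() for s, arr in genome.items()}

    # ---- planted ceRNA triplets: 8mer sites with full 3' pairing ----------
    plus_lincs = [t for t in lncs if t.strand == "+" and truth.lnc_classes[t.id] == "lincRNA"
                  and t.id not in {h for h, _, _ in truth.planted_hosts}]
    plus_genes = [g for g in genes if g.strand == "+"]
    k = config.triplet_spec
    if k > 0:
        if len(plus_lincs) < k or len(plus_genes) < k or len(mir_loci) < k:
            raise SimSizingError(
                "not enough plus-strand lincRNAs/genes or miRNA loci to plant "
                f"{k} triplets"
            )
        # a triplet miRNA is skipped when its planted site would embed the
        # seed core of another simulated miRNA (which would create a second,
        # unplanted target assignment at the same position)
        all_cores = {
            mid: revcomp(seq.replace("U", "T")[1:7])
            for mid, seq in truth.mature_sequences.items()
        }
        usable = []
        for locus in mir_loci:
            mat = truth.mature_sequences[locus.id].replace("U", "T")
            site = revcomp(mat[1:]) + "A"
            if not any(c in site for mid, c in all_cores.items() if mid != locus.id):
                usable.append(locus)
        if len(usable) < k:
            usable = mir_loci  # degenerate seed space; fall back
        for t in range(k):
            lnc, mir, gene = plus_lincs[-(t + 1)], usable[t], plus_genes[-(t + 1)]
            mature_dna = truth.mature_sequences[mir.id].replace("U", "T")
            # 8mer: reverse complement of positions 2..end, then A opposite
            # position 1; the revcomp of positions 9+ is the fully paired
            # 3' context immediately 5' of the seed match
            site = revcomp(mature_dna[1:]) + "A"
            for target in (lnc, gene):
                ex = target.exons[-1]
                pos = ex.start + 10  # 1-based genome coordinate
                genome[target.scaffold][pos - 1 : pos - 1 + len(site)] = np.frombuffer(
                    site.encode(), dtype="S1"
                )
            truth.planted_triplets.append((lnc.id, mir.id, gene.id))
        genome_str = {s: arr.tobytes().decode() for s, arr in genome.items()}

    # ---- planted differential expression ----------------------------------
    for ids in (truth.mrna_ids, truth.lncrna_ids, truth.mirna_ids):
        n_de = int(round(config.de_fraction * len(ids)))
        if n_de and config.de_log2fc != 0:
            chosen = rng.choice(np.array(ids), size=n_de, replace=False)
            signs = rng.choice([1.0, -1.0], size=n_de)
            for fid, s in zip(chosen, signs):
                direction = "testis" if s > 0 else "ovary"
                truth.de_features[str(fid)] = (direction, float(s * config.de_log2fc))
    for lnc_id, mir_id, mrna_id in truth.planted_triplets:
        d = str(rng.choice(["testis", "ovary"]))
        lfc = abs(config.de_log2fc) if config.de_log2fc else 4.0
        sign = 1.0 if d == "testis" else -1.0
        truth.de_features[lnc_id] = (d, sign * lfc)
        truth.de_features[mrna_id] = (d, sign * lfc)
        anti = "ovary" if d == "testis" else "testis"
        truth.de_features[mir_id] = (anti, -sign * lfc)

    sequences = {
        "genome": genome_str,
        "transcripts": {t.id: t.spliced_sequence(genome_str) for t in ann},
        "mature_mirna": dict(truth.mature_sequences),
        "utr3": {
            g.id: genome_str[g.scaffold][g.exons[-1].start - 1 : g.exons[-1].end]
            if g.strand == "+"
            else revcomp(genome_str[g.scaffold][g.exons[0].start - 1 : g.exons[0].end])
            for g in genes
        },
    }
    return ann, sequences, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

#: log-scale SD of the shared lognormal factor driving triplet co-expression.
#: Triplet members share both the factor and the planted sex-bias shift; on
#: the log scale the shift contributes ~(ln-ratio/2)^2 ~ 1.9 of shared
#: variance at |log2fc| = 4 against ~0.05-0.1 of independent NB noise, so
#: sigma = 0.25 puts the expected lncRNA-mRNA Pearson r near 0.97 (> 0.95)
#: while keeping the within-group variance small enough for the planted
#: fold change to stay detectable at 3 vs 3.
LATENT_FACTOR_SD = 0.25


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, variance = mean + alpha * mean^2) via gamma-Poisson mixture."""
    if alpha <= 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_counts(truth: SimTruth, config: SimConfig) -> dict[str, ExpressionMatrix]:
    """Draw ovary/testis NB count matrices for each RNA class.

    Planted DE features get group mean ratio 2^log2fc (testis over ovary,
    split symmetrically around the baseline); members of each planted
    triplet share a per-sample lognormal latent factor.
    """
    rng = np.random.default_rng((truth.seed + 1) % 2**31)
    n = config.n_samples_per_group
    samples = [f"ovary_{i + 1}" for i in range(n)] + [f"testis_{i + 1}" for i in range(n)]
    groups = pd.Series(["ovary"] * n + ["testis"] * n, index=samples)

    factors = {
        trip: np.exp(rng.normal(0.0, LATENT_FACTOR_SD, size=2 * n))
        for trip in truth.planted_triplets
    }
    member_factor: dict[str, np.ndarray] = {}
    for (lnc_id, _mir, mrna_id), f in factors.items():
        member_factor[lnc_id] = f
        member_factor[mrna_id] = f

    out: dict[str, ExpressionMatrix] = {}
    for cls, ids in (("mRNA", truth.mrna_ids), ("lncRNA", truth.lncrna_ids),
                     ("miRNA", truth.mirna_ids)):
        if not ids:
            out[cls] = ExpressionMatrix(
                values=pd.DataFrame(index=pd.Index([], name="feature"), columns=samples,
                                    dtype=float).fillna(0),
                groups=groups, value_kind="counts")
            continue
        base = rng.lognormal(mean=np.log(300.0), sigma=1.0, size=len(ids))
        means = np.tile(base[:, None], (1, 2 * n))
        for i, fid in enumerate(ids):
            if fid in truth.de_features:
                _, lfc = truth.de_features[fid]
                means[i, :n] *= 2.0 ** (-lfc / 2.0)   # ovary
                means[i, n:] *= 2.0 ** (lfc / 2.0)    # testis
            if fid in member_factor:
                means[i, :] *= member_factor[fid]
        counts = _nb_sample(rng, means, config.nb_dispersion)
        out[cls] = ExpressionMatrix(
            values=pd.DataFrame(counts, index=pd.Index(ids, name="feature"),
                                columns=samples, dtype=int),
            groups=groups, value_kind="counts",
        )
    return out


# ---------------------------------------------------------------------------
# coding-potential scores
# ---------------------------------------------------------------------------

def emit_coding_scores(truth: SimTruth, noise: float = 0.0,
                       seed: int | None = None) -> pd.DataFrame:
    """Emulate the upstream coding-potential scorers as a per-transcript table.

    True lncRNAs satisfy each of the six criteria (CPC < 0, CNCI < 0,
    CPAT < 0.85, ORF <= 100 aa, no BLASTX hit, no Pfam hit) independently
    with probability 1 - noise; coding transcripts the converse.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng((truth.seed + 2 if seed is None else seed) % 2**31)
    rows = []
    for tid in list(truth.mrna_ids) + list(truth.lncrna_ids):
        is_lnc = tid in truth.true_lncrnas
        # one flip decision per criterion; a flip hands the transcript the
        # other class's value for that criterion
        want = [is_lnc != (rng.random() < noise) for _ in range(N_SCORE_CRITERIA)]
        rows.append({
            "transcript_id": tid,
            "cpc_score": float(rng.uniform(-3.0, -0.1)) if want[0] else float(rng.uniform(0.1, 3.0)),
            "cnci_score": float(rng.uniform(-3.0, -0.1)) if want[1] else float(rng.uniform(0.1, 3.0)),
            "cpat_prob": float(rng.uniform(0.0, 0.84)) if want[2] else float(rng.uniform(0.86, 1.0)),
            "longest_orf_aa": int(rng.integers(10, 101)) if want[3] else int(rng.integers(101, 400)),
            "blastx_hit": not want[4],
            "pfam_hit": not want[5],
        })
    return pd.DataFrame(
        rows, columns=["transcript_id", "cpc_score", "cnci_score", "cpat_prob",
                       "longest_orf_aa", "blastx_hit", "pfam_hit"]
    ).set_index("transcript_id")
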