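"""Standard-format readers/writers, pipeline configuration, and the
end-to-end synthetic pipeline run.

GFF3 is the canonical annotation dialect: 1-based inclusive coordinates,
gene -> transcript -> exon hierarchy resolved in two passes (gffutils), so
child lines may precede their parents. All writers are deterministic:
fixed sort order, fixed float formats, so a fixed seed reproduces outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import cerna, lncrna, mirna, targeting
from .expression import DE_GATES, ExpressionMatrix, NBDifferential, tpm as tpm_fn
from .genomics import GenomeAnnotation, GenomicInterval, TranscriptModel
from .synthetic import SimConfig, SimTruth, emit_coding_scores, generate_annotation, simulate_counts

logger = logging.getLogger(__name__)

_BIOTYPE_TO_SO = {
    "coding": "mRNA",
    "lnc_candidate": "transcript",
    "lncRNA": "lnc_RNA",
    "pre_miRNA": "pre_miRNA",
}
_SO_TO_BIOTYPE = {v: k for k, v in _BIOTYPE_TO_SO.items()}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(ann: GenomeAnnotation) -> str:
    """Serialize an annotation as GFF3 text (deterministic ordering)."""
    lines = ["##gff-version 3"]
    for s in sorted(ann.scaffold_lengths):
        lines.append(f"##sequence-region {s} 1 {ann.scaffold_lengths[s]}")
    txs = sorted(ann.transcripts.values(), key=lambda t: (t.scaffold, t.start, t.id))
    genes_written: set[str] = set()
    for tx in txs:
        # gene IDs get their own namespace so a single-transcript gene
        # sharing its transcript's name stays unambiguous
        if tx.gene_id not in genes_written:
            genes_written.add(tx.gene_id)
            lines.append(
                f"{tx.scaffold}\tcernapipe\tgene\t{tx.start}\t{tx.end}\t.\t"
                f"{tx.strand}\t.\tID=gene-{tx.gene_id}"
            )
        so = _BIOTYPE_TO_SO[tx.biotype]
        lines.append(
            f"{tx.scaffold}\tcernapipe\t{so}\t{tx.start}\t{tx.end}\t.\t"
            f"{tx.strand}\t.\tID={tx.id};Parent=gene-{tx.gene_id};biotype={tx.biotype}"
        )
        for k, e in enumerate(tx.exons, 1):
            lines.append(
                f"{tx.scaffold}\tcernapipe\texon\t{e.start}\t{e.end}\t.\t"
                f"{tx.strand}\t.\tID={tx.id}.exon{k};Parent={tx.id}"
            )
    return "\n".join(lines) + "\n"


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 file into the internal annotation model.

    Parent/child links are resolved after a full pass, so exon lines may
    precede their transcript line. Malformed lines raise with their line
    number; an exon naming a missing parent raises too. Feature types
    other than the known transcript/exon types are preserved in the file
    but ignored by the model.
    """
    path = Path(path)
    text = path.read_text()
    for ln, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise ValueError(f"{path}:{ln}: malformed GFF3 line (need 9 columns)")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ann = GenomeAnnotation()
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            _, s, _start, end = line.split()
            ann.scaffold_lengths[s] = int(end)
    exons_by_parent: dict[str, list] = {}
    tx_rows: dict[str, gffutils.Feature] = {}
    for f in db.all_features():
        if f.featuretype == "exon":
            for parent in f.attributes.get("Parent", []):
                exons_by_parent.setdefault(parent, []).append(f)
        elif f.featuretype in _SO_TO_BIOTYPE:
            tx_rows[f.id] = f
    for parent in exons_by_parent:
        if parent not in tx_rows:
            raise ValueError(f"exon references missing parent {parent!r}")
    for tid, f in sorted(tx_rows.items()):
        exons = exons_by_parent.get(tid, [])
        if not exons:
            raise ValueError(f"transcript {tid} has no exons")
        biotype = f.attributes.get("biotype", [_SO_TO_BIOTYPE[f.featuretype]])[0]
        gene_id = f.attributes.get("Parent", [tid])[0]
        if gene_id.startswith("gene-"):
            gene_id = gene_id[5:]
        ann.add(
            TranscriptModel(
                id=tid,
                gene_id=gene_id,
                scaffold=f.seqid,
                strand=f.strand,
                exons=[
                    GenomicInterval(e.seqid, e.start, e.end, e.strand) for e in exons
                ],
                biotype=biotype,
            )
        )
    return ann


# ---------------------------------------------------------------------------
# FASTA / TSV / JSON
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_counts(counts_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    g = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values=values, groups=g, value_kind="counts")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    d = dataclasses.asdict(truth)
    d["true_lncrnas"] = sorted(d["true_lncrnas"])
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All thresholds of the pipeline; defaults are the study's values."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_length: int = 200
    min_exons: int = 2
    cpat_max: float = 0.85
    orf_max_aa: int = 100
    cis_window: int = 100_000
    trans_r: float = 0.95
    cerna_pcc: float = 0.9
    cerna_p: float = 0.05
    cluster_max_gap: int = 10_000
    score_gate: float = -10.0
    score_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed != self.sim.seed:
            self.sim = replace(self.sim, seed=self.seed)
        if not (self.cerna_pcc <= 1 and 0 <= self.cerna_p <= 1):
            raise ValueError("ceRNA thresholds out of range")
        if self.cluster_max_gap < 0 or self.cis_window < 0:
            raise ValueError("window thresholds must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "cluster_spec" in sim_raw:
            sim_raw["cluster_spec"] = [tuple(x) for x in sim_raw["cluster_spec"]]
        return cls(sim=SimConfig(**sim_raw), **raw)

    def thresholds(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("sim")
        d["de_gates"] = {k: list(v) for k, v in DE_GATES.items()}
        return d


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _recovery(recovered: set, truth: set) -> dict:
    tp = len(recovered & truth)
    recall = tp / len(truth) if truth else 1.0
    precision = tp / len(recovered) if recovered else 1.0
    return {
        "n_true": len(truth),
        "n_recovered": len(recovered),
        "recall": round(recall, 4),
        "precision": round(precision, 4),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on a freshly generated synthetic dataset.

    Order: simulate -> lncRNA filter/classify -> TPM + DE per class ->
    miRNA targets (seed + cis + trans) -> ceRNA triplets/network ->
    miRNA clusters/families/host relations. Returns the machine-readable
    summary; with ``outdir`` every stage artifact is written to disk.
    """
    logger.info("pipeline start (seed=%d)", config.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage: synthetic data -------------------------------------------
    ann, seqs, truth = generate_annotation(config.sim)
    matrices = simulate_counts(truth, config.sim)
    scores = emit_coding_scores(truth, config.score_noise)
    genes = ann.by_biotype("coding")
    mir_loci = ann.by_biotype("pre_miRNA")

    # ---- stage: lncRNA identification ------------------------------------
    candidates = [t for t in ann if t.biotype in ("coding", "lnc_candidate")]
    passed, reasons = lncrna.filter_lncrna_candidates(
        candidates, scores, min_length=config.min_length, min_exons=config.min_exons,
        cpat_max=config.cpat_max, orf_max_aa=config.orf_max_aa,
    )
    lncs = [ann.transcripts[i] for i in sorted(passed)]
    classes = lncrna.classify_all(lncs, genes)
    class_counts = classes["category"].value_counts().to_dict()

    # ---- stage: expression -----------------------------------------------
    lengths = {
        "mRNA": pd.Series({t.id: t.length for t in genes}),
        "lncRNA": pd.Series({i: ann.transcripts[i].length for i in truth.lncrna_ids}),
        "miRNA": pd.Series({i: 22 for i in truth.mirna_ids}),
    }
    de_results = {}
    tpms = {}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        mat = matrices[cls]
        tpms[cls] = tpm_fn(mat.values, lengths[cls].reindex(mat.values.index))
        de_results[cls] = NBDifferential(mat, cls).fit()
        logger.info("DE %s: %s", cls, de_results[cls].counts())
    de_sets = {cls: set(r.de_features) for cls, r in de_results.items()}
    de_lnc = de_sets["lncRNA"] & passed

    # ---- stage: targeting -------------------------------------------------
    lnc_seqs = {i: seqs["transcripts"][i] for i in sorted(passed)}
    utr3 = seqs["utr3"]
    sites = []
    for mid in sorted(de_sets["miRNA"]):
        mat_mirna = targeting.MatureMiRNA(mid, truth.mature_sequences[mid])
        sites.extend(targeting.predict_targets(mat_mirna, lnc_seqs, score_gate=config.score_gate))
        sites.extend(targeting.predict_targets(mat_mirna, utr3, score_gate=config.score_gate))
    site_table = targeting.sites_to_frame(sites)
    cis = {
        lid: targeting.cis_targets(ann.transcripts[lid], genes, config.cis_window)
        for lid in sorted(de_lnc)
    }
    trans = targeting.trans_targets(
        tpms["lncRNA"].loc[sorted(de_lnc)] if de_lnc else tpms["lncRNA"].iloc[:0],
        tpms["mRNA"], config.trans_r,
    )

    # ---- stage: ceRNA network ---------------------------------------------
    log_expr = pd.concat([np.log2(tpms["lncRNA"] + 1), np.log2(tpms["mRNA"] + 1)])
    triplets = cerna.build_triplets(
        de_sets["miRNA"], de_lnc, de_sets["mRNA"], site_table, log_expr,
        pcc_threshold=config.cerna_pcc, p_threshold=config.cerna_p,
    )

    # ---- stage: miRNA annotation ------------------------------------------
    clusters = mirna.detect_clusters(mir_loci, config.cluster_max_gap)
    n_clusters, n_clustered, pct_clustered = mirna.clustered_fraction(mir_loci, clusters)
    families = mirna.seed_family(truth.mature_sequences)
    host_rows = []
    for lnc in lncs:
        for locus in mir_loci:
            rel = mirna.classify_host_relation(lnc, locus)
            if rel != "none":
                host_rows.append({"lncrna": lnc.id, "mirna_locus": locus.id,
                                  "relation": rel})

    # ---- recovery vs planted truth ----------------------------------------
    true_de = {
        cls: {f for f in ids if f in truth.de_features}
        for cls, ids in (("mRNA", truth.mrna_ids), ("lncRNA", truth.lncrna_ids),
                         ("miRNA", truth.mirna_ids))
    }
    recovery = {
        "lncrna_filter": _recovery(passed, truth.true_lncrnas),
        "de": {cls: _recovery(de_sets[cls], true_de[cls]) for cls in de_sets},
        "clusters": _recovery(
            {frozenset(c.members) for c in clusters},
            {frozenset(c) for c in truth.planted_clusters},
        ),
        "triplets": _recovery(
            {(t.lncrna, t.mirna, t.mrna) for t in triplets},
            set(truth.planted_triplets),
        ),
    }

    pct = mirna.round_half_up
    n_per_class = {"mRNA": len(truth.mrna_ids), "lncRNA": len(truth.lncrna_ids),
                   "miRNA": len(truth.mirna_ids)}
    summary = {
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "lncrna": {
            "n_candidates": len(candidates),
            "n_pass": len(passed),
            "classes": {
                c: {"count": int(class_counts.get(c, 0)),
                    "percent": pct(100 * class_counts.get(c, 0) / max(len(passed), 1))}
                for c in ("lincRNA", "intronic", "antisense", "sense")
            },
        },
        "differential_expression": {
            cls: {
                "total": n_per_class[cls],
                "up": de_results[cls].counts()["testis_biased"],
                "down": de_results[cls].counts()["ovary_biased"],
                "up_percent": pct(100 * de_results[cls].counts()["testis_biased"] / max(n_per_class[cls], 1)),
                "down_percent": pct(100 * de_results[cls].counts()["ovary_biased"] / max(n_per_class[cls], 1)),
            }
            for cls in ("mRNA", "lncRNA", "miRNA")
        },
        "targeting": {
            "n_seed_sites": len(sites),
            "n_cis_pairs": sum(len(v) for v in cis.values()),
            "n_trans_pairs": int(len(trans)),
        },
        "cerna": {"n_triplets": len(triplets)},
        "mirna_clusters": {
            "n_loci": len(mir_loci),
            "n_clusters": n_clusters,
            "n_clustered": n_clustered,
            "percent_clustered": pct_clustered,
        },
        "host_relations": {"n": len(host_rows)},
        "recovery": recovery,
    }

    if out is not None:
        write_fasta(seqs["genome"], out / "genome.fa")
        write_fasta(seqs["transcripts"], out / "transcripts.fa")
        (out / "annotation.gff3").write_text(write_gff3(ann))
        write_truth(truth, out / "truth.json")
        scores.to_csv(out / "coding_scores.tsv", sep="\t")
        for cls, mat in matrices.items():
            write_counts(mat, out / f"counts_{cls}.tsv")
        mat0 = matrices["mRNA"]
        mat0.groups.rename("group").to_csv(out / "groups.tsv", sep="\t")
        pd.DataFrame(
            [{"transcript_id": t, "status": "pass" if t in passed else "fail",
              "reasons": ",".join(reasons.get(t, []))} for t in sorted(r.id for r in candidates)]
        ).to_csv(out / "lncrna_filter.tsv", sep="\t", index=False)
        classes.to_csv(out / "lncrna_classes.tsv", sep="\t")
        for cls, res in de_results.items():
            res.frame.to_csv(out / f"de_{cls}.tsv", sep="\t", float_format="%.6g")
        site_table.to_csv(out / "seed_sites.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"lncrna": l, "gene": g} for l in cis for g in cis[l]]
        ).to_csv(out / "cis_targets.tsv", sep="\t", index=False)
        trans.to_csv(out / "trans_targets.tsv", sep="\t", index=False, float_format="%.6g")
        de_dir = {
            f: ("testis-biased" if row == "testis-biased" else "ovary-biased")
            for cls, res in de_results.items()
            for f, row in res.frame["call"].items() if row != "ns"
        }
        cerna.export_network(triplets, out, de_direction=de_dir)
        pd.DataFrame(
            [{"cluster": c.id, "members": ",".join(c.members),
              "scaffold": c.span.scaffold, "start": c.span.start, "end": c.span.end}
             for c in clusters]
        ).to_csv(out / "mirna_clusters.tsv", sep="\t", index=False)
        families.to_csv(out / "mirna_families.tsv", sep="\t")
        pd.DataFrame(host_rows, columns=["lncrna", "mirna_locus", "relation"]).to_csv(
            out / "host_relations.tsv", sep="\t", index=False
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline done: %d triplets, %d clusters", len(triplets), n_clusters)
    return summary
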