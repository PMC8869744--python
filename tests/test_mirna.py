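"""Small-RNA read matching, cluster detection, seed families, PFM, hosts."""

import numpy as np
import pandas as pd
import pytest

from oracles import cluster_components_bruteforce, read_match_bruteforce

from cernapipe.genomics import GenomicInterval, TranscriptModel
from cernapipe.mirna import (
    classify_host_relation,
    clustered_fraction,
    clustered_percentage,
    detect_clusters,
    match_read_to_mirna,
    position_frequency_matrix,
    round_half_up,
    seed_family,
)

REFS = {
    "mir-a": "UGAGGUAGUAGGUUGUAUAGUU",
    "mir-b": "UCCCUGAGACCCUAACUUGUGA",
    "mir-c": "AACCCGUAGAUCCGAACUUGUG",
}


class TestReadMatching:
    def test_identical_read_assigned_with_zero_mismatches(self):
        a = match_read_to_mirna(REFS["mir-a"], REFS)
        assert a.reference_id == "mir-a" and a.mismatches == 0

    def test_two_internal_substitutions_rejected(self):
        read = list(REFS["mir-a"])
        read[5], read[10] = "C", "C"
        assert match_read_to_mirna("".join(read), {"mir-a": REFS["mir-a"]}) is None

    def test_read_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="18-28"):
            match_read_to_mirna("ACGUACGU", REFS)

    def test_matches_bruteforce_on_mutated_trimmed_reads(self):
        rng = np.random.default_rng(13)
        refs = {
            f"r{i}": "".join(rng.choice(list("ACGU"), size=22)) for i in range(8)
        }
        bases = list("ACGU")
        for _ in range(500):
            ref = refs[f"r{int(rng.integers(8))}"]
            read = list(ref)
            # random end trims/extensions and up to 2 internal substitutions
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(2, len(read) - 2))
                read[pos] = bases[int(rng.integers(4))]
            lo = int(rng.integers(0, 4))
            hi = len(read) - int(rng.integers(0, 4))
            read = "".join(read[lo:hi])
            if not 18 <= len(read) <= 28:
                continue
            got = match_read_to_mirna(read, refs)
            expect = read_match_bruteforce(read, refs)
            if expect is None:
                assert got is None
            else:
                assert (got.mismatches, -got.overlap, got.reference_id) == expect


def _locus(lid, scaffold, start, end, strand="+"):
    return TranscriptModel(
        id=lid, gene_id=lid, scaffold=scaffold, strand=strand,
        exons=[GenomicInterval(scaffold, start, end, strand)],
        biotype="pre_miRNA",
    )


class TestClusterDetection:
    def test_two_distant_loci_do_not_cluster(self):
        loci = [_locus("a", "s1", 1000, 1090), _locus("b", "s1", 16_090, 16_180)]
        assert detect_clusters(loci) == []

    def test_chaining_is_transitive(self):
        loci = [_locus("a", "s1", 1000, 1090),
                _locus("b", "s1", 3090, 3180),   # 2 kb gap
                _locus("c", "s1", 12_180, 12_270)]  # 9 kb gap
        [c] = detect_clusters(loci)
        assert c.members == ["a", "b", "c"]

    def test_matches_bruteforce_components_on_random_loci(self):
        rng = np.random.default_rng(99)
        loci = []
        for i in range(300):
            s = int(rng.integers(1, 400_000))
            loci.append(_locus(f"m{i}", f"s{int(rng.integers(5))}", s,
                               s + int(rng.integers(60, 120)),
                               str(rng.choice(["+", "-"]))))
        got = {frozenset(c.members) for c in detect_clusters(loci)}
        spans = [(l.scaffold, l.start, l.end) for l in loci]
        expect = {
            frozenset(loci[i].id for i in comp)
            for comp in cluster_components_bruteforce(spans, 10_000)
        }
        assert got == expect

    def test_invariant_to_input_order_and_strand(self):
        rng = np.random.default_rng(5)
        loci = []
        for i in range(50):
            s = int(rng.integers(1, 100_000))
            loci.append(_locus(f"m{i}", "s1", s, s + 90))
        a = {frozenset(c.members) for c in detect_clusters(loci)}
        shuffled = list(loci)[::-1]
        flipped = [
            TranscriptModel(id=l.id, gene_id=l.gene_id, scaffold=l.scaffold,
                            strand="-",
                            exons=[GenomicInterval(l.scaffold, l.start, l.end, "-")],
                            biotype="pre_miRNA")
            for l in shuffled
        ]
        assert {frozenset(c.members) for c in detect_clusters(flipped)} == a

    def test_planted_clusters_recovered_exactly(self, sim_dataset):
        ann, truth = sim_dataset["annotation"], sim_dataset["truth"]
        clusters = detect_clusters(ann.by_biotype("pre_miRNA"))
        assert {frozenset(c.members) for c in clusters} == {
            frozenset(c) for c in truth.planted_clusters
        }


class TestClusteredFraction:
    @pytest.mark.parametrize(
        "total,clustered,expected",
        [(824, 427, 51.8), (504, 299, 59.3), (765, 305, 39.9), (824, 0, 0.0)],
    )
    def test_percentages_match_printed_tables(self, total, clustered, expected):
        assert clustered_percentage(total, clustered) == expected

    def test_fraction_from_detected_clusters(self):
        loci = [_locus("a", "s1", 1000, 1090), _locus("b", "s1", 2000, 2090),
                _locus("c", "s1", 50_000, 50_090)]
        n_clusters, n_clustered, pct = clustered_fraction(loci, detect_clusters(loci))
        assert (n_clusters, n_clustered, pct) == (1, 2, 66.7)

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError):
            clustered_fraction([], [])

    def test_half_up_rounding(self):
        assert round_half_up(51.85, 1) == 51.9
        assert round_half_up(51.84, 1) == 51.8


class TestSeedFamily:
    def test_let7_seed_and_curated_name(self):
        fam = seed_family({"po-let-7": "UGAGGUAGUAGGUUGUAUAGUU"})
        assert fam.loc["po-let-7", "seed"] == "GAGGUAG"
        assert fam.loc["po-let-7", "family"] == "let-7"

    def test_position_one_difference_keeps_family(self):
        fam = seed_family({"a": "UGAGGUAGUAGGUUGUAUAGUU",
                           "b": "CGAGGUAGUAGGUUGUAUAGUU"})
        assert fam.loc["a", "family"] == fam.loc["b", "family"]

    def test_grouping_matches_substring_comparison(self):
        rng = np.random.default_rng(3)
        matures = {f"m{i}": "".join(rng.choice(list("ACGU"), size=22))
                   for i in range(50)}
        fam = seed_family(matures)
        for i in matures:
            for j in matures:
                same = matures[i][1:8] == matures[j][1:8]
                assert (fam.loc[i, "family"] == fam.loc[j, "family"]) == same

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            seed_family({"x": "ACGUA"})


class TestPositionFrequencyMatrix:
    def test_identical_sequences_give_unit_frequencies(self):
        pfm, consensus = position_frequency_matrix(["ACGU"] * 5)
        assert consensus == "ACGU"
        assert np.allclose(pfm.max(axis=1), 1.0)

    def test_even_tie_yields_iupac_code(self):
        pfm, consensus = position_frequency_matrix(["AGGG", "GGGG"])
        assert consensus[0] == "R"  # A/G ambiguity
        assert np.isclose(pfm.loc[1, "A"], 0.5)

    def test_simulated_let7_variants_keep_seed_consensus(self):
        rng = np.random.default_rng(10)
        seqs = []
        for _ in range(20):
            tail = "".join(rng.choice(list("ACGU"), size=14))
            seqs.append("U" + "GAGGUAG" + tail)
        _, consensus = position_frequency_matrix(seqs)
        assert consensus[1:8] == "GAGGUAG"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([])


class TestHostRelation:
    LNC = TranscriptModel(
        id="lnc", gene_id="lnc", scaffold="s1", strand="+",
        exons=[GenomicInterval("s1", 1000, 3000, "+"),
               GenomicInterval("s1", 5000, 6000, "+")],
        biotype="lncRNA",
    )

    def test_precursor_inside_exon_same_strand_is_host_exonic(self):
        assert classify_host_relation(self.LNC, _locus("m", "s1", 1200, 1290)) == "host_exonic"

    def test_precursor_in_intron_same_strand_is_host_intronic(self):
        assert classify_host_relation(self.LNC, _locus("m", "s1", 3500, 3590)) == "host_intronic"

    def test_opposite_strand_overlap_is_antisense(self):
        locus = _locus("m", "s1", 1200, 1290, strand="-")
        assert classify_host_relation(self.LNC, locus) == "antisense"

    def test_disjoint_locus_is_none(self):
        assert classify_host_relation(self.LNC, _locus("m", "s1", 9000, 9090)) == "none"

    def test_matches_bruteforce_on_random_placements(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            s = int(rng.integers(1, 8000))
            locus = _locus("m", "s1", s, s + 90, str(rng.choice(["+", "-"])))
            got = classify_host_relation(self.LNC, locus)
            # direct re-derivation from the definition
            pre = locus.span
            overlap = self.LNC.start <= pre.end and pre.start <= self.LNC.end
            if locus.strand != "+":
                expect = "antisense" if overlap else "none"
            elif any(e.start <= pre.start and pre.end <= e.end
                     for e in self.LNC.exons):
                expect = "host_exonic"
            elif self.LNC.start <= pre.start and pre.end <= self.LNC.end:
                expect = "host_intronic"
            else:
                expect = "none"
            assert got == expect

    def test_planted_host_relations_recovered(self, sim_dataset):
        ann, truth = sim_dataset["annotation"], sim_dataset["truth"]
        for lnc_id, locus_id, relation in truth.planted_hosts:
            got = classify_host_relation(
                ann.transcripts[lnc_id], ann.transcripts[locus_id]
            )
            assert got == relation
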