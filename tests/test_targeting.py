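"""Seed scanner, duplex score gate, cis window and trans correlation rules."""

import numpy as np
import pandas as pd
import pytest

from oracles import pearson_twopass, seed_scan_bruteforce

from cernapipe.genomics import GenomicInterval, TranscriptModel, revcomp
from cernapipe.targeting import (
    MatureMiRNA,
    cis_targets,
    context_percentile_filter,
    duplex_score,
    find_seed_matches,
    predict_targets,
    score_sites,
    trans_targets,
)

MIR = MatureMiRNA("mir-test", "UGAGGUAGUAGGUUGUAUAGUU")  # let-7 layout


class TestSeedScanner:
    def test_noncomplementary_target_yields_nothing(self):
        assert find_seed_matches(MIR, "A" * 200, "t") == []

    def test_constructed_8mer_site_detected(self):
        m = MIR.sequence.replace("U", "T")
        site = revcomp(m[1:8]) + "A"  # seed match 2-8 plus A opposite pos 1
        target = "C" * 30 + site + "C" * 30
        hits = find_seed_matches(MIR, target, "t")
        assert len(hits) == 1
        assert hits[0].site_type == "8mer"
        assert hits[0].start == 32  # core starts after the m8 base

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(21)
        mirnas = [
            MatureMiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), size=22)))
            for i in range(10)
        ]
        for rep in range(100):
            target = "".join(rng.choice(list("ACGT"), size=500))
            mir = mirnas[rep % 10]
            got = [(h.start, h.site_type) for h in find_seed_matches(mir, target, "t")]
            assert got == seed_scan_bruteforce(mir.sequence, target)

    def test_mirna_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            MatureMiRNA("short", "ACGUACGUACGU")


class TestDuplexScore:
    def test_bare_6mer_scores_minus_three_and_fails_gate(self):
        # all-A tail pairs nothing in a G context; G is neither comp(p8)
        # nor the A1 adenosine, so the hit stays a bare 6mer
        mir = MatureMiRNA("polyA", "UGAGGUAGAAAAAAAAAAAA")
        core = revcomp(mir.sequence.replace("U", "T")[1:7])
        target = "G" * 30 + core + "G" * 30
        [hit] = find_seed_matches(mir, target, "t")
        assert hit.site_type == "6mer"
        [scored] = score_sites(mir, target, [hit])
        assert scored.duplex_score == -3.0
        assert predict_targets(mir, {"t": target}) == []

    def test_hand_enumerated_windows(self):
        """Score decomposes as -(2 WC + GU) + site-type bonus on constructed
        windows where the best ungapped 3' pairing is known by hand."""
        # miRNA tail (positions 9+) all A: pairs only T (WC), never G:U
        mir = MatureMiRNA("polyA", "UGAGGUAGAAAAAAAAAAAA")
        m = mir.sequence.replace("U", "T")
        core = revcomp(m[1:7])
        for n_t in range(6):
            # context of n_t consecutive T's padded with C (no A pairing)
            context = ("C" * (10 - n_t)) + "T" * n_t
            window = context + core
            expected = -(2 * n_t) - 3.0  # 6mer bonus
            assert duplex_score(mir, window, "6mer") == expected
        # wobble: all-G tail pairs T only as G:U (A in context pairs nothing)
        mir_g = MatureMiRNA("polyG", "UGAGGUAGGGGGGGGGGGGG")
        window = "AAAAAATTTT" + revcomp(mir_g.sequence.replace("U", "T")[1:7])
        assert duplex_score(mir_g, window, "6mer") == -(1 * 4) - 3.0

    def test_site_type_bonus_ordering(self):
        # all-A tail never pairs a C/G window, so scores reduce to the bonus
        mir = MatureMiRNA("polyA", "UGAGGUAGAAAAAAAAAAAA")
        window = "C" * 10 + "GGGGGGG"
        scores = [duplex_score(mir, window, st)
                  for st in ("8mer", "7mer-m8", "7mer-A1", "6mer")]
        assert scores == [-8.0, -6.0, -5.0, -3.0]

    def test_window_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError):
            duplex_score(MIR, "ACG", "6mer")

    def test_planted_perfect_sites_always_pass_gate(self, sim_dataset):
        seqs, truth = sim_dataset["sequences"], sim_dataset["truth"]
        for lnc_id, mir_id, mrna_id in truth.planted_triplets:
            mir = MatureMiRNA(mir_id, truth.mature_sequences[mir_id])
            for target in (seqs["transcripts"][lnc_id], seqs["utr3"][mrna_id]):
                kept = predict_targets(mir, {"x": target})
                assert any(s.site_type == "8mer" and s.duplex_score < -10
                           for s in kept)

    def test_percentile_filter_keeps_better_half(self):
        m = MIR.sequence.replace("U", "T")
        strong = "C" * 10 + revcomp(m[1:8]) + "A"
        weak = "C" * 30 + revcomp(m[1:7]) + "C" * 10
        sites = score_sites(MIR, strong, find_seed_matches(MIR, strong, "a"))
        sites += score_sites(MIR, weak, find_seed_matches(MIR, weak, "b"))
        kept = context_percentile_filter(sites, 0.5)
        assert [s.target_id for s in kept] == ["a"]


def _gene(gid, scaffold, start, end, strand="+"):
    return TranscriptModel(
        id=gid, gene_id=gid, scaffold=scaffold, strand=strand,
        exons=[GenomicInterval(scaffold, start, end, strand)], biotype="coding",
    )


class TestCisTargets:
    LNC = TranscriptModel(
        id="lnc", gene_id="lnc", scaffold="s1", strand="+",
        exons=[GenomicInterval("s1", 500_000, 500_300, "+"),
               GenomicInterval("s1", 501_000, 501_500, "+")],
        biotype="lncRNA",
    )

    def test_gene_150kb_away_excluded(self):
        g = _gene("far", "s1", 651_501, 652_000)
        assert cis_targets(self.LNC, [g]) == []

    def test_boundary_exactly_100kb_included(self):
        g = _gene("edge", "s1", 601_500, 602_000)  # starts lnc_end + 100000
        assert cis_targets(self.LNC, [g]) == ["edge"]

    def test_own_host_gene_excluded(self):
        host = _gene("lnc", "s1", 499_000, 502_000)
        assert cis_targets(self.LNC, [host]) == []

    def test_matches_bruteforce_on_random_placements(self):
        rng = np.random.default_rng(33)
        for _ in range(500):
            ls = int(rng.integers(1, 2_000_000))
            lnc = TranscriptModel(
                id="l", gene_id="l", scaffold="s1", strand="+",
                exons=[GenomicInterval("s1", ls, ls + 1000, "+")],
                biotype="lncRNA",
            )
            gs = int(rng.integers(1, 2_000_000))
            g = _gene("g", rng.choice(["s1", "s2"]), gs, gs + int(rng.integers(100, 5000)))
            got = cis_targets(lnc, [g], 100_000)
            dist = max(0, max(lnc.start, g.start) - min(lnc.end, g.end))
            expected = ["g"] if (g.scaffold == "s1" and dist <= 100_000) else []
            assert got == expected

    def test_widening_window_never_removes_targets(self):
        genes = [_gene(f"g{i}", "s1", 1000 + 70_000 * i, 2000 + 70_000 * i)
                 for i in range(10)]
        narrow = set(cis_targets(self.LNC, genes, 50_000))
        wide = set(cis_targets(self.LNC, genes, 100_000))
        assert narrow <= wide


class TestTransTargets:
    def _mats(self, lnc_rows, mrna_rows):
        cols = [f"s{i}" for i in range(6)]
        return (pd.DataFrame(lnc_rows, columns=cols),
                pd.DataFrame(mrna_rows, columns=cols))

    def test_identical_profile_gives_r_one(self):
        prof = [[1, 5, 20, 80, 300, 1000]]
        l, m = self._mats(prof, prof)
        l.index, m.index = ["l0"], ["m0"]
        out = trans_targets(l, m, 0.95)
        assert list(out.itertuples(index=False))[0][:2] == ("l0", "m0")
        assert np.isclose(out["r"].iloc[0], 1.0)

    def test_anticorrelated_profile_included_by_absolute_rule(self):
        x = np.array([1.0, 5, 20, 80, 300, 1000])
        l, m = self._mats([x], [x[::-1]])
        l.index, m.index = ["l0"], ["m0"]
        out = trans_targets(l, m, 0.95)
        assert len(out) == 1 and out["r"].iloc[0] < -0.95

    def test_r_matches_two_pass_formula(self):
        rng = np.random.default_rng(6)
        l = pd.DataFrame(rng.uniform(0, 1000, size=(20, 6)),
                         index=[f"l{i}" for i in range(20)])
        m = pd.DataFrame(rng.uniform(0, 1000, size=(10, 6)),
                         index=[f"m{i}" for i in range(10)])
        m.columns = l.columns
        out = trans_targets(l, m, r_threshold=0.0)
        assert len(out) == 200
        for row in out.sample(25, random_state=0).itertuples(index=False):
            expect = pearson_twopass(
                np.log2(l.loc[row.lncrna].to_numpy() + 1),
                np.log2(m.loc[row.mrna].to_numpy() + 1),
            )
            assert np.isclose(row.r, expect)

    def test_zero_variance_feature_skipped(self):
        l = pd.DataFrame([[5.0] * 6], index=["flat"])
        m = pd.DataFrame([[1, 2, 3, 4, 5, 6.0]], index=["m0"])
        m.columns = l.columns
        assert trans_targets(l, m, 0.0).empty

    def test_threshold_one_returns_only_perfect_pairs(self):
        x = np.array([1.0, 2, 4, 8, 16, 32])
        l = pd.DataFrame([x, x * 2 + 1], index=["a", "b"])
        m = pd.DataFrame([x], index=["m0"])
        m.columns = l.columns
        assert trans_targets(l, m, r_threshold=1.0).empty
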