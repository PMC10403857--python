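"""k-mer extraction, consensus construction (with an independent oracle),
PWM similarity, and in-vitro table handling."""

import itertools

import numpy as np
import pytest

from clipnet.attribution import AttributionMap
from clipnet.genomic_io import one_hot_encode
from clipnet.motifs import (KmerRanking, KmerScore, MotifMatrix,
                            aggregate_relevance, build_consensus,
                            convert_7mer_to_5mer, extract_top_kmer,
                            kmer_pwm_similarity, read_motifs, rscores_to_z,
                            top_k_recall, write_meme_minimal)

_RNA = "ACGU"


def _map_for(sequence, pos_scores, track="target"):
    scores = np.zeros((len(sequence), 4))
    oh = one_hot_encode(sequence)
    for i, s in enumerate(pos_scores):
        scores[i] = s * oh[i]
    return AttributionMap(scores, track, 1.0, 0.0)


class TestExtractTopKmer:
    def test_unique_positive_window(self):
        rng = np.random.default_rng(0)
        seq = "".join(_RNA[i] for i in rng.integers(0, 4, 40))
        scores = np.zeros(40)
        scores[10:15] = 1.0
        ks = extract_top_kmer(_map_for(seq, scores), seq)
        assert ks.start == 10
        assert ks.kmer == seq[10:15]
        assert ks.ig_sum == pytest.approx(5.0)

    def test_tie_breaks_leftmost(self):
        seq = "ACGUACGUAC"
        ks = extract_top_kmer(_map_for(seq, np.ones(10)), seq)
        assert ks.start == 0

    def test_unknown_base_window_skipped(self):
        seq = "AANAAGGGGGGG"
        scores = np.zeros(12)
        scores[0:5] = 10.0   # best window but contains N
        scores[5:10] = 1.0
        ks = extract_top_kmer(_map_for(seq, scores), seq)
        assert "N" not in ks.kmer
        assert ks.start >= 3

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            L = int(rng.integers(8, 60))
            seq = "".join(_RNA[i] for i in rng.integers(0, 4, L))
            scores = rng.normal(size=L)
            ks = extract_top_kmer(_map_for(seq, scores), seq)
            best = max(
                ((sum(scores[s: s + 5]), -s) for s in range(L - 4)),
                key=lambda t: (round(t[0], 9), t[1]),
            )
            assert ks.ig_sum == pytest.approx(best[0])


class TestAggregateRelevance:
    def test_sum_over_occurrences_and_order_invariance(self):
        scores = [KmerScore("ACGUA", 1.0), KmerScore("UUUUU", 0.5),
                  KmerScore("ACGUA", 2.0)]
        r1 = aggregate_relevance(scores)
        r2 = aggregate_relevance(scores[::-1])
        assert r1.items == r2.items
        assert r1.items[0] == ("ACGUA", 3.0)


def _consensus_oracle(kmers, min_matches=3):
    """Independent re-derivation of the greedy alignment: explicit alignments
    as dicts column -> list of bases, scanning all offsets."""
    alignments = []  # list of list[(kmer, offset)]

    def majority(members, col):
        bases = [k[col - off] for k, off in members if off <= col < off + len(k)]
        if not bases:
            return None
        counts = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        for b in bases:          # first base reaching the max count
            if counts[b] == best:
                return b

    for kmer in kmers:
        placed = False
        for members in alignments:
            lo = min(off for _, off in members)
            hi = max(off + len(k) for k, off in members)
            candidates = []
            for off in range(lo - len(kmer) + min_matches,
                             hi - min_matches + 1):
                cols = [c for c in range(max(off, lo), min(off + len(kmer), hi))]
                m = sum(1 for c in cols if kmer[c - off] == majority(members, c))
                candidates.append((-m, abs(off), off))
            candidates.sort()
            if candidates and -candidates[0][0] >= min_matches:
                members.append((kmer, candidates[0][2]))
                placed = True
                break
        if not placed:
            alignments.append([(kmer, 0)])
    return [
        sorted((k for k, _ in members)) for members in alignments
    ]


class TestBuildConsensus:
    def test_worked_fixture(self):
        """ACUAA and CUAAC align at offset +1 (4 matches); GGGGG seeds its
        own motif: supports 2/3 and 1/3."""
        ranking = KmerRanking([("ACUAA", 3.0), ("CUAAC", 2.0), ("GGGGG", 1.0)])
        motifs = build_consensus(ranking)
        assert len(motifs) == 2
        assert motifs[0].support == 2
        assert motifs[0].support_fraction == pytest.approx(2 / 3)
        assert motifs[1].support_fraction == pytest.approx(1 / 3)
        assert dict(motifs[0].members)["CUAAC"] == 1  # offset +1
        assert motifs[0].matrix.consensus_string() == "ACUAAC"

    def test_identical_kmers_single_motif(self):
        ranking = KmerRanking([("ACGUA", float(5 - i)) for i in range(4)])
        motifs = build_consensus(ranking)
        assert len(motifs) == 1
        assert motifs[0].support_fraction == 1.0
        np.testing.assert_allclose(motifs[0].matrix.probs,
                                   one_hot_encode("ACGUA"))

    def test_unalignable_pair_seeds_two_motifs(self):
        motifs = build_consensus(KmerRanking([("AAAAA", 2.0), ("GGGGG", 1.0)]))
        assert [m.support for m in motifs] == [1, 1]

    def test_support_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        kmers = ["".join(_RNA[i] for i in rng.integers(0, 4, 5))
                 for _ in range(30)]
        ranking = KmerRanking([(k, float(30 - i)) for i, k in enumerate(kmers)])
        motifs = build_consensus(ranking)
        assert sum(m.support_fraction for m in motifs) == pytest.approx(1.0)
        assert sum(m.support for m in motifs) == len(kmers)

    def test_matches_independent_oracle_on_random_sets(self):
        rng = np.random.default_rng(99)
        for trial in range(50):
            n = int(rng.integers(2, 12))
            kmers = ["".join(_RNA[i] for i in rng.integers(0, 4, 5))
                     for _ in range(n)]
            scores = sorted(rng.normal(size=n), reverse=True)
            ranking = KmerRanking(list(zip(kmers, scores)))
            ordered = [k for k, _ in ranking]
            got = sorted(sorted(k for k, _ in m.members)
                         for m in build_consensus(ranking))
            expected = sorted(_consensus_oracle(ordered))
            assert got == expected, f"trial {trial}: {ordered}"


class TestKmerPwmSimilarity:
    def test_self_similarity_is_one(self):
        ref = MotifMatrix(one_hot_encode("ACUAA"))
        assert kmer_pwm_similarity("ACUAA", ref) == pytest.approx(1.0)

    def test_disjoint_point_masses_column(self):
        # full-overlap alignment of AAAAA vs CCCCC: every column JSD = 1
        ref = MotifMatrix(one_hot_encode("CCCCC"))
        sim = kmer_pwm_similarity("AAAAA", ref)
        # best offset is a 3-column overlap, still all-mismatch -> 0
        assert sim == pytest.approx(0.0, abs=1e-12)

    def test_sliding_finds_interior_match(self):
        ref = MotifMatrix(one_hot_encode("GACUAA"))
        assert kmer_pwm_similarity("ACUAA", ref) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ref = MotifMatrix(rng.dirichlet(np.ones(4), size=6))
            kmer = "".join(_RNA[i] for i in rng.integers(0, 4, 5))
            assert 0.0 <= kmer_pwm_similarity(kmer, ref) <= 1.0

    def test_short_references_skipped(self):
        with pytest.raises(ValueError):
            kmer_pwm_similarity("ACUAA", MotifMatrix(one_hot_encode("AC")))


class TestInVitroTables:
    def test_contained_twice_counts_twice(self):
        # UUUUU occurs twice in UUUUUUG; with one other 7-mer containing it
        # once, the mean must weight the double occurrence twice
        z7 = KmerRanking([("UUUUUUG", 3.0), ("AUUUUUA", 0.0)],
                         provenance="RNAcompete z")
        z5 = dict(convert_7mer_to_5mer(z7))
        assert z5["UUUUU"] == pytest.approx((3.0 + 3.0 + 0.0) / 3)

    def test_single_occurrence_inherits_score(self):
        z7 = KmerRanking([("ACGUACG", 1.5)])
        z5 = dict(convert_7mer_to_5mer(z7))
        assert z5["ACGUA"] == pytest.approx(1.5)

    def test_uniform_scores_stay_uniform(self):
        kmers = ["".join(p) for p in itertools.product("AC", repeat=7)]
        z5 = convert_7mer_to_5mer(KmerRanking([(k, 2.0) for k in kmers]))
        assert all(s == pytest.approx(2.0) for _, s in z5)

    def test_z_scores_population_sd(self):
        z = rscores_to_z({"A": 1.0, "B": 2.0, "C": 3.0})
        assert z["A"] == pytest.approx(-1.2247, abs=1e-4)
        assert z["B"] == pytest.approx(0.0, abs=1e-12)
        assert z["C"] == pytest.approx(1.2247, abs=1e-4)

    def test_z_scores_idempotent(self):
        vals = {"A": -1.0, "B": 0.0, "C": 1.0}
        scaled = {k: v / np.std([-1, 0, 1]) for k, v in vals.items()}
        z = rscores_to_z(scaled)
        for k in scaled:
            assert z[k] == pytest.approx(scaled[k], abs=1e-12)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            rscores_to_z({"A": 1.0, "B": 1.0})

    @pytest.mark.parametrize("overlap, expected", [(20, 1.0), (0, 0.0), (5, 0.25)])
    def test_top_k_recall(self, overlap, expected):
        base = ["".join(p) for p in itertools.product("ACGU", repeat=3)]
        a = KmerRanking([(k, 100.0 - i) for i, k in enumerate(base[:40])])
        b_items = base[:overlap] + base[40: 60 - overlap]
        b = KmerRanking([(k, 100.0 - i) for i, k in enumerate(b_items)])
        assert top_k_recall(a, b, k=20) == pytest.approx(expected)


class TestMotifIO:
    def test_meme_minimal_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        motifs = [MotifMatrix(rng.dirichlet(np.ones(4), size=6),
                              identifier=f"m{i}") for i in range(2)]
        path = tmp_path / "motifs.meme"
        write_meme_minimal(motifs, path, alphabet="ACGT")
        back = read_motifs(path, fmt="minimal")
        assert len(back) == 2
        # parser quantises probabilities to 1/nsites resolution
        np.testing.assert_allclose(back[0].probs, motifs[0].probs, atol=2e-3)
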