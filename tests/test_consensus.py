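"""Local alignment to L1 consensus sequences and TSS percent positioning."""

import numpy as np
import pytest

from l1asp.consensus import (
    Scoring,
    build_profile,
    local_align,
    map_tss_position,
    revcomp,
    tss_percent_position,
)
from l1asp.simulate import SimConfig, simulate
from oracles import sw_affine_score


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLocalAlign:
    def test_exact_substring_identity(self):
        rng = np.random.default_rng(0)
        cons = random_dna(rng, 400)
        q = cons[120:170]
        aln = local_align(q, cons)
        assert aln.score == 50 * 2
        assert (aln.consensus_start, aln.consensus_end) == (120, 170)
        assert aln.orientation == "forward"

    def test_reverse_complement_substring(self):
        rng = np.random.default_rng(1)
        cons = random_dna(rng, 400)
        q = revcomp(cons[200:260])
        aln = local_align(q, cons)
        assert aln.orientation == "reverse-complement"
        assert (aln.consensus_start, aln.consensus_end) == (200, 260)
        assert aln.score == 60 * 2

    def test_matches_dp_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(100):
            nq = int(rng.integers(20, 60))
            nc = int(rng.integers(40, 100))
            cons = random_dna(rng, nc)
            if trial % 2 == 0:
                # plant a (mutated) substring so high-scoring paths occur
                s = int(rng.integers(0, nc - 25))
                q = list(cons[s : s + 25])
                for k in range(len(q)):
                    if rng.random() < 0.1:
                        q[k] = "ACGT"[int(rng.integers(0, 4))]
                q = "".join(q)
            else:
                q = random_dna(rng, nq)
            expected = max(sw_affine_score(q, cons), sw_affine_score(revcomp(q), cons))
            assert local_align(q, cons).score == pytest.approx(expected)

    def test_score_invariant_under_double_revcomp(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            q, c = random_dna(rng, 40), random_dna(rng, 80)
            assert local_align(q, c).score == pytest.approx(
                local_align(revcomp(q), revcomp(c)).score
            )

    def test_no_similarity_gives_empty(self):
        aln = local_align("AAAA", "TTTT"[::-1].replace("T", "C"))  # vs "CCCC"
        assert aln.is_empty and aln.score == 0.0


class TestTssPercent:
    def test_position_zero(self):
        aln = local_align("ACGTACGTAC" * 3, ("ACGTACGTAC" * 3) + "G" * 30)
        assert tss_percent_position(aln, 6000) == 0.0

    def test_midpoint(self):
        rng = np.random.default_rng(4)
        cons = random_dna(rng, 6000)
        aln = local_align(cons[3000:3060], cons)
        assert tss_percent_position(aln, 6000) == pytest.approx(50.0)

    def test_empty_alignment_errors(self):
        from l1asp.consensus import LocalAlignment

        with pytest.raises(ValueError):
            tss_percent_position(LocalAlignment(), 6000)

    def test_reverse_complement_uses_consensus_end(self):
        rng = np.random.default_rng(5)
        cons = random_dna(rng, 1000)
        # transcript 5' end corresponds to consensus position 499
        q = revcomp(cons[400:500])
        aln = local_align(q, cons)
        assert tss_percent_position(aln, 1000) == pytest.approx(100 * 499 / 1000)


class TestPlantedRecovery:
    def test_recovery_without_mutation_within_1pct(self):
        d = simulate(SimConfig(seed=31, n_chimeras=12, n_exonization_decoys=0,
                               n_plain_ests=0, n_zero_orientation=0,
                               n_multi_alignment=0, mutation_rate=0.0))
        for c in d.truth.chimeras:
            p = map_tss_position(
                d.transcript_seqs[c.id],
                d.consensus_seqs[f"{c.subfamily_class}_consensus"],
            )
            assert p is not None
            assert abs(p - c.tss_consensus_pct) <= 1.0

    def test_recovery_at_10pct_mutation_within_3pct(self):
        d = simulate(SimConfig(seed=32, n_chimeras=12, n_exonization_decoys=0,
                               n_plain_ests=0, n_zero_orientation=0,
                               n_multi_alignment=0, mutation_rate=0.10))
        for c in d.truth.chimeras:
            p = map_tss_position(
                d.transcript_seqs[c.id],
                d.consensus_seqs[f"{c.subfamily_class}_consensus"],
            )
            assert p is not None
            assert abs(p - c.tss_consensus_pct) <= 3.0


class TestBuildProfile:
    def test_missing_consensus_errors(self):
        with pytest.raises(KeyError):
            build_profile([("t1", "L1HS", "ACGT" * 50)], {"L1PA2_8": "ACGT" * 200})

    def test_single_transcript_single_point(self):
        rng = np.random.default_rng(6)
        cons = random_dna(rng, 2000)
        seq = revcomp(cons[300:500])  # antisense transcript, 5' end at 499
        profiles = build_profile([("t1", "L1HS", seq)], {"L1HS": cons})
        assert profiles["L1HS"].n == 1
        assert profiles["L1HS"].positions[0] == pytest.approx(100 * 499 / 2000)

    def test_unmappable_counted_not_raised(self):
        rng = np.random.default_rng(7)
        cons = random_dna(rng, 2000)
        profiles = build_profile(
            [("junk", "L1HS", "AC" * 15)], {"L1HS": cons}, min_score=40.0
        )
        assert profiles["L1HS"].unmappable == ["junk"]
        assert profiles["L1HS"].n == 0

    def test_empty_class_empty_profile(self):
        profiles = build_profile([], {"L1HS": "ACGT" * 100})
        assert profiles["L1HS"].n == 0 and profiles["L1HS"].unmappable == []
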