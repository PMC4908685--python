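"""Coverage tracks, log2FC, LOESS smoothing, and TSS metaprofiles."""

import numpy as np
import pytest

from l1asp.signals import (
    ReadSet,
    SignalTrack,
    coverage_rpm,
    log2fc_track,
    loess_smooth,
    tss_metaprofile,
)


def rs(reads, library=1_000_000):
    return ReadSet(reads=reads, library_size=library)


class TestCoverage:
    def test_single_read(self):
        track = coverage_rpm(rs([("c", 0, 10, "+")]), 30, "c")
        assert np.all(track.values[:10] == 1.0)
        assert np.all(track.values[10:] == 0.0)

    def test_library_scaling(self):
        reads = [("c", 5, 25, "+"), ("c", 10, 30, "-")]
        a = coverage_rpm(rs(reads, 1_000_000), 40, "c")
        b = coverage_rpm(rs(reads, 2_000_000), 40, "c")
        assert np.allclose(a.values, 2 * b.values)

    def test_matches_per_base_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            length = 200
            reads = []
            for _ in range(int(rng.integers(1, 50))):
                s = int(rng.integers(0, length - 1))
                reads.append(("c", s, s + int(rng.integers(1, 40)), "+"))
            track = coverage_rpm(rs(reads), length, "c")
            oracle = np.zeros(length)
            for _, s, e, _ in reads:
                for i in range(s, min(e, length)):
                    oracle[i] += 1
            assert np.allclose(track.values, oracle * 1e6 / 1_000_000)

    def test_mass_conservation(self):
        rng = np.random.default_rng(1)
        length = 500
        reads = []
        for _ in range(100):
            s = int(rng.integers(0, length - 50))
            reads.append(("c", s, s + int(rng.integers(1, 50)), "+"))
        track = coverage_rpm(rs(reads), length, "c")
        total_len = sum(e - s for _, s, e, _ in reads)
        assert track.values.sum() == pytest.approx(total_len * 1e6 / 1_000_000)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            coverage_rpm(ReadSet([], 0), 10, "c")


class TestLog2FC:
    def test_identity_gives_zero(self):
        v = np.array([0.0, 1.0, 5.0, 2.5])
        t = SignalTrack("c", v)
        assert np.allclose(log2fc_track(t, t).values, 0.0)

    def test_doubling_gives_plus_one(self):
        inp = SignalTrack("c", np.full(10, 4.0))
        chip = SignalTrack("c", np.full(10, 8.0))
        out = log2fc_track(chip, inp, epsilon=1e-9)
        assert np.allclose(out.values, 1.0, atol=1e-6)

    def test_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(50) * 5, rng.random(50) * 5
        eps = 0.25
        out = log2fc_track(SignalTrack("c", a), SignalTrack("c", b), eps)
        assert np.allclose(out.values, np.log2((a + eps) / (b + eps)))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            log2fc_track(SignalTrack("c", np.zeros(5)), SignalTrack("c", np.zeros(6)))


class TestLoess:
    def test_constant_exact(self):
        t = SignalTrack("c", np.full(100, 3.7))
        assert np.allclose(loess_smooth(t, 0.1).values, 3.7, atol=1e-9)

    def test_linear_exact(self):
        x = np.arange(200, dtype=float)
        t = SignalTrack("c", 0.5 * x - 7.0)
        assert np.allclose(loess_smooth(t, 0.2).values, t.values, atol=1e-8)

    def test_noisy_sinusoid_recovered(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = np.arange(n)
        clean = np.sin(2 * np.pi * x / 500.0)
        noise_sd = 0.2
        noisy = clean + rng.normal(0, noise_sd, n)
        sm = loess_smooth(SignalTrack("c", noisy), 0.1).values
        interior = slice(100, 900)
        assert np.max(np.abs(sm[interior] - clean[interior])) < 2 * noise_sd

    def test_short_track_errors(self):
        with pytest.raises(ValueError):
            loess_smooth(SignalTrack("c", np.zeros(5)), 0.5)


class TestMetaprofile:
    lengths = {"c": 10_000}

    def test_single_read_lands_in_first_downstream_bin(self):
        tss = [("c", 5000, "+")]
        chip = rs([("c", 5050, 5080, "+")])
        prof = tss_metaprofile(tss, chip, None, self.lengths)
        assert prof.values.shape == (20,)
        nonzero = np.nonzero(prof.values)[0]
        assert list(nonzero) == [10]  # bin covering +0..+100

    def test_mirror_symmetry(self):
        # identical pileups mirror-imaged around a + and a - TSS
        plus_reads = [("c", 2000 + d, 2030 + d, "+") for d in range(0, 150, 10)]
        minus_reads = [("c", 7970 - d, 8000 - d, "-") for d in range(0, 150, 10)]
        p_plus = tss_metaprofile([("c", 2000, "+")], rs(plus_reads), None, self.lengths)
        p_minus = tss_metaprofile([("c", 8000, "-")], rs(minus_reads), None, self.lengths)
        assert np.allclose(p_plus.values, p_minus.values)

    def test_input_equal_chip_is_zero(self):
        reads = [("c", 4900 + 7 * k, 4930 + 7 * k, "+") for k in range(30)]
        prof = tss_metaprofile([("c", 5000, "+")], rs(reads), rs(reads), self.lengths)
        assert np.allclose(prof.values, 0.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        tss = [("c", int(p), "+") for p in rng.integers(1500, 8500, size=15)]
        reads = [
            ("c", int(s), int(s) + 30, "+") for s in rng.integers(0, 9900, size=300)
        ]
        a = tss_metaprofile(tss, rs(reads), None, self.lengths)
        b = tss_metaprofile(tss[::-1], rs(reads), None, self.lengths)
        assert np.allclose(a.values, b.values)

    def test_out_of_bounds_tss_dropped(self):
        prof = tss_metaprofile(
            [("c", 500, "+"), ("c", 5000, "+")], rs([("c", 5050, 5080, "+")]),
            None, self.lengths,
        )
        assert prof.n_tss == 1 and prof.n_dropped == 1

    def test_strand_match_filters_reads(self):
        tss = [("c", 5000, "+")]
        chip = rs([("c", 5050, 5080, "-")])  # opposite strand only
        prof = tss_metaprofile(tss, chip, None, self.lengths, strand_match=True)
        assert np.allclose(prof.values, 0.0)
        prof2 = tss_metaprofile(tss, chip, None, self.lengths, strand_match=False)
        assert prof2.values.sum() > 0

    def test_planted_promoter_pileup_downstream(self, sim_default):
        d = sim_default
        prof = tss_metaprofile(
            d.truth.tss_sites, d.chip_reads, d.input_reads, d.chrom_lengths
        )
        # pileups are planted 0-200 bp downstream: maxima in bins 10-11
        top2 = set(np.argsort(prof.values)[-2:])
        assert top2 == {10, 11}
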