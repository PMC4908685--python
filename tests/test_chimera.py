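"""The three-criterion chimera screen and its annotations."""

import numpy as np
import pytest

from l1asp.chimera import (
    SubfamilyClassMap,
    annotate_gene_overlap,
    classify_subfamily,
    is_exonization_support,
    screen,
    tally,
    validate_with_isoforms,
)
from l1asp.intervals import (
    GeneModel,
    GenomicInterval,
    RepeatElement,
    SplicedTranscript,
    resolve_txn_strand,
)
from l1asp.simulate import SimConfig, make_fixture, simulate


def run_fixture(name):
    fx = make_fixture(name)
    return fx, screen(fx["transcripts"], fx["repeats"], fx["genes"])


class TestFixtures:
    def test_exonization_decoy_removed(self):
        fx, res = run_fixture("exonization_decoy")
        assert res.accepted == []
        assert [c.transcript_id for c in res.removed_exonization] == ["CAND"]
        assert res.removed_exonization[0].excluded_by_exonization

    def test_boundary_tss_half_open(self):
        # TSS on the last base inside the L1 is accepted; one base past is not
        fx, res = run_fixture("boundary_tss")
        assert res.accepted_ids == {"IN"}

    def test_overlapping_l1_anchor_choice(self):
        fx, res = run_fixture("overlapping_l1")
        assert res.accepted_ids == {"OVL"}
        assert res.accepted[0].anchor.subfamily == fx["expect"]["anchor_subfamily"]

    def test_zero_orientation_dropped_with_count(self):
        fx, res = run_fixture("zero_orientation")
        assert res.accepted == []
        assert res.dropped_zero_orientation == 1


class TestSubfamilyClassification:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("L1HS", "L1HS"),
            ("L1PA1", "L1HS"),
            ("L1PA2", "L1PA2_8"),
            ("L1PA5", "L1PA2_8"),
            ("L1PA8", "L1PA2_8"),
            ("L1PA10", "ancient_primate"),
            ("L1PB1", "ancient_primate"),
            ("L1M5", "ancient_mammalian"),
            ("L1ME1", "ancient_mammalian"),
            ("HAL1", "ancient_mammalian"),
        ],
    )
    def test_default_map(self, name, expected):
        assert classify_subfamily(name) == expected

    def test_unknown_name_errors(self):
        with pytest.raises(KeyError, match="AluY"):
            classify_subfamily("AluY")

    def test_explicit_map_overrides_and_errors(self):
        cmap = SubfamilyClassMap({"L1Mus1": "L1HS"})
        assert classify_subfamily("L1Mus1", cmap) == "L1HS"
        with pytest.raises(KeyError):
            classify_subfamily("L1HS", cmap)


class TestGeneOverlapAnnotation:
    def make_gene(self, strand, exons):
        return GeneModel(
            gene_id="G",
            chrom="chr1",
            strand=strand,
            exons=tuple(GenomicInterval("chr1", a, b, strand) for a, b in exons),
        )

    def test_plus_gene_downstream_sense(self):
        gene = self.make_gene("+", [(1000, 1200), (6000, 6500)])
        ov = annotate_gene_overlap("+", 5000, gene, 120)
        assert (ov.relative_orientation, ov.tss_distance) == ("sense", 4000)

    def test_minus_gene_downstream_antisense(self):
        gene = self.make_gene("-", [(2000, 2500), (8800, 9001)])  # TSS at 9000
        ov = annotate_gene_overlap("+", 5000, gene, 80)
        assert (ov.relative_orientation, ov.tss_distance) == ("antisense", 4000)

    def test_coincident_tss_distance_zero(self):
        gene = self.make_gene("+", [(5000, 5200), (6000, 6500)])
        assert annotate_gene_overlap("+", 5000, gene, 10).tss_distance == 0


class TestExonizationSupport:
    l1 = RepeatElement("chr1", 1000, 2000, "-", "L1PA4", "L1")

    def make(self, blocks, orientation=1, align="+"):
        ivs = tuple(GenomicInterval("chr1", a, b, align) for a, b in blocks)
        t = SplicedTranscript(
            id="X",
            chrom="chr1",
            align_start=ivs[0].start,
            align_end=ivs[-1].end,
            align_strand=align,
            blocks=ivs,
            intron_orientation=orientation,
        )
        return resolve_txn_strand(t)

    def test_internal_l1_block_is_support(self):
        t = self.make([(500, 600), (1400, 1500), (2500, 2600)])
        assert is_exonization_support(t, self.l1)

    def test_five_prime_block_in_l1_is_not_support(self):
        # the transcript *starts* in the L1: ASP candidate, not exonization
        t = self.make([(1400, 1500), (2500, 2600)])
        assert not is_exonization_support(t, self.l1)

    def test_same_strand_is_not_support(self):
        t = self.make([(500, 600), (1400, 1500), (2500, 2600)], orientation=-1)
        assert t.txn_strand == "-" == self.l1.strand
        assert not is_exonization_support(t, self.l1)


class TestScreenProperties:
    def test_shuffle_invariance(self, sim_default):
        d = sim_default
        base = screen(d.transcripts, d.repeats, d.genes)
        rng = np.random.default_rng(7)
        ts = list(d.transcripts)
        rng.shuffle(ts)
        rp = list(d.repeats)
        rng.shuffle(rp)
        gn = list(d.genes)
        rng.shuffle(gn)
        shuffled = screen(ts, rp, gn)
        assert shuffled.accepted_ids == base.accepted_ids
        assert {c.transcript_id for c in shuffled.removed_exonization} == {
            c.transcript_id for c in base.removed_exonization
        }

    def test_accepted_and_removed_partition(self, sim_default):
        d = sim_default
        res = screen(d.transcripts, d.repeats, d.genes)
        acc = res.accepted_ids
        rem = {c.transcript_id for c in res.removed_exonization}
        assert acc & rem == set()
        # every call's TSS sits inside its anchor, antisense to it
        for call in res.accepted + res.removed_exonization:
            assert call.anchor.start <= call.tss < call.anchor.end
            assert call.anchor.strand != call.txn_strand

    def test_multi_alignment_flagged_not_removed(self, sim_default):
        d = sim_default
        res = screen(d.transcripts, d.repeats, d.genes)
        flagged = {c.transcript_id for c in res.accepted if c.multi_alignment}
        expected = {c.id for c in d.truth.chimeras if c.multi_alignment}
        assert flagged == expected and len(flagged) == d.config.n_multi_alignment


class TestTally:
    def test_counts_sum_and_per_gene(self, sim_default):
        d = sim_default
        res = screen(d.transcripts, d.repeats, d.genes)
        summary = tally(res.accepted)
        assert summary.n_accepted == len(res.accepted)
        assert sum(summary.subfamily_class_counts.values()) == summary.n_accepted
        assert summary.per_gene_est_counts == d.truth.per_gene_counts

    def test_per_gene_histogram_with_shared_genes(self):
        d = simulate(SimConfig(seed=21, n_chimeras=12, chimeras_per_gene=3,
                               n_exonization_decoys=0, n_plain_ests=5,
                               n_zero_orientation=0, n_multi_alignment=0))
        res = screen(d.transcripts, d.repeats, d.genes)
        summary = tally(res.accepted)
        assert summary.per_gene_est_counts == d.truth.per_gene_counts
        assert sorted(summary.per_gene_est_counts.values()) == [3, 3, 3, 3]

    def test_empty_input(self):
        summary = tally([])
        assert summary.n_accepted == 0
        assert summary.sense_overlaps == summary.antisense_overlaps == 0
        assert summary.per_gene_est_counts == {}


def test_isoform_validation_intersects_gene_sets(sim_default):
    from l1asp.chimera import ScreenResult

    d = sim_default
    res = screen(d.transcripts, d.repeats, d.genes)
    all_genes = {ov.gene_id for c in res.accepted for ov in c.gene_overlaps}
    assert validate_with_isoforms(res, res) == all_genes
    # a second cohort recovering only half the calls validates exactly
    # the genes of that half
    half = ScreenResult(res.accepted[::2], [], 0)
    expected = {ov.gene_id for c in half.accepted for ov in c.gene_overlaps}
    assert validate_with_isoforms(res, half) == expected
    assert validate_with_isoforms(res, ScreenResult([], [], 0)) == set()
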