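"""Map chimeric-transcript 5' ends onto L1 consensus sequences.

Young L1 subfamilies fire their antisense promoter inside the 5' UTR
(here planted at consensus position 400); ancient, 5'-truncated elements
fire near the 3' end.  The transcript 5' region is Smith-Waterman-aligned
to the class consensus and the TSS expressed as percent of its length.
"""

from l1asp.consensus import build_profile
from l1asp.simulate import SimConfig, simulate

young = simulate(SimConfig(seed=2, n_chimeras=20, n_exonization_decoys=0,
                           n_plain_ests=0, n_zero_orientation=0,
                           n_multi_alignment=0,
                           class_weights={"L1HS": 1.0},
                           fixed_tss_position={"L1HS": 400}))
records = [(c.id, c.subfamily_class, young.transcript_seqs[c.id])
           for c in young.truth.chimeras]
profiles = build_profile(records, {"L1HS": young.consensus_seqs["L1HS_consensus"]})
prof = profiles["L1HS"]
print(f"mapped transcripts: {prof.n}, unmappable: {len(prof.unmappable)}")
print(f"TSS positions (% of 6064-bp consensus): "
      f"min {min(prof.positions):.2f}, max {max(prof.positions):.2f}")
print(f"profile mode: {prof.mode_percent():.1f} %")
# All TSSs map to ~6.6 % of the consensus = position 400/6064, the planted
# antisense-promoter position within the 5' UTR.
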