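"""Scan a consensus sequence for transcription-factor binding sites.

Uses the synthetic cohort's YY1-like position weight matrix against the
young-element consensus at a 90 % relative-score threshold (both strands)
and prints sites in the 1-based inclusive dialect used in reports.
"""

from l1asp.motifs import PWM, report_sites, scan
from l1asp.simulate import SimConfig, simulate

data = simulate(SimConfig(seed=3))
pwm = PWM(data.pwm_id, data.pwm_counts)
hits = scan(data.consensus_seqs["L1HS_consensus"], pwm, threshold=0.9,
            sequence_id="L1HS_consensus")
print(report_sites(hits).to_string(index=False))
print("planted sites (0-based half-open):",
      [(s, e) for ref, s, e, _ in data.truth.motif_sites if ref == "L1HS_consensus"])
# The two planted sites are recovered at full relative score; a planted
# site at [447, 453) prints as 448..453 in 1-based inclusive coordinates.
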