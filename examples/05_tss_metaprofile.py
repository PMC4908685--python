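"""Build an input-subtracted read metaprofile around chimera TSSs.

Averages ChIP-style read depth (RPM) in 100-bp bins over +/-1000 bp around
every planted TSS, oriented so negative offsets are upstream of
transcription, and subtracts the input-control profile.
"""

import numpy as np

from l1asp.signals import tss_metaprofile
from l1asp.simulate import SimConfig, simulate

data = simulate(SimConfig(seed=4))
prof = tss_metaprofile(data.truth.tss_sites, data.chip_reads,
                       data.input_reads, data.chrom_lengths)
print(f"TSSs used: {prof.n_tss} (dropped: {prof.n_dropped})")
for center, value in zip(prof.bin_centers, prof.values):
    bar = "#" * int(max(0.0, value) * 5)
    print(f"{int(center):+6d} bp  {value:8.4f}  {bar}")
peak = prof.bin_centers[int(np.argmax(prof.values))]
print(f"peak bin center: {peak:+.0f} bp")
# The pileups are planted 0-200 bp downstream of each TSS, so the profile
# peaks in the first two downstream bins (+50/+150) and is ~0 elsewhere.
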