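"""Simulate dye tracks and raw reads for one labeled peptide.

The error model: each dye is missing from the start with probability
m=0.07 (dud), the whole peptide detaches with probability d=0.05 per
cycle, Edman degradation fails with probability e=0.06 per cycle, and
each surviving dye bleaches with probability p=0.05 per cycle. Intensities
are Gaussian around (count x mu) with variance sigma_bg^2 + count*sigma^2.
"""

import numpy as np

from fluoroseq.params import SequencingParams
from fluoroseq.proteome import DyeSeq
from fluoroseq.simulator import emit_raw_reads, simulate_dye_tracks

params = SequencingParams.create(2, num_timesteps=6)
dye_seq = DyeSeq.from_code(".00.1", 2)  # e.g. RKKAY with K->color0, Y->color1
rng = np.random.default_rng(1)

counts = simulate_dye_tracks(dye_seq, 3, params, rng)
reads = emit_raw_reads(counts, params, rng)

print(f"dye sequence {dye_seq.code!r}: starts with "
      f"{[int(n) for n in dye_seq.initial_counts]} dyes per color")
for i in range(3):
    print(f"molecule {i}: dye track (rows = timestep, cols = color)")
    print(counts[i])
print("raw read of molecule 0 (fluorescence intensities):")
np.set_printoptions(precision=3, suppress=True)
print(reads[0])
print("counts only ever decrease; the cycle at which each color steps down")
print("carries the position information the classifier uses.")
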