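"""Scan a sequence for estrogen response elements (EREs).

The ERE is a palindromic 15-mer, AGGTCAnnnTGACCT. A window is reported
when its exact PWM p-value is below 5e-4 AND it has at most 4 mismatches
to the consensus (the 3-bp spacer is free).
"""

import numpy as np

from eretarget import (
    GenomeSequence,
    Peak,
    ScorePValueTable,
    default_ere_motif,
    mismatch_count,
    scan_peaks,
)

rng = np.random.default_rng(0)
background = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=1000)])

# plant a perfect site at 300 and a one-transition-mismatch site at 700
perfect = "AGGTCACAGTGACCT"
one_off = "AGGTCACAGTGACCC"  # T -> C (transition) in the last position
seq = background[:300] + perfect + background[315:700] + one_off + background[715:]

genome = GenomeSequence({"chr1": seq})
peaks = [Peak("site1", "chr1", 250, 451), Peak("site2", "chr1", 650, 851)]

motif = default_ere_motif()
for hit in scan_peaks(genome, peaks, motif):
    print(f"{hit.peak_id}: [{hit.start}, {hit.end}) strand {hit.strand} "
          f"score {hit.pwm_score:.2f} bits, p = {hit.p_value:.2e}, "
          f"{hit.mismatches} mismatch(es)")

# the exact null distribution of the quantized score
table = ScorePValueTable(motif)
print(f"\nscore needed for p < 5e-4: "
      f"{table.score_threshold(5e-4) * table.resolution:.2f} bits")
print(f"mismatches in the one-off site: {mismatch_count(one_off)}")
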