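"""Frequency-matched "expected" read simulation.

Samples pseudo-reads from a reference genome so that their per-position
nucleotide frequencies match a pyrimidine-biased target (the signature of
damage windows), using closed-loop feedback acceptance. The emitted
profile should match the target to within a small mean absolute deviation
while every sequence remains an exact substring of the reference.
"""

import numpy as np

from nucshield import (
    FreqProfile,
    GenomeSpec,
    generate_genome,
    infer_freq_profile,
    profile_mad,
    simulate_reads,
)

genome = generate_genome(GenomeSpec({"chr1": 10_000_000}), seed=50)

L = 10
target = np.full((L, 4), 0.25)
for pos in (4, 5):  # positions 5-6: C+T = 0.95
    target[pos] = [0.025, 0.475, 0.025, 0.475]
profile = FreqProfile({L: target}, {L: 1.0})

for n in (1_000, 10_000, 50_000):
    sim = simulate_reads(genome, profile, n, seed=51)
    emitted = infer_freq_profile(sim).matrices[L]
    print(f"n={n:>6}: MAD(target, emitted) = {profile_mad(target, emitted):.4f}, "
          f"C+T at position 5 = {emitted[4, 1] + emitted[4, 3]:.3f}")
print("the deviation shrinks with n: the feedback loop converges on the target.")

row = sim.iloc[0]
print(f"example read {row.chrom}:{row.start}-{row.end}({row.strand}) seq={row.seq} "
      "(identical to the reference at those coordinates)")
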