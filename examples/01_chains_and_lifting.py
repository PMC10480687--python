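"""Build liftOver chains from repeat alignments and lift an interval.

Generates a tiny genome with 5 diverged copies of a 300 nt consensus,
compiles one chain per RepeatMasker-style alignment record, and lifts a
genomic interval from the third copy back onto consensus coordinates.
"""

import numpy as np

from replift import (
    ChainIndex,
    build_chains,
    lift_interval,
    make_repeat_genome,
    write_chain,
)

rng = np.random.default_rng(42)
consensus = {"L1toy": "".join("ACGT"[i] for i in rng.integers(0, 4, 300))}

fixture = make_repeat_genome(
    consensus, n_instances=5, sub_rate=0.1, indel_rate=0.02,
    minus_fraction=0.4, spacer_len=200, seed=1,
)
chains = build_chains(
    fixture.align_records, fixture.consensus_sizes(), fixture.chrom_sizes()
)
print("first chain header:")
print(write_chain(chains[:1]).splitlines()[0])

index = ChainIndex(chains)
inst = fixture.truth[2]
start = inst.g_start + 40
segments = lift_interval(index, inst.chrom, start, start + 36)
print(f"\ngenomic {inst.chrom}:{start}-{start + 36} (instance strand {inst.strand})")
for seg in segments:
    print(f"  lifts to {seg.q_name}:[{seg.q_start},{seg.q_end}) via a {seg.strand} chain")
print("(pieces shorter than 36 nt mean the read crossed an indel; those bases map nowhere)")
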