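"""Generate a small synthetic dataset: biased reads, spiked CNVs, truth BED.

The generator writes a reference FASTA with a GC gradient, embedded
dinucleotide runs and an N-gap, then samples paired reads whose rate follows
a fragment-GC bias curve, motif-specific suppression and the local copy
number.  Everything is deterministic given the seed.
"""

import pysam

from rdcnv import simulate

spec = simulate.default_fixture_spec(seed=7, chrom_length=500_000, n_del=3, n_dup=3)
paths = simulate.build_fixture(spec, "scratch/example_fixture")

print("files written:")
for k, v in paths.items():
    print(f"  {k}: {v}")

with pysam.AlignmentFile(paths["bam"]) as bam:
    n_reads = sum(1 for _ in bam.fetch(until_eof=True))
print(f"\n{n_reads} aligned reads over {sum(spec.chrom_lengths.values()):,} bases")
print(f"target coverage {spec.coverage}x, read length {spec.read_length}, "
      f"insert {spec.mean_insert}")
print("\nspiked events (the truth set the caller should recover):")
for e in spec.cnv_events:
    print(f"  {e.chrom}:{e.start}-{e.end}  {e.type}  copy number {e.copy_number}")
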