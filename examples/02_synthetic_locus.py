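"""Build the synthetic FibH-like locus and inspect its ground truth.

The generator embeds a ~16.8 kb two-exon gene in a 500 kb background
chromosome: a GC-rich repetitive core of ten 11-mer motifs arranged as
12 repetitive domains separated by 11 amorphous regions, with the two
Cas12a guide pairs planted in the flanks.
"""

from collections import Counter

from ceoseq import build_synthetic_locus, count_offtargets
from ceoseq.dna import gc_fraction

locus = build_synthetic_locus(seed=42)
spec = locus.spec

print(f"chromosome {locus.chrom}: {spec.genome_len:,} bp, "
      f"gene at {locus.gene.start:,}-{locus.gene.end:,} ({locus.gene.length:,} bp)")

core0, core1 = locus.core
core_gc = gc_fraction(locus.genome[locus.chrom][core0:core1])
kinds = Counter(k for k, _, _ in locus.domains)
print(f"repetitive core: {core1 - core0:,} bp, GC {core_gc:.3f}, "
      f"{kinds['R']} repetitive domains / {kinds['A']} amorphous regions")

counts = Counter(i.motif_name for i in locus.motif_instances)
print(f"{sum(counts.values())} motif instances planted:")
for m in spec.motif_mix:
    print(f"  {m.name:<9} {m.sequence}  x{counts[m.name]:<4} meth_prob {m.meth_prob}")

print(f"\n{len(locus.cg_sites)} CG sites inside the gene "
      f"({len(locus.meth_prob)} of them on motif instances)")

# off-target census of one planted guide against the whole synthetic
# genome: a well-placed guide is unique (0 0 0 0)
g = locus.guides[0]
census = count_offtargets(g, locus.genome)
print(f"\noff-target census of {g.name}: MM0-3 = {census.as_tuple()}")
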