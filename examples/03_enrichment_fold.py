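"""Simulate the enrichment protocol and quantify coverage.

Runs the four-step protocol (dephosphorylation, Cas12a cleavage,
adapter ligation, sequencing) on the synthetic locus, then computes
per-region mean depths and enrichment folds from the ground-truth
alignments, and compares the measured target fold with the
closed-form expectation of the sampling model.
"""

from ceoseq import (
    AlignmentRecord,
    ProtocolParams,
    build_synthetic_locus,
    expected_enrichment_fold,
    region_depth_table,
    simulate_locus,
)

locus = build_synthetic_locus(seed=42)
params = ProtocolParams()
sim = simulate_locus(locus, params, seed=43)
print(f"{len(sim.reads)} reads from {params.n_genome_copies} genome copies")

alignments = [
    AlignmentRecord(r.read_id, *r.truth, mean_q=r.mean_q) for r in sim.reads
]
table = region_depth_table(alignments, list(locus.regions), sim.chrom_lengths, min_q=7)
print("\nper-region coverage (Q >= 7 reads):")
print(table.to_string(index=False))

expected = expected_enrichment_fold(locus, params)
print(f"\nclosed-form expected target fold: {expected:.2f}")
# The target fold exceeds 1 because only Cas12a-cut ends ligate
# adapters efficiently; the short upstream/downstream regions sit
# between paired cut sites and are enriched even more strongly per
# base, exactly as in the real experiment.
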