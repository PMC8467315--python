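"""Published inputs for the Bombyx mori FibH enrichment experiment.

These constants are experimental inputs — the four crRNA target sites
flanking the fibroin heavy-chain gene (FibH, KWMTBOMO15365) on
Bomo_Chr25, and the ten CG-containing 11-mer repeat motifs of the FibH
repetitive core with their copy numbers. They are used both to check
the analysis arithmetic and as defaults for the synthetic-locus
generator, which emulates this gene.
"""

from __future__ import annotations

#: The four Cas12a guide sites flanking FibH, as (name, pam, protospacer,
#: chrom, start, end, efficiency_score). Coordinates are 1-based inclusive
#: and span PAM + protospacer; descending start/end denotes the reverse
#: strand. The two "up" guides sit on the high-coordinate (upstream) side
#: of the gene, the two "down" guides on the low-coordinate side.
FIBH_GUIDES = [
    ("FibH-up-1", "TTTA", "TGTTACCGGGGTCTAGTGAC", "Bomo_Chr25", 10_372_894, 10_372_871, 60),
    ("FibH-up-2", "TTTA", "AGCTTGTTGTACAAAACTGC", "Bomo_Chr25", 10_372_500, 10_372_477, 52),
    ("FibH-down-1", "TTTA", "TATGAACCTATTGTAATTTAG", "Bomo_Chr25", 10_354_516, 10_354_540, 59),
    ("FibH-down-2", "TTTG", "TACCCTCATACCTCAAAGAAC", "Bomo_Chr25", 10_353_778, 10_353_802, 42),
]

#: Reported per-guide cleavage efficiencies (gel densitometry): only
#: FibH-down-2 cut incompletely (~98%).
FIBH_CUT_EFFICIENCY = {
    "FibH-up-1": 1.00,
    "FibH-up-2": 1.00,
    "FibH-down-1": 1.00,
    "FibH-down-2": 0.98,
}

#: The ten CG-containing repeat motifs of the FibH core:
#: name -> (11-mer sequence, copy number, total methylation frequency).
#: The total methylation frequency is the sum over the motif's instances
#: of per-CG-site frequency (called_sites_methylated / called_sites).
FIBH_MOTIFS = {
    "motif-1": ("TGCTCCGTATC", 145, 2.121),
    "motif-2": ("AGCACCGGCAC", 92, 1.782),
    "motif-3": ("AGCTCCGCTTC", 65, 3.251),
    "motif-4": ("ATATCCGCCAT", 11, 0.267),
    "motif-5": ("TACTCCGTATC", 10, 0.222),
    "motif-6": ("TGAACCGGCAC", 9, 0.123),
    "motif-7": ("AGCTCCGGCAC", 8, 0.123),
    "motif-8": ("TGCTCCGTACC", 8, 0.166),
    "motif-9": ("AGAACCGGCAC", 3, 0.092),
    "motif-10": ("AGTTCCGCTTC", 3, 0.438),
}

#: Reported region depths on Bomo_Chr25 (label, start, end, average depth),
#: against a genome-wide mean depth of 38x.
FIBH_REGION_DEPTHS = [
    ("downstream sequence", 10_353_778, 10_354_516, 60.05),
    ("KWMTBOMO15365", 10_354_516, 10_372_477, 87.07),
    ("upstream sequence", 10_372_477, 10_372_871, 80.12),
]

FIBH_GENOME_MEAN_DEPTH = 38.0

#: FibH gene architecture used by the synthetic-locus generator:
#: exon 1 (57 bp), one intron (971 bp), exon 2 (15,810 bp) whose middle is
#: the repetitive core of 12 repetitive domains and 11 amorphous regions.
FIBH_EXON1_LEN = 57
FIBH_INTRON_LEN = 971
FIBH_EXON2_LEN = 15_810
FIBH_CORE_GC = 0.59
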