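# Methods

## The enrichment model

The package models Cas12a-based negative-selection enrichment ("CEO"):
genomic DNA is sheared during extraction, every pre-existing 5′ end is
dephosphorylated, Cas12a/crRNA complexes cut at four guide sites
flanking the locus of interest, fresh (phosphorylated) cut ends are
filled in and adapter-ligated, and each ligatable end seeds a nanopore
read running from the adapter into the fragment. Enrichment arises
because cut ends are concentrated at the locus while background ends
survive dephosphorylation only at a low rate.

### Guide model

Cas12a recognises a T-rich PAM 5′ of the protospacer. The default PAM
pattern is `TTTV` (configurable as any IUPAC string, since FnCpf1
tolerates TTN in some contexts). Protospacer length is per-guide
(published guides mix 20 and 21 nt); the site scanner takes it as a
parameter, default 21. Guide records carry 1-based inclusive
coordinates spanning PAM + protospacer, descending on the reverse
strand — the convention of published guide tables, in which a 20-nt
guide occupies a 24-bp site.

Off-target counting mirrors the CCTop/CHOPCHOP convention: the PAM
must match the pattern exactly, mismatches are Hamming distance within
the protospacer only, both strands are scanned, and the guide's own
locus is excluded (so a genome-unique guide has MM0 = 0). No bulges,
no degenerate-PAM relaxation by default.

### Region derivation

Two guide pairs flank the target. Each guide contributes one boundary
coordinate: the **lower** 1-based coordinate of its printed site. With
the four boundaries sorted ascending (b1..b4), the target is (b2, b3)
and each pair's own interval is the upstream/downstream region; the
three regions tile (b1, b4) and share boundary coordinates. Published
guide coordinates reproduce the published region table exactly under
this rule. The underlying data do not disambiguate whether the
reported boundary is the PAM-proximal base or the predicted cut site;
the lower-coordinate rule is therefore a documented convention chosen
for consistency with the published tables, not a mechanistic claim.

## The synthetic locus

`build_synthetic_locus` realises a FibH-like gene in a background
chromosome. Defaults (all in `LocusSpec`):

| parameter | default | rationale |
|---|---|---|
| gene architecture | exon 1 = 57 bp, intron = 971 bp, exon 2 = 15,810 bp | the two-exon FibH annotation |
| repetitive core | 12 R domains / 11 A regions, alternating | reported FibH architecture |
| motif mix | the ten published 11-mers, copies 145/92/65/11/10/9/8/8/3/3 | reported motif census |
| motif methylation probability | published total frequency / copies (0.0146 … 0.146) | emulates the reported per-motif signal |
| amorphous / core GC | 0.59 | reported core GC; amorphous filler is drawn at this GC |
| background chromosome | 500 kb at GC 0.38, gene at 200 kb | desk-scale window of the AT-rich host genome; ≥95 % of the window is off-target |
| background CG methylation | 0.02 | low-methylation insect genome background |
| guide layout | down pair forward at gene start −738/0; up pair reverse at gene end −1/+394 | mirrors the published guide geometry, so derived regions relate to the gene exactly as in the experiment |

Motif instances are shuffled and split evenly into the 12 domains;
amorphous regions (default 1,000 bp) and the unique exon-2 flanks are
random sequence rejected against containing any motif. After assembly
the builder re-censuses the whole genome and re-draws if any spurious
motif occurrence appeared, so the emitted truth is exact by
construction. Every published motif contains exactly one CG (at offset
5), so motif copies = motif CG sites.

Deliberate differences from the real gene: amorphous regions are
random GC-matched sequence (the real amorphous sequences are not
published) and are therefore CpG-rich — the synthetic gene has ~1,450
CG sites rather than the reported 506; the real core's non-CG repeat
units are not modelled, so the synthetic core is motif-sparse
(~26 % motif bases) relative to the real one. Neither affects the
quantities the package computes, which are all conditioned on the
emitted ground truth.

## The protocol simulator

Per genome copy (`ProtocolParams`, defaults in brackets):

1. **Fragmentation.** Shear points are an equilibrium renewal process
   with i.i.d. uniform 23–200 kb fragment lengths [reported extraction
   fragment range]. The stationary phase matters: the simulated
   chromosome is a *window* into a much larger genome, so boundary
   density must be uniform and the window's outer coordinates are
   continuations, not free DNA ends — they never ligate. (With a
   naive linear-molecule model the zero-cut control showed a spurious
   0.7–0.85× "depletion" from edge reads and shear-phase artifacts.)
2. **Dephosphorylation.** Each pre-existing end is ligatable with
   probability `(1 − dephos_efficiency) + dephos_efficiency ×
   background_end_rate` [0.95, 0.0]. The real experiment's residual
   38× background has no reported mechanism; both knobs are free
   parameters rather than a mechanistic claim.
3. **Cleavage.** Each guide site fires with its cut efficiency
   [1.00/1.00/1.00/0.98, the reported per-guide values]. A staggered
   cut at 18/23 nt beyond the PAM (canonical FnCpf1; configurable)
   leaves a 5-nt 5′ overhang; after fill-in both daughter fragments
   carry the overhang, so left daughters end at the distal cut and
   right daughters start at the proximal cut. Fresh ends are always
   ligatable.
4. **Sequencing.** Each ligatable end seeds a read with probability
   `reads_per_ligatable_end` [0.25]; read length is lognormal
   [median 6 kb, σ = 0.6, floor 200 bp] truncated at the fragment;
   per-read mean quality is a two-component normal mixture
   [90 % N(12, 1.5), 10 % N(5, 1)] so the Q ≥ 7 filter removes a
   realistic minority. Bases are emitted error-free — the analyses
   need coordinates, not basecall realism — and ground truth is a
   1:1 read↔alignment PAF. Per-read CpG calls are Bernoulli draws
   from the covering motif's probability (background 0.02 elsewhere),
   flipped with `meth_caller_error` [0.02].

400 genome copies give ~850 reads, ~6× genome / ~70× target depth —
deliberately desk-scale. The reported experiment's absolute numbers
(38× genome over 460 Mb, fold 2.29) are functions of genome size and
throughput and are not reproduced at a 500 kb window; the package
instead verifies the *arithmetic* on published inputs exactly and the
*model* by parameter recovery. All randomness flows from a single
`numpy` generator per stage, so identical seeds give byte-identical
outputs.

## Closed-form expected fold

For acceptance of the simulator, the expected target enrichment fold
is derived from the sampling model (`ceoseq.expectation`). A read from
an end deposits, at travel distances [a, b),

    ∫ₐᵇ S_L(u) · S_B(u) · C(u) du

bases, where S_L is read-length survival, S_B the survival of the
distance to the next shear boundary (a full fragment length from a
pre-existing boundary; the stationary residual-life distribution from
a cut), and C(u) the probability no intervening guide cut fired.
Summing over background ends (density 2/E[F] per bp, ligatable with
p_bg) and the eight directed cut ends gives expected genome depth
(total bases / G) and expected target depth (background + cut-read
overlap with the target / target length); the fold is their ratio.
Neglected effects, each ≲1 %: shear boundaries between adjacent cut
sites, cuts straddling a shear boundary, guide cuts truncating
background reads, and read-length floor interactions. Monte-Carlo
means over ≥6 replicates agree with the closed form within ~1 % at the
default and perturbed parameter settings.

## Quantification conventions

- "Average depth" is the mean per-base coverage over the region
  (half-open internal arithmetic); a median variant is available via
  the depth profile but the mean is the default because it reproduces
  the published table's arithmetic (87.07 / 38 = 2.29).
- A read counts toward a region if it overlaps it by ≥1 bp; the
  long-read tally threshold ("16,000 bp or more") is inclusive.
- The Q filter keeps reads with mean quality ≥ 7 (boundary kept).
- Folds and depths are rounded to two decimals in reports; raw floats
  are used internally.
- Genome mean depth is computed from the quality-filtered alignments
  by default (whether the published 38× was pre- or post-filter is
  not stated; both are available).

## Methylation conventions

- Per site: `frequency = called_sites_methylated / called_sites`;
  sites with zero calls are absent. One call per read per site;
  duplicates are an input error.
- Per motif: the reported statistic is the **sum** of site frequencies
  over the motif's instances (bounded by the copy number, not by 1).
  This is forced by the published table's internal consistency: a
  3-copy motif reports total 0.438 while one of its sites alone
  reports 0.206, impossible for a per-site mean constrained to single
  dominant sites but natural for a sum. A per-copy view
  (total / repetition) is provided alongside.
- A CG site belongs to a motif instance iff its start lies inside the
  instance's 11-bp span; overlapping claims are an error; call strand
  is collapsed (CpG symmetric).
- "Methylated site" defaults to frequency > 0, with a
  `min_frequency` override — the threshold behind published
  methylated-site tallies is not stated, so no such tally is asserted.

## Domain segmentation

The published architecture figure shows the result, not the
algorithm, so segmentation uses a transparent density-window rule:
windows of 200 bp with motif-coverage ≥ 0.5 are repetitive; unioned
windows closer than 50 bp merge; each repetitive block is clipped to
its first/last motif-covered base; interior gaps are amorphous and the
outer flanks are N-/C-terminal. All three knobs are config keys. On
generator output (dense ~320 bp domains, 1,000 bp motif-free spacers)
the rule recovers the planted 12 R + 11 A exactly; counts on real
sequence depend on the knobs and are validation-only.

## What the tests do and do not show

The suite verifies: published-input arithmetic exactly (GC%, region
boundaries, folds, motif CG structure); oracle equivalence of the
off-target census and all counting/depth primitives against brute
force; generator round-trips (census, architecture, GC); simulator
determinism and provenance invariants; fold agreement with the closed
form and monotonicity in cut/dephosphorylation efficiency; and
methylation parameter recovery within exact binomial 99 % CIs at
≥50× depth with an error-free caller. Passing these shows the
arithmetic and the sampling model are self-consistent and correctly
implemented; it does not show that real nanopore data (basecall
errors, mapping ambiguity in repeats, signal-level methylation
calling) would behave identically — those steps are consumed as
upstream outputs, not modelled.
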