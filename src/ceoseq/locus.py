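"""Synthetic FibH-like locus generation.

Builds a ground-truthed in-silico twin of the fibroin heavy-chain gene:
a ~16.8 kb two-exon gene (57 bp exon 1, one intron, 15.8 kb exon 2)
whose exon-2 middle is a GC-rich repetitive core of 11-mer motifs
arranged as 12 repetitive domains separated by 11 amorphous regions,
embedded mid-chromosome in a larger AT-rich background, with two
Cas12a guide pairs planted in the flanks exactly mirroring the
published guide geometry (down pair on the low-coordinate side, up
pair reverse-strand on the high-coordinate side).

Every annotation (motif instances, domains, CG sites, enrichment
regions, guides) is emitted as ground truth so downstream census,
coverage and methylation analyses can be validated by round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dna import gc_fraction, random_seq, revcomp
from .guides import EnrichmentRegions, GuideRecord, LabeledInterval, define_enrichment_regions
from .repeats import MotifInstance, count_motifs, find_cg_sites
from .tables import (
    FIBH_CORE_GC,
    FIBH_EXON1_LEN,
    FIBH_EXON2_LEN,
    FIBH_GUIDES,
    FIBH_INTRON_LEN,
    FIBH_MOTIFS,
)


@dataclass(frozen=True)
class MotifSpec:
    """A repeat motif to plant: 11-mer sequence, copy number, and the
    methylation probability assigned to its CG site."""

    name: str
    sequence: str
    copies: int
    meth_prob: float

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if not 0.0 <= self.meth_prob <= 1.0:
            raise ValueError("meth_prob must be in [0, 1]")


def default_motif_mix() -> list[MotifSpec]:
    """The ten published FibH motifs with their copy numbers; each
    motif's CG methylation probability defaults to its published mean
    per-instance frequency (total frequency / repetition)."""
    return [
        MotifSpec(name, seq, copies, round(total / copies, 4))
        for name, (seq, copies, total) in FIBH_MOTIFS.items()
    ]


@dataclass(frozen=True)
class LocusSpec:
    """Blueprint for the synthetic locus.

    Defaults realize the published FibH architecture: 12 repetitive
    domains / 11 amorphous regions, exon 1 of 57 bp, a 971 bp intron,
    a 15,810 bp exon 2, core GC ~0.59, guide-pair gaps of 738 bp
    (downstream) and 394 bp (upstream), all inside a 500 kb AT-rich
    background chromosome so >95% of the genome is off-target.
    """

    n_repetitive_domains: int = 12
    n_amorphous: int = 11
    motif_mix: tuple[MotifSpec, ...] = field(default_factory=lambda: tuple(default_motif_mix()))
    exon1_len: int = FIBH_EXON1_LEN
    intron_len: int = FIBH_INTRON_LEN
    exon2_len: int = FIBH_EXON2_LEN
    amorphous_len: int = 1000
    amorphous_gc: float = FIBH_CORE_GC
    background_gc: float = 0.38
    background_meth_prob: float = 0.02
    genome_len: int = 500_000
    chrom: str = "sim_chr25"
    gene_start: int = 200_000
    downstream_gap: int = 738
    upstream_gap: int = 394

    def __post_init__(self) -> None:
        if self.n_amorphous != self.n_repetitive_domains - 1:
            raise ValueError("n_amorphous must equal n_repetitive_domains - 1")
        if self.n_repetitive_domains < 1:
            raise ValueError("need at least one repetitive domain")

    @property
    def gene_len(self) -> int:
        return self.exon1_len + self.intron_len + self.exon2_len

    @property
    def motif_bases(self) -> int:
        return sum(len(m.sequence) * m.copies for m in self.motif_mix)

    @property
    def core_len(self) -> int:
        return self.motif_bases + self.n_amorphous * self.amorphous_len

    def validate_geometry(self) -> None:
        if self.core_len > self.exon2_len:
            raise ValueError(
                f"motif copies too large for the gene: core {self.core_len} bp "
                f"exceeds exon 2 ({self.exon2_len} bp)"
            )
        if self.gene_start < self.downstream_gap + 30:
            raise ValueError("gene_start leaves no room for the downstream guide pair")
        if self.gene_start + self.gene_len + self.upstream_gap + 30 > self.genome_len:
            raise ValueError("genome too short for the gene plus upstream guide pair")


@dataclass
class SyntheticLocus:
    """A realized locus: genome, planted guides, and full ground truth."""

    spec: LocusSpec
    genome: dict[str, str]
    gene: LabeledInterval                 # 1-based inclusive
    core: tuple[int, int]                 # 0-based half-open, genome coords
    guides: list[GuideRecord]
    regions: EnrichmentRegions
    motif_instances: list[MotifInstance]  # genome coords
    domains: list[tuple[str, int, int]]   # (kind R/A, start0, end0) genome coords
    cg_sites: list[int]                   # 0-based CG starts within the gene
    meth_prob: dict[int, float]           # genome CG position -> probability
    seed: int

    @property
    def chrom(self) -> str:
        return self.spec.chrom

    @property
    def gene_sequence(self) -> str:
        lo, hi = self.gene.interval0()
        return self.genome[self.chrom][lo:hi]

    def all_cg_sites(self) -> np.ndarray:
        """Sorted CG positions genome-wide (0-based)."""
        return np.array(find_cg_sites(self.genome[self.chrom]), dtype=np.int64)

    def cg_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions, methylation probabilities) for every genomic CG:
        the motif's probability inside a motif instance, the background
        probability elsewhere."""
        pos = self.all_cg_sites()
        probs = np.full(pos.size, self.spec.background_meth_prob)
        lookup = self.meth_prob
        for k, p in enumerate(pos.tolist()):
            if p in lookup:
                probs[k] = lookup[p]
        return pos, probs

    def write(self, outdir) -> dict[str, Path]:
        """Emit genome FASTA plus ground-truth BED annotations."""
        from .io import motif_instances_bed, regions_bed, write_bed, write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "motifs": outdir / "motif_instances.bed",
            "domains": outdir / "domains.bed",
            "cg_sites": outdir / "cg_sites.bed",
            "regions": outdir / "regions.bed",
            "gene": outdir / "gene.bed",
        }
        write_fasta(self.genome, paths["genome"])
        write_bed(motif_instances_bed(self.motif_instances), paths["motifs"])
        write_bed([(self.chrom, s, e, kind) for kind, s, e in self.domains], paths["domains"])
        write_bed([(self.chrom, p, p + 2, "CG") for p in self.cg_sites], paths["cg_sites"])
        write_bed(regions_bed(list(self.regions)), paths["regions"])
        lo, hi = self.gene.interval0()
        write_bed([(self.chrom, lo, hi, "gene")], paths["gene"])
        return paths


def _draw_nonmatching(length: int, rng: np.random.Generator, gc: float,
                      forbidden: list[str], tries: int = 50) -> str:
    """Random sequence containing none of the forbidden motifs."""
    for _ in range(tries):
        s = random_seq(length, rng, gc)
        if not any(m in s for m in forbidden):
            return s
    raise RuntimeError("could not draw a motif-free random segment")


def build_synthetic_locus(spec: LocusSpec | None = None, seed: int = 0) -> SyntheticLocus:
    """Realize a :class:`LocusSpec` into a ground-truthed genome.

    The planted guide sites reuse the published FibH guide sequences:
    the down pair forward-strand with the inner site starting at the
    gene's first base, the up pair reverse-strand with the inner site's
    low coordinate at the gene's last base — so the derived enrichment
    regions relate to the gene exactly as in the published experiment.
    Fails rather than emitting inconsistent truth: the motif census of
    the emitted genome must equal the spec (spurious chance occurrences
    trigger a re-draw of the random segments).
    """
    spec = spec or LocusSpec()
    spec.validate_geometry()
    motif_seqs = {m.name: m.sequence for m in spec.motif_mix}
    forbidden = list(motif_seqs.values())

    for attempt in range(20):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        # ---- exon-2 layout: lead | (R A)*11 R | tail -------------------
        instance_names = [m.name for m in spec.motif_mix for _ in range(m.copies)]
        rng.shuffle(instance_names)
        nd = spec.n_repetitive_domains
        bounds = np.linspace(0, len(instance_names), nd + 1).astype(int)
        domain_names = [instance_names[bounds[k]: bounds[k + 1]] for k in range(nd)]

        lead = (spec.exon2_len - spec.core_len) // 2
        tail = spec.exon2_len - spec.core_len - lead

        gene_parts: list[str] = []
        g0 = spec.gene_start
        gene_parts.append(_draw_nonmatching(spec.exon1_len, rng, spec.background_gc, forbidden))
        gene_parts.append(_draw_nonmatching(spec.intron_len, rng, spec.background_gc, forbidden))
        gene_parts.append(_draw_nonmatching(lead, rng, spec.amorphous_gc, forbidden))
        core_start = g0 + spec.exon1_len + spec.intron_len + lead

        domains: list[tuple[str, int, int]] = []
        instances: list[MotifInstance] = []
        cursor = core_start
        for k, names in enumerate(domain_names):
            if k > 0:
                gene_parts.append(
                    _draw_nonmatching(spec.amorphous_len, rng, spec.amorphous_gc, forbidden)
                )
                domains.append(("A", cursor, cursor + spec.amorphous_len))
                cursor += spec.amorphous_len
            dstart = cursor
            for name in names:
                seq = motif_seqs[name]
                instances.append(MotifInstance(name, spec.chrom, cursor, len(seq)))
                gene_parts.append(seq)
                cursor += len(seq)
            domains.append(("R", dstart, cursor))
        core_end = cursor
        gene_parts.append(_draw_nonmatching(tail, rng, spec.amorphous_gc, forbidden))

        gene_seq = "".join(gene_parts)
        assert len(gene_seq) == spec.gene_len

        # ---- background chromosome with the gene embedded --------------
        left = _draw_nonmatching(g0, rng, spec.background_gc, forbidden)
        right = _draw_nonmatching(
            spec.genome_len - g0 - spec.gene_len, rng, spec.background_gc, forbidden
        )
        chrom_seq = list(left + gene_seq + right)

        # ---- plant the two guide pairs ---------------------------------
        g1 = g0 + spec.gene_len  # 0-based exclusive gene end
        placements = []  # (name, pam, proto, eff, strand, lo0)
        for name, pam, proto, _chrom, _s, _e, eff in FIBH_GUIDES:
            site_len = len(pam) + len(proto)
            if "down-1" in name:
                lo = g0
            elif "down-2" in name:
                lo = g0 - spec.downstream_gap
            elif "up-2" in name:
                lo = g1 - 1
            else:  # up-1, outer upstream
                lo = g1 - 1 + spec.upstream_gap
            strand = "-" if name.startswith("FibH-up") else "+"
            placements.append((name, pam, proto, eff, strand, lo))

        guides: list[GuideRecord] = []
        for name, pam, proto, eff, strand, lo in placements:
            site = pam + proto
            genomic = site if strand == "+" else revcomp(site)
            chrom_seq[lo : lo + len(site)] = genomic
            start, end = (lo + 1, lo + len(site)) if strand == "+" else (lo + len(site), lo + 1)
            guides.append(
                GuideRecord(
                    name=name, pam=pam, protospacer=proto, strand=strand,
                    chrom=spec.chrom, start=start, end=end, efficiency_score=eff,
                )
            )

        genome = {spec.chrom: "".join(chrom_seq)}

        # ---- self-consistency: census must round-trip the spec ---------
        counts, found = count_motifs(genome[spec.chrom], motif_seqs, chrom=spec.chrom)
        expected = {m.name: m.copies for m in spec.motif_mix}
        if dict(counts) != expected:
            continue  # spurious occurrence in a random segment; re-draw

        gene = LabeledInterval("gene", spec.chrom, g0 + 1, g1)
        regions = define_enrichment_regions(
            up_pair=[g for g in guides if "up" in g.name],
            down_pair=[g for g in guides if "down" in g.name],
        )
        cg_sites = find_cg_sites(genome[spec.chrom][g0:g1], offset=g0)
        meth_prob = {}
        prob_by_name = {m.name: m.meth_prob for m in spec.motif_mix}
        for inst in found:
            for p in find_cg_sites(genome[spec.chrom][inst.start : inst.end], offset=inst.start):
                meth_prob[p] = prob_by_name[inst.motif_name]

        return SyntheticLocus(
            spec=spec, genome=genome, gene=gene, core=(core_start, core_end),
            guides=guides, regions=regions, motif_instances=found,
            domains=domains, cg_sites=cg_sites, meth_prob=meth_prob, seed=seed,
        )
    raise RuntimeError("failed to build a self-consistent locus in 20 attempts")
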