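"""Simulation of the four-step Cas12a enrichment protocol.

The protocol negatively selects background DNA: (1) genomic DNA is
fragmented (extraction shear) and its pre-existing 5' ends are
dephosphorylated so they cannot be adapter-ligated; (2) Cas12a/crRNA
complexes cut at the planted guide sites, leaving fresh phosphorylated
staggered ends; (3) after fill-in, adapters ligate to ligatable ends
only; (4) each ligatable end seeds a nanopore read proceeding from the
adapter into the fragment. Reads therefore pile up at the cut sites,
enriching the excised target, while residual background comes from
incompletely dephosphorylated (or re-phosphorylated) pre-existing ends.

Sequences are emitted error-free (coordinates, not basecall realism,
are the quantity of interest); per-read mean quality is drawn from a
two-component mixture so the Q >= 7 filter is exercisable, and per-read
CpG calls are Bernoulli draws from the site's assigned methylation
probability, optionally flipped by a caller-error channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .guides import GuideRecord
from .locus import SyntheticLocus
from .dna import revcomp


@dataclass(frozen=True)
class ProtocolParams:
    """Tunable protocol parameters.

    Cut efficiencies default to the published per-guide values (only
    the outer downstream guide cuts incompletely, ~98%). The staggered
    cut sits 18/23 nt beyond the PAM (canonical FnCpf1), giving a 5-nt
    5' overhang that fill-in duplicates on both daughter fragments.
    Fragment lengths emulate the published 23–200 kb extraction shear.
    """

    dephos_efficiency: float = 0.95
    background_end_rate: float = 0.0
    cut_efficiency: Mapping[str, float] | float = field(
        default_factory=lambda: {
            "FibH-up-1": 1.00, "FibH-up-2": 1.00,
            "FibH-down-1": 1.00, "FibH-down-2": 0.98,
        }
    )
    cut_offsets: tuple[int, int] = (18, 23)
    fragment_len_range: tuple[int, int] = (23_000, 200_000)
    n_genome_copies: int = 400
    reads_per_ligatable_end: float = 0.25
    read_len_median: float = 6_000.0
    read_len_sigma: float = 0.6
    read_len_min: int = 200
    q_high_mean: float = 12.0
    q_high_sd: float = 1.5
    q_low_mean: float = 5.0
    q_low_sd: float = 1.0
    q_low_weight: float = 0.10
    meth_caller_error: float = 0.02

    def __post_init__(self) -> None:
        for name in ("dephos_efficiency", "background_end_rate",
                     "reads_per_ligatable_end", "q_low_weight", "meth_caller_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.fragment_len_range
        if not 0 < lo <= hi:
            raise ValueError("fragment_len_range must be positive and ordered")
        if self.cut_offsets[0] > self.cut_offsets[1]:
            raise ValueError("cut_offsets must be (proximal, distal)")

    def efficiency_of(self, guide_name: str) -> float:
        if isinstance(self.cut_efficiency, Mapping):
            return self.cut_efficiency.get(guide_name, 1.0)
        return float(self.cut_efficiency)

    @property
    def ligatable_end_prob(self) -> float:
        """Probability a pre-existing end accepts an adapter: it escaped
        dephosphorylation, or a background event restored ligatability."""
        e = self.dephos_efficiency
        return (1.0 - e) + e * self.background_end_rate


@dataclass(frozen=True)
class ReadRecord:
    """One simulated nanopore read with its ground truth."""

    read_id: str
    sequence: str
    mean_q: float
    truth: tuple[str, int, int, str]           # chrom, start0, end0, strand
    cg_calls: tuple[tuple[int, int], ...]      # (genomic CG position, call 1/0)

    def __post_init__(self) -> None:
        chrom, start, end, strand = self.truth
        if end - start != len(self.sequence):
            raise ValueError(f"{self.read_id}: truth span != sequence length")
        for pos, _ in self.cg_calls:
            if not start <= pos < end:
                raise ValueError(f"{self.read_id}: CG call at {pos} outside truth interval")


@dataclass
class SimulationResult:
    reads: list[ReadRecord]
    chrom_lengths: dict[str, int]
    params: ProtocolParams
    seed: int

    def write(self, outdir) -> dict[str, Path]:
        from .io import write_calls_tsv, write_fastq, write_paf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": outdir / "reads.fastq",
            "paf": outdir / "truth.paf",
            "calls": outdir / "meth_calls.tsv",
        }
        write_fastq(self.reads, paths["fastq"])
        write_paf(self.reads, self.chrom_lengths, paths["paf"])
        write_calls_tsv(self.reads, paths["calls"])
        return paths


def guide_cut_coords(guide: GuideRecord, offsets: tuple[int, int]) -> tuple[int, int]:
    """(cut_lo, cut_hi) 0-based genome coordinates of the staggered cut.

    After fill-in the left daughter fragment ends at ``cut_hi`` and the
    right daughter starts at ``cut_lo``; the 5-nt overhang between them
    appears on both.
    """
    lo0, hi0 = guide.interval0()
    d1, d2 = offsets
    if guide.strand == "+":
        pam_end = lo0 + len(guide.pam)
        return pam_end + d1, pam_end + d2
    pam_start = hi0 - len(guide.pam)
    return pam_start - d2, pam_start - d1


def _fragment_bounds(genome_len: int, rng: np.random.Generator,
                     lo: int, hi: int) -> list[tuple[int, int]]:
    """Stationary-phase fragmentation of the genome window.

    The simulated chromosome stands in for a window of a much larger
    genome, so shear points follow an equilibrium renewal process: the
    first boundary is a stationary residual (uniform position within a
    length-biased fragment), making interior boundary density uniform
    with no phase artifact at the window edge.
    """
    lb = np.sqrt(lo * lo + rng.random() * (hi * hi - lo * lo))  # length-biased draw
    bounds = [0]
    x = rng.random() * lb
    while x < genome_len:
        if int(x) > bounds[-1]:
            bounds.append(int(x))
        x += rng.uniform(lo, hi)
    if bounds[-1] < genome_len:
        bounds.append(genome_len)
    return list(zip(bounds[:-1], bounds[1:]))


def simulate_protocol(
    genome: Mapping[str, str],
    guides: Sequence[GuideRecord],
    params: ProtocolParams,
    seed: int,
    cg_positions: np.ndarray | None = None,
    cg_probs: np.ndarray | None = None,
) -> SimulationResult:
    """Run the dephosphorylation / cleavage / ligation / sequencing model.

    ``cg_positions``/``cg_probs`` assign a methylation probability to
    each genomic CG (single-chromosome genomes); omit them for a
    methylation-free simulation. Identical inputs and seed give
    byte-identical outputs.
    """
    if len(genome) != 1:
        raise ValueError("the protocol simulator expects a single-chromosome genome")
    (chrom, seq), = genome.items()
    n = len(seq)
    rng = np.random.default_rng(seed)
    if cg_positions is None:
        cg_positions = np.empty(0, dtype=np.int64)
        cg_probs = np.empty(0)

    cuts = []
    for g in guides:
        if g.chrom != chrom:
            raise ValueError(f"guide {g.name} is not on {chrom}")
        cut_lo, cut_hi = guide_cut_coords(g, params.cut_offsets)
        if not 0 <= cut_lo < cut_hi <= n:
            raise ValueError(f"guide {g.name} cut site outside the genome")
        cuts.append((cut_lo, cut_hi, params.efficiency_of(g.name)))
    cuts.sort()

    p_lig = params.ligatable_end_prob
    r = params.reads_per_ligatable_end
    flo, fhi = params.fragment_len_range
    mu = np.log(params.read_len_median)

    reads: list[ReadRecord] = []
    for _copy in range(params.n_genome_copies):
        # the window's outer ends (0, n) are continuations of the larger
        # genome, not free DNA ends: never ligatable
        fragments = [
            [a, b,
             a != 0 and rng.random() < p_lig,
             b != n and rng.random() < p_lig]
            for a, b in _fragment_bounds(n, rng, flo, fhi)
        ]
        for cut_lo, cut_hi, eff in cuts:
            if rng.random() >= eff:
                continue
            for k, (a, b, la, lb) in enumerate(fragments):
                if a < cut_lo and cut_hi < b:
                    fragments[k] = [a, cut_hi, la, True]
                    fragments.insert(k + 1, [cut_lo, b, True, lb])
                    break
        for a, b, left_lig, right_lig in fragments:
            for from_left in (True, False):
                lig = left_lig if from_left else right_lig
                if not lig or rng.random() >= r:
                    continue
                length = int(rng.lognormal(mu, params.read_len_sigma))
                length = max(params.read_len_min, length)
                length = min(length, b - a)
                if from_left:
                    start, end, strand = a, a + length, "+"
                else:
                    start, end, strand = b - length, b, "-"
                if rng.random() < params.q_low_weight:
                    q = rng.normal(params.q_low_mean, params.q_low_sd)
                else:
                    q = rng.normal(params.q_high_mean, params.q_high_sd)
                q = float(max(q, 1.0))
                i0 = np.searchsorted(cg_positions, start)
                i1 = np.searchsorted(cg_positions, end - 1)
                pos = cg_positions[i0:i1]
                if pos.size:
                    methylated = rng.random(pos.size) < cg_probs[i0:i1]
                    flipped = rng.random(pos.size) < params.meth_caller_error
                    states = methylated ^ flipped
                    calls = tuple(zip(pos.tolist(), states.astype(int).tolist()))
                else:
                    calls = ()
                raw = seq[start:end]
                reads.append(
                    ReadRecord(
                        read_id=f"read_{len(reads):06d}",
                        sequence=raw if strand == "+" else revcomp(raw),
                        mean_q=round(q, 2),
                        truth=(chrom, start, end, strand),
                        cg_calls=calls,
                    )
                )
    return SimulationResult(reads=reads, chrom_lengths={chrom: n}, params=params, seed=seed)


def simulate_locus(
    locus: SyntheticLocus, params: ProtocolParams, seed: int
) -> SimulationResult:
    """Simulate the protocol on a synthetic locus, using its ground-truth
    per-CG methylation probabilities."""
    pos, probs = locus.cg_probabilities()
    return simulate_protocol(locus.genome, locus.guides, params, seed, pos, probs)
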