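"""Repeat-motif census and repetitive-domain segmentation.

The fibroin heavy-chain gene's core is built from short (11-mer) repeat
units organised as motif-dense "repetitive domains" separated by
low-motif "amorphous regions". This module enumerates exact motif
occurrences and CG dinucleotides, and segments a locus into alternating
repetitive (R) and amorphous (A) blocks with a sliding-window
motif-coverage density rule.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dna import validate_acgt

REPETITIVE = "R"
AMORPHOUS = "A"
N_TERMINAL = "N-terminal"
C_TERMINAL = "C-terminal"


@dataclass(frozen=True)
class MotifInstance:
    """One exact occurrence of a named motif (0-based start, + strand)."""

    motif_name: str
    chrom: str
    start: int
    length: int
    strand: str = "+"

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass(frozen=True)
class DomainSegment:
    """A segment of the locus: repetitive (R), amorphous (A), or a
    terminal flank. 0-based half-open coordinates."""

    kind: str
    start: int
    end: int
    motif_density: float

    @property
    def length(self) -> int:
        return self.end - self.start


def count_motifs(
    sequence: str,
    motifs: Mapping[str, str] | Sequence[tuple[str, str]],
    chrom: str = "locus",
    offset: int = 0,
) -> tuple[Counter, list[MotifInstance]]:
    """Exhaustively count exact occurrences of each motif in ``sequence``.

    Overlapping occurrences of the same motif are counted (a lookahead
    scan); the canonical 11-mer repeat motifs cannot self-overlap, so
    for them this equals non-overlapping counting. Returns per-motif
    counts and the instance list sorted by position. ``offset`` shifts
    reported coordinates (for sequences excised from a larger contig).
    """
    seq = sequence.upper()
    items = motifs.items() if isinstance(motifs, Mapping) else list(motifs)
    counts: Counter = Counter()
    instances: list[MotifInstance] = []
    for name, motif in items:
        m = validate_acgt(motif, f"motif {name}")
        counts[name] = 0
        for hit in re.finditer(f"(?={re.escape(m)})", seq):
            counts[name] += 1
            instances.append(MotifInstance(name, chrom, offset + hit.start(), len(m)))
    instances.sort(key=lambda i: (i.chrom, i.start, i.motif_name))
    return counts, instances


def find_cg_sites(sequence: str, offset: int = 0) -> list[int]:
    """0-based start positions of every CG dinucleotide (CGCG -> 0 and 2)."""
    seq = sequence.upper()
    return [offset + m.start() for m in re.finditer("(?=CG)", seq)]


def segment_domains(
    motif_instances: Iterable[MotifInstance],
    locus_len: int,
    window: int = 200,
    density_threshold: float = 0.5,
    merge_gap: int = 50,
) -> list[DomainSegment]:
    """Segment a locus into alternating repetitive/amorphous blocks.

    A position window of ``window`` bp whose motif-coverage density is
    >= ``density_threshold`` marks a repetitive stretch; qualifying
    windows are unioned, stretches closer than ``merge_gap`` are merged,
    and each repetitive block is clipped to its first/last motif-covered
    base. The flank before the first (after the last) repetitive block
    is labeled N-terminal (C-terminal); interior gaps are amorphous.
    Segments tile [0, locus_len) and R/A alternate.
    """
    if locus_len <= 0:
        raise ValueError("locus_len must be positive")
    inst = sorted(motif_instances, key=lambda i: i.start)
    cov = np.zeros(locus_len, dtype=bool)
    for i in inst:
        if i.start < 0 or i.end > locus_len:
            raise ValueError(f"motif instance {i} outside locus of length {locus_len}")
        cov[i.start : i.end] = True
    if not inst:
        return [DomainSegment("non-repetitive", 0, locus_len, 0.0)]

    w = min(window, locus_len)
    csum = np.concatenate([[0], np.cumsum(cov)])
    dens = (csum[w:] - csum[:-w]) / w  # density of window starting at i
    ok = dens >= density_threshold

    # union of qualifying windows -> candidate repetitive spans
    spans: list[list[int]] = []
    in_run = False
    for i, flag in enumerate(ok):
        if flag and not in_run:
            spans.append([i, i + w])
            in_run = True
        elif flag:
            spans[-1][1] = i + w
        else:
            in_run = False
    if not spans:
        # motifs too sparse for any window: single non-repetitive segment
        return [DomainSegment("non-repetitive", 0, locus_len, float(cov.mean()))]

    merged = [spans[0]]
    for s, e in spans[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # clip each repetitive span to actual motif coverage
    covered = np.nonzero(cov)[0]
    clipped: list[tuple[int, int]] = []
    for s, e in merged:
        inside = covered[(covered >= s) & (covered < e)]
        if inside.size:
            clipped.append((int(inside[0]), int(inside[-1]) + 1))
    segments: list[DomainSegment] = []

    def density(a: int, b: int) -> float:
        return float((csum[b] - csum[a]) / (b - a)) if b > a else 0.0

    first, last = clipped[0][0], clipped[-1][1]
    if first > 0:
        segments.append(DomainSegment(N_TERMINAL, 0, first, density(0, first)))
    for k, (s, e) in enumerate(clipped):
        if k > 0:
            prev_end = clipped[k - 1][1]
            segments.append(DomainSegment(AMORPHOUS, prev_end, s, density(prev_end, s)))
        segments.append(DomainSegment(REPETITIVE, s, e, density(s, e)))
    if last < locus_len:
        segments.append(DomainSegment(C_TERMINAL, last, locus_len, density(last, locus_len)))
    return segments
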