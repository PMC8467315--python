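"""Cas12a (Cpf1) guide characterisation and enrichment-region derivation.

Cas12a recognises a T-rich PAM (default ``TTTV``) 5' of a 20–21 nt
protospacer and cleaves distally, leaving staggered ends. This module
finds candidate target sites in a genome, recomputes guide metrics
(GC%), counts mismatch-bounded potential off-targets (the MM0–MM3
census, PAM-anchored Hamming matching in the CCTop/CHOPCHOP style), and
derives the three enrichment regions (downstream / target / upstream)
implied by two flanking guide pairs.

Coordinate conventions
----------------------
Internally everything is 0-based half-open. User-facing records carry
1-based inclusive coordinates spanning PAM + protospacer, with
descending start/end for reverse-strand sites — the convention used in
published guide tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dna import encode, gc_fraction, iupac_to_regex, matches_iupac, revcomp, validate_acgt

log = logging.getLogger(__name__)

DEFAULT_PAM = "TTTV"
DEFAULT_SPACER_LEN = 21


def gc_percent(protospacer: str) -> int:
    """G+C content of a protospacer as an integer percent.

    The PAM is never included: callers pass the protospacer only.
    Rounded half-up agrees with round-half-even here for all published
    guide lengths; plain ``round`` is used.
    """
    return round(gc_fraction(validate_acgt(protospacer, "protospacer")) * 100)


def at_percent(protospacer: str) -> int:
    """A+T content as an integer percent (complement of :func:`gc_percent`)."""
    return 100 - gc_percent(protospacer)


@dataclass(frozen=True)
class OffTargetCensus:
    """Counts of genomic sites matching a guide with exactly 0–3 protospacer
    mismatches (PAM must match the PAM pattern exactly; the guide's own
    locus is excluded from mm0)."""

    mm0: int = 0
    mm1: int = 0
    mm2: int = 0
    mm3: int = 0

    def __post_init__(self) -> None:
        for k in ("mm0", "mm1", "mm2", "mm3"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.mm0, self.mm1, self.mm2, self.mm3)


@dataclass(frozen=True)
class GuideRecord:
    """A Cas12a crRNA target site.

    ``start``/``end`` are 1-based inclusive genomic coordinates of the
    full site (PAM + protospacer); ``start > end`` on the reverse
    strand. ``efficiency_score`` is opaque metadata from an external
    predictor; it is stored, never computed here.
    """

    name: str
    pam: str
    protospacer: str
    strand: str
    chrom: str
    start: int
    end: int
    gc_percent: int = -1
    efficiency_score: int | None = None
    offtargets: OffTargetCensus | None = None
    pam_pattern: str = DEFAULT_PAM

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        validate_acgt(self.protospacer, "protospacer")
        if not matches_iupac(self.pam, self.pam_pattern):
            raise ValueError(f"PAM {self.pam!r} does not match pattern {self.pam_pattern!r}")
        site_len = abs(self.end - self.start) + 1
        if site_len != self.size + len(self.pam):
            raise ValueError(
                f"{self.name}: site span {site_len} != PAM ({len(self.pam)}) "
                f"+ protospacer ({self.size})"
            )
        if (self.strand == "-") != (self.start > self.end):
            raise ValueError(f"{self.name}: descending coordinates must pair with '-' strand")
        if self.gc_percent == -1:
            object.__setattr__(self, "gc_percent", gc_percent(self.protospacer))
        if not 0 <= self.gc_percent <= 100:
            raise ValueError("gc_percent out of [0, 100]")

    @property
    def size(self) -> int:
        """Protospacer length in bp."""
        return len(self.protospacer)

    @property
    def boundary(self) -> int:
        """The site's lower 1-based genomic coordinate; the coordinate a
        guide contributes when deriving enrichment regions."""
        return min(self.start, self.end)

    def interval0(self) -> tuple[int, int]:
        """0-based half-open genomic interval of the full site."""
        lo = min(self.start, self.end) - 1
        return lo, lo + self.size + len(self.pam)

    @property
    def site_sequence(self) -> str:
        """PAM + protospacer in guide orientation."""
        return self.pam + self.protospacer


@dataclass(frozen=True)
class LabeledInterval:
    """A labeled 1-based inclusive genomic interval."""

    label: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interval0(self) -> tuple[int, int]:
        return self.start - 1, self.end


@dataclass(frozen=True)
class EnrichmentRegions:
    """The three regions a two-pair guide layout delimits: the excised
    target, plus the upstream and downstream guide-pair intervals."""

    target: LabeledInterval
    upstream: LabeledInterval
    downstream: LabeledInterval

    def __iter__(self):
        return iter((self.downstream, self.target, self.upstream))


def scan_pams(
    genome: Mapping[str, str],
    pam_pattern: str = DEFAULT_PAM,
    spacer_len: int = DEFAULT_SPACER_LEN,
) -> list[GuideRecord]:
    """Enumerate every candidate Cas12a site in ``genome`` on both strands.

    A candidate is a PAM-pattern occurrence followed (3' of the PAM, in
    the strand's orientation) by ``spacer_len`` bases of genomic
    sequence. Candidates whose protospacer would extend past the contig
    end are skipped with a log message.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    pat = re.compile(f"(?=({iupac_to_regex(pam_pattern)}))")
    plen = len(pam_pattern)
    out: list[GuideRecord] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for m in pat.finditer(s):
                i = m.start()
                proto = s[i + plen : i + plen + spacer_len]
                if len(proto) < spacer_len:
                    log.debug("skipping %s:%d (%s): spacer past contig end", chrom, i, strand)
                    continue
                if strand == "+":
                    start, end = i + 1, i + plen + spacer_len
                else:
                    # position j in revcomp maps to genome coordinate n-1-j (0-based)
                    start, end = n - i, n - (i + plen + spacer_len) + 1
                out.append(
                    GuideRecord(
                        name=f"{chrom}:{start}:{strand}",
                        pam=s[i : i + plen],
                        protospacer=proto,
                        strand=strand,
                        chrom=chrom,
                        start=start,
                        end=end,
                        pam_pattern=pam_pattern,
                    )
                )
    return out


def _pam_match_positions(arr: np.ndarray, pattern: str) -> np.ndarray:
    """0-based start positions where the IUPAC ``pattern`` matches ``arr``."""
    n = arr.size
    plen = len(pattern)
    if n < plen:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n - plen + 1, dtype=bool)
    from .dna import IUPAC

    for off, code in enumerate(pattern.upper()):
        window = arr[off : off + n - plen + 1]
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC[code]:
            allowed[ord(b)] = True
        ok &= allowed[window]
    return np.nonzero(ok)[0]


def count_offtargets(
    guide: GuideRecord,
    genome: Mapping[str, str],
    max_mm: int = 3,
) -> OffTargetCensus:
    """PAM-anchored mismatch census of ``guide`` against ``genome``.

    A site counts if the PAM position matches ``guide.pam_pattern``
    exactly and the adjacent ``spacer_len`` bases are within ``max_mm``
    Hamming mismatches of the protospacer. Both strands are scanned and
    the guide's own locus is excluded, so a genome-unique guide reports
    mm0 == 0.
    """
    pattern = guide.pam_pattern
    plen = len(pattern)
    proto = encode(guide.protospacer)
    L = proto.size
    counts = np.zeros(max_mm + 1, dtype=np.int64)
    own = (guide.chrom, guide.strand, guide.interval0())
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = encode(s)
            pos = _pam_match_positions(arr, pattern)
            pos = pos[pos + plen + L <= n]
            if pos.size == 0:
                continue
            windows = arr[pos[:, None] + (np.arange(L) + plen)[None, :]]
            mm = (windows != proto[None, :]).sum(axis=1)
            for p, d in zip(pos.tolist(), mm.tolist()):
                if d > max_mm:
                    continue
                if strand == "+":
                    iv = (p, p + plen + L)
                else:
                    iv = (n - (p + plen + L), n - p)
                if (chrom, strand, iv) == own:
                    continue
                counts[d] += 1
    pad = [int(c) for c in counts] + [0] * (4 - len(counts))
    return OffTargetCensus(*pad[:4])


def annotate_guides(
    guides: Iterable[GuideRecord],
    genome: Mapping[str, str],
    max_mm: int = 3,
) -> list[GuideRecord]:
    """Attach an off-target census to each guide."""
    return [replace(g, offtargets=count_offtargets(g, genome, max_mm)) for g in guides]


def define_enrichment_regions(
    up_pair: Sequence[GuideRecord],
    down_pair: Sequence[GuideRecord],
) -> EnrichmentRegions:
    """Derive the downstream / target / upstream regions from two guide pairs.

    Each guide contributes one boundary: the lower 1-based coordinate of
    its printed site. Sorting the four boundaries ascending yields
    b1 <= b2 <= b3 <= b4; the target is the middle interval (b2, b3),
    and each pair's own interval is its upstream/downstream region. The
    three regions tile (b1, b4), sharing boundary coordinates. This
    convention reproduces the published region table from the published
    guide table.
    """
    if len(up_pair) != 2 or len(down_pair) != 2:
        raise ValueError("exactly two guides per pair are required")
    chroms = {g.chrom for g in (*up_pair, *down_pair)}
    if len(chroms) != 1:
        raise ValueError(f"guides lie on different chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    up_b = sorted(g.boundary for g in up_pair)
    down_b = sorted(g.boundary for g in down_pair)
    if not (up_b[1] < down_b[0] or down_b[1] < up_b[0]):
        raise ValueError("guide pairs interleave or overlap; pairs must flank the target")
    lo_pair, hi_pair = (up_b, down_b) if up_b[1] < down_b[0] else (down_b, up_b)
    target = LabeledInterval("target", chrom, lo_pair[1], hi_pair[0])
    upstream = LabeledInterval("upstream", chrom, up_b[0], up_b[1])
    downstream = LabeledInterval("downstream", chrom, down_b[0], down_b[1])
    return EnrichmentRegions(target=target, upstream=upstream, downstream=downstream)


def published_fibh_guides() -> list[GuideRecord]:
    """The four FibH-flanking guides with their published metadata."""
    from .tables import FIBH_GUIDES

    return [
        GuideRecord(
            name=name,
            pam=pam,
            protospacer=proto,
            strand="-" if start > end else "+",
            chrom=chrom,
            start=start,
            end=end,
            efficiency_score=eff,
        )
        for name, pam, proto, chrom, start, end, eff in FIBH_GUIDES
    ]
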