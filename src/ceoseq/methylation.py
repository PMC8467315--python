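"""Aggregation of per-read CpG methylation calls.

Per-site: methylation frequency = called_sites_methylated / called_sites,
the convention of nanopolish-style frequency tables. Per-motif: the
reported statistic is the SUM over the motif's instances of the CG-site
frequency inside each instance (not a mean) — a motif with R copies
therefore has a total frequency in [0, R]. A ``--per-copy`` style view
(total / repetition) is available via :attr:`MotifSummary.per_copy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .repeats import MotifInstance

CALL_COLUMNS = ["chromosome", "position", "read_id", "call"]


@dataclass(frozen=True)
class SiteMethylation:
    """Aggregated calls at one CG site (0-based CG start position)."""

    chrom: str
    position: int
    called_sites: int
    called_sites_methylated: int

    def __post_init__(self) -> None:
        if not 0 <= self.called_sites_methylated <= self.called_sites:
            raise ValueError("called_sites_methylated must be in [0, called_sites]")

    @property
    def frequency(self) -> float:
        """called_sites_methylated / called_sites (0.0 for uncalled sites)."""
        if self.called_sites == 0:
            return 0.0
        return self.called_sites_methylated / self.called_sites


@dataclass(frozen=True)
class MotifSummary:
    """Per-motif methylation summary: instance count and the summed
    per-instance CG-site frequency."""

    motif_name: str
    sequence: str
    repetition: int
    methylation_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.methylation_frequency <= self.repetition + 1e-9:
            raise ValueError("summed frequency must be within [0, repetition]")

    @property
    def per_copy(self) -> float:
        """Mean per-instance frequency (total / repetition)."""
        return self.methylation_frequency / self.repetition if self.repetition else 0.0


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        df = pd.DataFrame(list(calls), columns=CALL_COLUMNS)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    return df


def site_frequencies(calls) -> list[SiteMethylation]:
    """Aggregate per-read calls into per-site tallies.

    ``calls`` is a DataFrame (or iterable of tuples) with columns
    chromosome, position, read_id, call where call is 1 (methylated) or
    0 (unmethylated). Each read may call each site at most once;
    duplicates raise. Sites with zero calls are absent from the output.
    """
    df = _calls_frame(calls)
    if df.empty:
        return []
    dup = df.duplicated(subset=["chromosome", "position", "read_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate call for read {row['read_id']!r} at "
            f"{row['chromosome']}:{row['position']}"
        )
    if not df["call"].isin([0, 1]).all():
        raise ValueError("call column must contain only 0/1")
    grouped = df.groupby(["chromosome", "position"], sort=True)["call"].agg(["count", "sum"])
    return [
        SiteMethylation(chrom, int(pos), int(row["count"]), int(row["sum"]))
        for (chrom, pos), row in grouped.iterrows()
    ]


def motif_frequencies(
    sites: Iterable[SiteMethylation],
    instances: Sequence[MotifInstance],
    motif_sequences: Mapping[str, str] | None = None,
) -> list[MotifSummary]:
    """Sum per-site frequencies over each motif's instances.

    A CG site belongs to an instance iff its start position lies within
    the instance's span; instances must not overlap where a site would
    be claimed twice. Instances whose CG site received no calls
    contribute 0. Repetition is the instance count.
    """
    by_chrom: dict[str, list[MotifInstance]] = {}
    for inst in sorted(instances, key=lambda i: (i.chrom, i.start)):
        by_chrom.setdefault(inst.chrom, []).append(inst)

    totals: dict[str, float] = {}
    reps: dict[str, int] = {}
    order: list[str] = []
    for inst in sorted(instances, key=lambda i: (i.chrom, i.start)):
        if inst.motif_name not in reps:
            reps[inst.motif_name] = 0
            totals[inst.motif_name] = 0.0
            order.append(inst.motif_name)
        reps[inst.motif_name] += 1

    from bisect import bisect_right

    starts = {c: [i.start for i in lst] for c, lst in by_chrom.items()}
    max_len = max((i.length for i in instances), default=0)
    for site in sites:
        chrom_inst = by_chrom.get(site.chrom, [])
        if not chrom_inst:
            continue
        # only instances starting within max_len of the site can contain it
        hi = bisect_right(starts[site.chrom], site.position)
        lo = bisect_right(starts[site.chrom], site.position - max_len)
        owners = [i for i in chrom_inst[lo:hi] if i.start <= site.position < i.end]
        if len(owners) > 1:
            names = [i.motif_name for i in owners]
            raise ValueError(
                f"CG site {site.chrom}:{site.position} lies inside "
                f"{len(owners)} overlapping instances ({names})"
            )
        if owners:
            totals[owners[0].motif_name] += site.frequency

    seqs = motif_sequences or {}
    return [
        MotifSummary(name, seqs.get(name, ""), reps[name], totals[name])
        for name in order
    ]


def count_methylated_sites(
    sites: Iterable[SiteMethylation], min_frequency: float | None = None
) -> int:
    """Number of 'methylated' sites: frequency > 0 by default, or
    frequency >= ``min_frequency`` when a threshold is given."""
    if min_frequency is not None and not 0.0 <= min_frequency <= 1.0:
        raise ValueError("min_frequency must be in [0, 1]")
    if min_frequency is None:
        return sum(1 for s in sites if s.frequency > 0)
    return sum(1 for s in sites if s.frequency >= min_frequency)


def read_frequency_table(path) -> list[SiteMethylation]:
    """Load a nanopolish-style methylation frequency TSV
    (chromosome, start, ..., called_sites, called_sites_methylated)
    directly as per-site records."""
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "start", "called_sites", "called_sites_methylated"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing columns: {sorted(missing)}")
    return [
        SiteMethylation(
            str(r.chromosome), int(r.start),
            int(r.called_sites), int(r.called_sites_methylated),
        )
        for r in df.itertuples()
    ]


def site_table(sites: Iterable[SiteMethylation]) -> pd.DataFrame:
    """Per-site bedMethyl-like frame (1-based reported positions)."""
    return pd.DataFrame(
        [
            {
                "chromosome": s.chrom,
                "position": s.position + 1,
                "called_sites": s.called_sites,
                "called_sites_methylated": s.called_sites_methylated,
                "methylated_frequency": round(s.frequency, 3),
            }
            for s in sites
        ]
    )


def motif_table(summaries: Iterable[MotifSummary]) -> pd.DataFrame:
    """Per-motif frame mirroring the published motif methylation table."""
    return pd.DataFrame(
        [
            {
                "motif_name": m.motif_name,
                "motif_sequence": m.sequence,
                "motif_repetition": m.repetition,
                "methylation_frequency": round(m.methylation_frequency, 3),
            }
            for m in summaries
        ]
    )
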