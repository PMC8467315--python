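"""File I/O: FASTA, FASTQ, BED, PAF and the call/region TSV layouts.

PAF records carry the twelve mandatory columns plus a ``qm:f:`` tag with
the read's mean quality, so alignment-level quality filtering works
without revisiting the FASTQ.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import AlignmentRecord
from .guides import GuideRecord, LabeledInterval
from .repeats import DomainSegment, MotifInstance


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as a name -> uppercase-sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads, path) -> None:
    """Write simulator reads (objects with read_id, sequence, mean_q)."""
    with open(path, "w") as fh:
        for r in reads:
            q = min(max(int(round(r.mean_q)), 0), 60)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{chr(q + 33) * len(r.sequence)}\n")


def write_bed(rows: Iterable[tuple], path) -> None:
    """Write BED rows (chrom, start, end[, name[, score[, strand]]]),
    0-based half-open."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def motif_instances_bed(instances: Iterable[MotifInstance]) -> list[tuple]:
    return [(i.chrom, i.start, i.end, i.motif_name, 0, i.strand) for i in instances]


def domains_bed(segments: Iterable[DomainSegment], chrom: str, offset: int = 0) -> list[tuple]:
    return [(chrom, offset + s.start, offset + s.end, s.kind) for s in segments]


def regions_bed(regions: Iterable[LabeledInterval]) -> list[tuple]:
    return [(r.chrom, r.start - 1, r.end, r.label) for r in regions]


def write_paf(reads, chrom_lengths: Mapping[str, int], path) -> None:
    """Ground-truth PAF for simulated reads: full-length, error-free
    alignments with a ``qm:f:`` mean-quality tag."""
    with open(path, "w") as fh:
        for r in reads:
            chrom, start, end, strand = r.truth
            n = end - start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.read_id, n, 0, n, strand, chrom, chrom_lengths[chrom],
                        start, end, n, n, 60, f"qm:f:{r.mean_q:.2f}",
                    )
                )
                + "\n"
            )


def read_paf(path) -> list[AlignmentRecord]:
    """Load PAF alignments; mean quality comes from a ``qm:f:`` tag when
    present, else NaN (filtering then requires explicit qualities)."""
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"malformed PAF line: {line!r}")
            mean_q = float("nan")
            for tag in f[12:]:
                if tag.startswith("qm:f:"):
                    mean_q = float(tag[5:])
            out.append(
                AlignmentRecord(
                    read_id=f[0], chrom=f[5], start=int(f[7]), end=int(f[8]),
                    strand=f[4], mean_q=mean_q,
                )
            )
    return out


def write_calls_tsv(reads, path) -> None:
    """Per-read CG calls: chromosome, position, read_id, call (1/0)."""
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tread_id\tcall\n")
        for r in reads:
            chrom = r.truth[0]
            for pos, state in r.cg_calls:
                fh.write(f"{chrom}\t{pos}\t{r.read_id}\t{state}\n")


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str, "position": int, "call": int})


def guides_tsv(guides: Sequence[GuideRecord]) -> pd.DataFrame:
    """Guide table mirroring the published layout: PAM lowercased inside
    the target sequence, 1-based location, GC%, census, size."""
    rows = []
    for g in guides:
        ot = g.offtargets
        rows.append(
            {
                "name": g.name,
                "target_sequence": g.pam.lower() + g.protospacer,
                "genomic_location": f"{g.chrom}:{g.start:,}-{g.end:,}",
                "gc_percent": g.gc_percent,
                "efficiency": g.efficiency_score if g.efficiency_score is not None else ".",
                "mm0": ot.mm0 if ot else ".",
                "mm1": ot.mm1 if ot else ".",
                "mm2": ot.mm2 if ot else ".",
                "mm3": ot.mm3 if ot else ".",
                "size": g.size,
            }
        )
    return pd.DataFrame(rows)
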