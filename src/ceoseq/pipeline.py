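"""End-to-end orchestration: simulate -> design-verify -> quantify ->
census -> methylation, with a structured config, per-stage logging,
a manifest (inputs, parameters, seed, checksums) and a consolidated
machine- plus human-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import coverage, methylation, repeats
from .expectation import expected_enrichment_fold
from .guides import annotate_guides
from .io import guides_tsv, read_calls_tsv, read_paf
from .locus import LocusSpec, MotifSpec, build_synthetic_locus
from .protocol import ProtocolParams, simulate_locus

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Analysis thresholds shared across stages."""

    min_q: float = 7.0
    min_len: int = 16_000
    window: int = 200
    density_threshold: float = 0.5
    merge_gap: int = 50
    min_frequency: float | None = None


@dataclass(frozen=True)
class RunConfig:
    locus: LocusSpec = field(default_factory=LocusSpec)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "ceo_run"


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys reject."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    allowed = {"locus", "protocol", "thresholds", "seed", "outdir"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    locus_raw = dict(raw.get("locus", {}))
    if "motif_mix" in locus_raw:
        locus_raw["motif_mix"] = tuple(
            _build(MotifSpec, dict(m), "locus.motif_mix") for m in locus_raw["motif_mix"]
        )
    protocol_raw = dict(raw.get("protocol", {}))
    for tup_key in ("cut_offsets", "fragment_len_range"):
        if tup_key in protocol_raw:
            protocol_raw[tup_key] = tuple(protocol_raw[tup_key])
    return RunConfig(
        locus=_build(LocusSpec, locus_raw, "locus"),
        protocol=_build(ProtocolParams, protocol_raw, "protocol"),
        thresholds=_build(Thresholds, dict(raw.get("thresholds", {})), "thresholds"),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "ceo_run")),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and write a consolidated report.

    Returns the machine-readable report dict; files (FASTA/BED/FASTQ/
    PAF/TSVs, report.json, report.txt, manifest.json) land in
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed}
    paths: dict[str, Path] = {}

    stage = "simulate"
    try:
        locus = build_synthetic_locus(config.locus, seed=config.seed)
        paths.update(locus.write(outdir))
        sim = simulate_locus(locus, config.protocol, seed=config.seed + 1)
        paths.update(sim.write(outdir))
        log.info("simulate: %d reads from %d genome copies",
                 len(sim.reads), config.protocol.n_genome_copies)
        report["simulate"] = {
            "n_reads": len(sim.reads),
            "genome_len": config.locus.genome_len,
            "gene": [locus.gene.start, locus.gene.end],
        }

        stage = "design"
        guides = annotate_guides(locus.guides, locus.genome)
        gdf = guides_tsv(guides)
        gdf.to_csv(outdir / "guides.tsv", sep="\t", index=False)
        paths["guides"] = outdir / "guides.tsv"
        report["design"] = gdf.to_dict(orient="records")

        stage = "quantify"
        alignments = read_paf(paths["paf"])
        kept = coverage.filter_reads(alignments, config.thresholds.min_q)
        log.info("quantify: %d/%d reads pass Q>=%g", len(kept), len(alignments),
                 config.thresholds.min_q)
        table = coverage.region_depth_table(
            alignments, list(locus.regions), sim.chrom_lengths, min_q=config.thresholds.min_q
        )
        table.to_csv(outdir / "region_depths.tsv", sep="\t", index=False)
        paths["region_depths"] = outdir / "region_depths.tsv"
        profile = coverage.depth_profile(kept, sim.chrom_lengths)
        report["quantify"] = {
            "reads_total": len(alignments),
            "reads_pass_q": len(kept),
            "genome_mean_depth": round(coverage.genome_mean_depth(profile), 2),
            "regions": table.to_dict(orient="records"),
            "long_reads_on_target": coverage.long_read_tally(
                kept, locus.regions.target, config.thresholds.min_len
            ),
            "expected_target_fold": round(
                expected_enrichment_fold(locus, config.protocol), 2
            ),
        }

        stage = "census"
        motifs = {m.name: m.sequence for m in config.locus.motif_mix}
        counts, instances = repeats.count_motifs(
            locus.gene_sequence, motifs, chrom=locus.chrom, offset=locus.gene.interval0()[0]
        )
        core0, core1 = locus.core
        core_inst = [
            dataclasses.replace(i, start=i.start - core0)
            for i in instances
            if core0 <= i.start and i.end <= core1
        ]
        segments = repeats.segment_domains(
            core_inst, core1 - core0,
            window=config.thresholds.window,
            density_threshold=config.thresholds.density_threshold,
            merge_gap=config.thresholds.merge_gap,
        )
        report["census"] = {
            "motif_counts": dict(counts),
            "n_repetitive_segments": sum(1 for s in segments if s.kind == repeats.REPETITIVE),
            "n_amorphous_segments": sum(1 for s in segments if s.kind == repeats.AMORPHOUS),
            "cg_sites_in_gene": len(locus.cg_sites),
        }

        stage = "methylation"
        calls = read_calls_tsv(paths["calls"])
        gene_lo, gene_hi = locus.gene.interval0()
        gene_calls = calls[(calls.position >= gene_lo) & (calls.position < gene_hi)]
        sites = methylation.site_frequencies(gene_calls)
        summaries = methylation.motif_frequencies(sites, instances, motifs)
        mdf = methylation.motif_table(summaries)
        mdf.to_csv(outdir / "motif_methylation.tsv", sep="\t", index=False)
        paths["motif_methylation"] = outdir / "motif_methylation.tsv"
        methylation.site_table(sites).to_csv(outdir / "site_methylation.tsv",
                                             sep="\t", index=False)
        paths["site_methylation"] = outdir / "site_methylation.tsv"
        report["methylation"] = {
            "called_sites": len(sites),
            "methylated_sites": methylation.count_methylated_sites(
                sites, config.thresholds.min_frequency
            ),
            "motifs": mdf.to_dict(orient="records"),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": {
            "locus": dataclasses.asdict(config.locus),
            "protocol": {
                **dataclasses.asdict(config.protocol),
                "cut_efficiency": dict(config.protocol.cut_efficiency)
                if not isinstance(config.protocol.cut_efficiency, float)
                else config.protocol.cut_efficiency,
            },
            "thresholds": dataclasses.asdict(config.thresholds),
        },
        "files": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in sorted(paths.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (outdir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict[str, Any]) -> str:
    """Human-readable summary of a run_all report."""
    lines = [f"CEO pipeline report (seed {report['seed']})", ""]
    q = report["quantify"]
    lines.append(f"Reads: {q['reads_total']} simulated, {q['reads_pass_q']} pass Q filter")
    lines.append(f"Genome mean depth: {q['genome_mean_depth']}x")
    lines.append("Regions (chromosome, description, start, end, depth, fold):")
    for r in q["regions"]:
        lines.append(
            f"  {r['chromosome']}\t{r['description']}\t{r['start']:,}\t{r['end']:,}"
            f"\t{r['average_depth']}\t{r['enrichment_fold']}"
        )
    lines.append(f"Expected target fold (closed form): {q['expected_target_fold']}")
    lines.append(f"Long on-target reads: {q['long_reads_on_target']}")
    c = report["census"]
    lines.append("")
    lines.append(
        f"Census: {c['n_repetitive_segments']} repetitive / "
        f"{c['n_amorphous_segments']} amorphous segments, "
        f"{c['cg_sites_in_gene']} CG sites in gene"
    )
    m = report["methylation"]
    lines.append(f"Methylation: {m['methylated_sites']}/{m['called_sites']} sites methylated")
    for row in m["motifs"]:
        lines.append(
            f"  {row['motif_name']}\t{row['motif_sequence']}"
            f"\t{row['motif_repetition']}\t{row['methylation_frequency']}"
        )
    return "\n".join(lines) + "\n"
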