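"""Pipeline orchestration: run every analysis stage over one or more
annotated genomes and emit a TSV + JSON report bundle.

Outputs are plain TSV (diffable, re-runnable byte-identically for a
fixed config and inputs) plus one ``summary.json``.  Every TSV carries
the thresholds used in a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import codon_trna, duplication_split, orf_annotation, proteome_compare, skew_analysis
from .genome_io import GenomeRecord, feature_sequence, read_annotations

log = logging.getLogger(__name__)

ALL_STAGES = ("stats", "skew", "codon", "compare", "duplication", "splits", "synteny")

_CONFIG_KEYS = {
    "inputs", "fmt", "outdir", "stages", "min_aa", "rbs_spacer_min",
    "rbs_spacer_max", "homolog_max_evalue", "dup_max_evalue",
    "nt_min_identity", "nt_min_coverage", "synteny_max_gap",
    "trna_min_coverage", "trna_min_identity", "skew_window", "skew_step",
    "seed", "log_level",
}


@dataclass
class PipelineConfig:
    inputs: list[str]
    fmt: str = "genbank"
    outdir: str = "compgen_out"
    stages: tuple[str, ...] = ALL_STAGES
    min_aa: int = 30
    rbs_spacer_min: int = 4
    rbs_spacer_max: int = 18
    homolog_max_evalue: float = 1e-6
    dup_max_evalue: float = 1e-3
    nt_min_identity: float = 65.0
    nt_min_coverage: float = 50.0
    synteny_max_gap: int = 3
    trna_min_coverage: float = 50.0
    trna_min_identity: float = 70.0
    skew_window: int = 1000
    skew_step: int = 500
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in self.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.min_aa and 0 < self.skew_window and 0 < self.skew_step):
            raise ValueError("thresholds out of range")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file (``#`` comments allowed)."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            k, v = (x.strip() for x in line.split("=", 1))
            if k not in _CONFIG_KEYS:
                raise ValueError(f"unknown config key: {k!r}")
            kv[k] = v
        cfg = cls(inputs=[])
        for k, v in kv.items():
            if k in ("inputs", "stages"):
                setattr(cfg, k, [x.strip() for x in v.split(",") if x.strip()])
            else:
                cur = getattr(cfg, k)
                setattr(cfg, k, type(cur)(v))
        return cfg


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, thresholds: dict | None = None) -> None:
    with open(path, "w") as fh:
        if thresholds:
            fh.write("# " + "; ".join(f"{k}={v}" for k, v in sorted(thresholds.items())) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _trna_genes(record: GenomeRecord) -> list[codon_trna.TrnaGene]:
    out = []
    for f in record.trnas():
        out.append(codon_trna.TrnaGene(
            locus_tag=f.locus_tag, amino_acid=f.amino_acid or "?",
            anticodon=f.anticodon or "", start=f.start, end=f.end,
            strand=f.strand, sequence=feature_sequence(record, f)))
    return out


def analyze_genome(record: GenomeRecord, config: PipelineConfig | None = None) -> dict:
    """Single-genome analyses (stats, skew, codon/tRNA) as one dict.

    This is the per-genome core of the pipeline and the entry point for
    reproducing deposited-accession statistics.
    """
    config = config or PipelineConfig(inputs=[])
    stats = orf_annotation.genome_stats(record)
    profile = skew_analysis.gc_skew(record.sequence, window=config.skew_window,
                                    step=config.skew_step,
                                    circular=record.circular)
    ori_ter = skew_analysis.predict_ori_ter(profile)
    cds_seqs = [
        feature_sequence(record, f) for f in record.cds()
        if f.length(len(record)) % 3 == 0
    ]
    usage = codon_trna.codon_usage(cds_seqs)
    optimal = codon_trna.optimal_codons(usage)
    trnas = _trna_genes(record)
    optrep = codon_trna.trna_optimality(trnas, optimal)
    return {
        "stats": stats,
        "skew_profile": profile,
        "ori_ter": ori_ter,
        "codon_usage": usage,
        "optimal_codons": optimal,
        "trna_optimality": optrep,
    }


def analyze_genbank(path: str | Path) -> dict:
    """Headline numbers for one GenBank record (accession reproduction).

    Returns plain scalars: length, GC%, feature counts, start/stop codon
    tallies, mean product length, total codon count, cumulative-skew
    extrema, and the tRNA-optimality fraction.
    """
    record = read_annotations(path, fmt="genbank")
    res = analyze_genome(record)
    stats: orf_annotation.GenomeStats = res["stats"]
    opt: codon_trna.OptimalityReport = res["trna_optimality"]
    return {
        "genome_id": record.id,
        "length_bp": stats.length_bp,
        "gc_percent": round(stats.gc_percent, 1),
        "n_cds": stats.n_cds,
        "n_trna": stats.n_trna,
        "gene_density": stats.gene_density,
        "coding_percent": round(stats.coding_percent, 1),
        "avg_product_aa": round(stats.avg_product_aa),
        "start_codon_counts": dict(stats.start_codon_counts),
        "stop_codon_counts": dict(stats.stop_codon_counts),
        "total_codons": res["codon_usage"].total_codons,
        "skew_min_pos": res["skew_profile"].min_pos,
        "skew_max_pos": res["skew_profile"].max_pos,
        "origin_pos": res["ori_ter"].origin,
        "terminus_pos": res["ori_ter"].terminus,
        "n_optimal_trnas": opt.n_optimal_trnas,
        "n_a_ending_trnas": opt.n_a_ending,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages over all inputs; write the report bundle.

    Returns the summary dict (also written as ``summary.json``).  A stage
    failure marks the bundle partial and names the failing stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": {k: v if not isinstance(v, tuple) else list(v)
                   for k, v in asdict(config).items()},
        "inputs": [{"path": str(p), "sha256_16": _digest(p)} for p in config.inputs],
        "genomes": {},
        "stage_seconds": {},
        "status": "ok",
    }
    records = [read_annotations(p, fmt=config.fmt) for p in config.inputs]
    cache: dict = {}
    failing = None
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            failing = stage
            _run_stage(stage, records, config, outdir, summary, cache)
            summary["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)
        failing = None
    except Exception as exc:  # noqa: BLE001 - reported in the bundle
        summary["status"] = "partial"
        summary["failed_stage"] = failing
        summary["error"] = str(exc)
        log.error("stage %s failed: %s", failing, exc)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _core_result(records, config: PipelineConfig, cache: dict):
    if "core" not in cache:
        proteomes = [proteome_compare.proteome_from_record(r) for r in records]
        cache["proteomes"] = proteomes
        cache["core"] = proteome_compare.core_genome(
            proteomes, max_evalue=config.homolog_max_evalue)
    return cache["core"]


def _run_stage(stage, records, config: PipelineConfig, outdir: Path, summary,
               cache: dict) -> None:
    if stage == "stats":
        rows = [orf_annotation.genome_stats(r).to_dict() for r in records]
        _write_tsv(pd.DataFrame(rows), outdir / "genome_stats.tsv")
        for row in rows:
            summary["genomes"].setdefault(row["genome_id"], {})["stats"] = row
    elif stage == "skew":
        for r in records:
            profile = skew_analysis.gc_skew(r.sequence, config.skew_window,
                                            config.skew_step, r.circular)
            call = skew_analysis.predict_ori_ter(profile)
            df = pd.DataFrame({
                "position": profile.positions,
                "window_skew": profile.skew,
                "cumulative": profile.cumulative[
                    (profile.positions - 1).clip(0, len(profile.cumulative) - 1)
                ],
            })
            _write_tsv(df, outdir / f"skew_{r.id}.tsv",
                       {"window": config.skew_window, "step": config.skew_step})
            summary["genomes"].setdefault(r.id, {})["ori_ter"] = {
                "origin": call.origin, "terminus": call.terminus,
                "status": call.status,
            }
    elif stage == "codon":
        for r in records:
            res = analyze_genome(r, config)
            usage: codon_trna.CodonUsageTable = res["codon_usage"]
            per_k = usage.per_thousand()
            df = pd.DataFrame({
                "codon": codon_trna.ALL_CODONS,
                "amino_acid": [codon_trna.CODON_TO_AA[c] for c in codon_trna.ALL_CODONS],
                "count": [usage.counts.get(c, 0) for c in codon_trna.ALL_CODONS],
                "per_thousand": [round(per_k.get(c, 0.0), 3) for c in codon_trna.ALL_CODONS],
                "optimal": [res["optimal_codons"].get(codon_trna.CODON_TO_AA[c]) == c
                            for c in codon_trna.ALL_CODONS],
            })
            _write_tsv(df, outdir / f"codon_usage_{r.id}.tsv")
            opt: codon_trna.OptimalityReport = res["trna_optimality"]
            _write_tsv(pd.DataFrame(opt.rows), outdir / f"trna_optimality_{r.id}.tsv")
            summary["genomes"].setdefault(r.id, {})["trna_optimality"] = {
                "n_trnas": opt.n_trnas, "n_optimal": opt.n_optimal_trnas,
                "n_a_ending": opt.n_a_ending,
            }
    elif stage == "compare":
        if len(records) < 2:
            summary["comparative"] = "single genome: comparative sections empty"
            return
        core = _core_result(records, config, cache)
        for gid, df in core.homolog_tables.items():
            _write_tsv(df, outdir / f"homologs_{core.reference}_vs_{gid}.tsv",
                       {"max_evalue": config.homolog_max_evalue})
        _write_tsv(core.presence.reset_index(names="locus"),
                   outdir / "presence_absence.tsv")
        shared = proteome_compare.shared_count_summary(core, len(cache["proteomes"][0]))
        _write_tsv(shared, outdir / "shared_counts.tsv")
        summary["comparative"] = {
            "reference": core.reference,
            "core_size": len(core.core),
            "shared_counts": core.shared_counts,
            "max_identity": {k: round(v, 1) for k, v in core.max_identity.items()},
        }
    elif stage == "synteny":
        if len(records) < 2:
            return
        core = _core_result(records, config, cache)
        for gid, df in core.homolog_tables.items():
            rep = proteome_compare.synteny_blocks(df, max_gap=config.synteny_max_gap)
            rows = [{
                "block": i, "orientation": b.orientation, "n_genes": len(b),
                "q_loci": ",".join(q for q, _ in b.pairs),
                "s_loci": ",".join(s for _, s in b.pairs),
            } for i, b in enumerate(rep.blocks)]
            rows += [{"block": -1, "orientation": "relocated", "n_genes": 1,
                      "q_loci": q, "s_loci": s} for q, s in rep.relocated]
            _write_tsv(pd.DataFrame(rows),
                       outdir / f"synteny_{core.reference}_vs_{gid}.tsv",
                       {"max_gap": config.synteny_max_gap})
    elif stage == "duplication":
        for r in records:
            calls = duplication_split.call_duplications(
                r, max_evalue=config.dup_max_evalue,
                nt_min_identity=config.nt_min_identity,
                nt_min_coverage=config.nt_min_coverage)
            rows = [{
                "gene_a": c.gene_a, "gene_b": c.gene_b,
                "aa_identity": round(c.aa_identity, 1),
                "aa_evalue": c.aa_evalue,
                "nt_identity": round(c.nt_identity or 0.0, 1),
                "nt_coverage": round(c.nt_coverage or 0.0, 1),
                "verdict": c.verdict,
            } for c in calls]
            _write_tsv(pd.DataFrame(rows), outdir / f"duplications_{r.id}.tsv",
                       {"max_evalue": config.dup_max_evalue,
                        "nt_min_identity": config.nt_min_identity,
                        "nt_min_coverage": config.nt_min_coverage})
            summary["genomes"].setdefault(r.id, {})["n_duplication_candidates"] = len(rows)
    elif stage == "splits":
        if len(records) < 2:
            return
        proteomes = [proteome_compare.proteome_from_record(r) for r in records]
        ref = proteomes[0]
        for other in proteomes[1:]:
            calls = duplication_split.detect_splits(other, ref)
            rows = [{
                "target": c.target,
                "fragments": ",".join(f.fragment for f in c.fragments),
                "segments": ";".join(f"{f.t_start}-{f.t_end}" for f in c.fragments),
                "combined_coverage": round(c.combined_coverage, 1),
                "max_overlap": round(c.max_pairwise_overlap, 1),
            } for c in calls]
            _write_tsv(pd.DataFrame(rows),
                       outdir / f"splits_{other.genome_id}_targets_{ref.genome_id}_fragments.tsv")
    else:
        raise ValueError(f"unknown stage {stage}")
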