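"""End-to-end pipeline: one config document, machine-readable reports.

The pipeline runs the stages in dependency order (genome io -> repeat
screens -> rearrangement -> repeat tracing -> gene transfer), writing a TSV
or JSON artefact per stage plus a single ``report.json`` that echoes the
configuration (and its hash) for provenance.  Identical config + seeds give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional

from . import __version__
from .gene_transfer import find_introns, longest_orf, scan_promoter
from .genome_io import (
    format_percent,
    gc_content,
    parse_fasta,
    parse_genbank,
)
from .rearrangement import distance_matrix, read_grimm, sort_by_reversals
from .repeat_trace import (
    classify_arrangement,
    config_from_json,
    count_repeat_loci,
    scenario_from_json,
    trace_scenario,
)
from .repeats import (
    DEFAULT_SSR_THRESHOLDS,
    classify_ssr_regions,
    find_ssrs,
    find_tandem_repeats,
)

logger = logging.getLogger("plastrace")

_KNOWN_KEYS = {
    "seed",
    "output_dir",
    "stages",
    "genome",
    "permutations",
    "trace_config",
    "trace_scenario",
    "trace_prefix",
    "genomic",
    "transcript",
    "upstream",
    "ssr_thresholds",
    "tandem_min_unit",
    "tandem_min_identity",
    "promoter_motif",
    "promoter_window",
}
_KNOWN_STAGES = ("stats", "ssr", "tandem", "rearrangement", "trace", "gene_transfer")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration."""


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", {})
    bad = set(stages) - set(_KNOWN_STAGES)
    if bad:
        raise PipelineConfigError(f"unknown stages: {sorted(bad)}")
    return config


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: Optional[str] = None) -> dict:
    """Execute the configured stages; returns the report dict.

    Stage artefacts and ``report.json`` are written under the output
    directory (``output_dir`` in the config, overridable by ``out_dir``).
    A stage failure aborts the run with a log line naming the stage.
    """
    validate_config(config)
    out = Path(out_dir or config.get("output_dir", "plastrace_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", {s: True for s in _KNOWN_STAGES})
    report: dict = {
        "tool": "plastrace",
        "version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    genome = None
    if config.get("genome"):
        genome = parse_genbank(config["genome"])

    def stage(name):
        return stages.get(name, False)

    try:
        if stage("stats"):
            _require(genome, "stats", "genome")
            block = {
                "id": genome.id,
                "length_bp": len(genome),
                "gc_percent": format_percent(gc_content(genome)),
                "n_features": len(genome.features),
            }
            report["stages"]["stats"] = block
            logger.info("stats: %s bp, GC %s%%", block["length_bp"], block["gc_percent"])

        if stage("ssr"):
            _require(genome, "ssr", "genome")
            thr = {
                int(k): int(v)
                for k, v in config.get(
                    "ssr_thresholds", DEFAULT_SSR_THRESHOLDS
                ).items()
            }
            loci = classify_ssr_regions(find_ssrs(genome.seq, thr), genome)
            path = out / "ssr.tsv"
            with open(path, "w") as fh:
                fh.write("locus\tmotif\tunit_len\tcopies\tstart\tend\tregion\n")
                for i, l in enumerate(loci, 1):
                    fh.write(
                        f"SSR{i}\t{l.motif}\t{l.unit_len}\t{l.copies}"
                        f"\t{l.start}\t{l.end}\t{l.region_class}\n"
                    )
            by_unit: dict[int, int] = {}
            by_region: dict[str, int] = {}
            for l in loci:
                by_unit[l.unit_len] = by_unit.get(l.unit_len, 0) + 1
                by_region[l.region_class] = by_region.get(l.region_class, 0) + 1
            report["stages"]["ssr"] = {
                "total": len(loci),
                "by_unit_len": by_unit,
                "by_region": by_region,
                "tsv": path.name,
            }
            logger.info("ssr: %d loci", len(loci))

        if stage("tandem"):
            _require(genome, "tandem", "genome")
            trs = find_tandem_repeats(
                genome.seq,
                min_unit=int(config.get("tandem_min_unit", 30)),
                min_identity=float(config.get("tandem_min_identity", 0.90)),
            )
            path = out / "tandem.tsv"
            with open(path, "w") as fh:
                fh.write("repeat\tunit_len\tcopies\tidentity\tstart\tend\n")
                for i, t in enumerate(trs, 1):
                    fh.write(
                        f"TR{i}\t{t.unit_len}\t{t.copies}\t{t.identity}"
                        f"\t{t.start}\t{t.end}\n"
                    )
            report["stages"]["tandem"] = {"total": len(trs), "tsv": path.name}
            logger.info("tandem: %d arrays", len(trs))

        if stage("rearrangement"):
            if not config.get("permutations"):
                raise PipelineConfigError("rearrangement stage needs 'permutations'")
            perms = read_grimm(Path(config["permutations"]).read_text())
            names = list(perms)
            mat = distance_matrix(list(perms.values()))
            path = out / "distance_matrix.tsv"
            with open(path, "w") as fh:
                fh.write("\t" + "\t".join(names) + "\n")
                for nm, row in zip(names, mat):
                    fh.write(nm + "\t" + "\t".join(str(int(x)) for x in row) + "\n")
            report["stages"]["rearrangement"] = {
                "genomes": names,
                "max_distance": int(mat.max()) if len(names) > 1 else 0,
                "tsv": path.name,
            }
            logger.info("rearrangement: %d genomes", len(names))

        if stage("trace"):
            if not config.get("trace_config"):
                raise PipelineConfigError("trace stage needs 'trace_config'")
            cfg = config_from_json(
                json.loads(Path(config["trace_config"]).read_text())
            )
            steps = scenario_from_json(
                json.loads(Path(config["trace_scenario"]).read_text())
            ) if config.get("trace_scenario") else []
            prefix = config.get("trace_prefix", "")
            states = trace_scenario(cfg, steps)
            path = out / "trace.tsv"
            with open(path, "w") as fh:
                fh.write("step\tarrangement\tloci\tclass\n")
                for i, st in enumerate(states):
                    cls = classify_arrangement(st, prefix)
                    if isinstance(cls, tuple):
                        cls = cls[0]
                    fh.write(
                        f"{i}\t{st}\t{count_repeat_loci(st, prefix)}\t{cls}\n"
                    )
            final_cls = classify_arrangement(states[-1], prefix)
            report["stages"]["trace"] = {
                "steps": len(states) - 1,
                "final_loci": count_repeat_loci(states[-1], prefix),
                "final_class": final_cls[0]
                if isinstance(final_cls, tuple)
                else final_cls,
                "tsv": path.name,
            }
            logger.info("trace: %d steps", len(states) - 1)

        if stage("gene_transfer"):
            if not (config.get("genomic") and config.get("transcript")):
                raise PipelineConfigError(
                    "gene_transfer stage needs 'genomic' and 'transcript'"
                )
            genomic = parse_fasta(config["genomic"]).seq
            transcript = parse_fasta(config["transcript"]).seq
            gs = find_introns(genomic, transcript)
            protein, _, _ = longest_orf(transcript)
            block = {
                "orf_span": [gs.orf_start, gs.orf_end],
                "protein_length": len(protein),
                "utr5_len": gs.utr5_len,
                "utr3_len": gs.utr3_len,
                "introns": [
                    {
                        "start": i.start,
                        "end": i.end,
                        "length": i.length,
                        "offsets": [i.five_offset, i.three_offset],
                        "gt_ag": i.gt_ag,
                    }
                    for i in gs.introns
                ],
                "exon_mismatches": list(gs.exon_mismatches),
            }
            if config.get("upstream"):
                upstream = parse_fasta(config["upstream"]).seq
                block["promoter_hits"] = scan_promoter(
                    upstream,
                    config.get("promoter_motif", "TATA"),
                    config.get("promoter_window"),
                )
            report["stages"]["gene_transfer"] = block
            logger.info("gene_transfer: %d introns", len(gs.introns))
    except Exception as exc:
        failed = next(
            (s for s in _KNOWN_STAGES if s not in report["stages"] and stage(s)),
            "unknown",
        )
        logger.error("stage %r failed: %s", failed, exc)
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _require(obj, stage: str, key: str):
    if obj is None:
        raise PipelineConfigError(f"{stage} stage needs {key!r} in the config")
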