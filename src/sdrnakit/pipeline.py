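"""End-to-end pipeline: ingest -> profile -> sdRNA classification -> reports.

Driven by a JSON/YAML config that either points at real per-compartment
alignment files plus an annotation, or requests a simulation preset.  All
outputs are TSV/JSON; a manifest records the tool version, config hash,
input/output checksums, seed and per-stage record counts.  Outputs are
deterministic given identical inputs and seed (the manifest's timestamps
are informational; the recorded checksums are the determinism contract).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import sha256_file, sha256_text
from .annotation import AnnotationSet, load_annotation
from .classifier import (
    build_locus_table,
    call_reads,
    compartment_correlation,
    filter_loci,
    five_prime_fraction_comparison,
)
from .ingest import Library, filter_unique, load_library
from .profiler import (
    AssignmentStatus,
    assign_reads,
    biotype_breakdown,
    size_histogram,
    summarize_alignment,
)
from .simulate import (
    SimConfig,
    apply_overrides,
    make_reference,
    preset_paper_like,
    simulate_libraries,
    write_reference,
)

log = logging.getLogger(__name__)

_VALID_KEYS = {
    "seed", "simulate", "libraries", "annotation", "min_overlap_frac",
    "min_reads", "uniform_denominator", "end_rule",
}


class ConfigError(ValueError):
    pass


def load_config(config_path: str | Path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    config = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    unknown = set(config) - _VALID_KEYS
    if unknown:
        raise ConfigError(
            f"invalid config key(s) {sorted(unknown)}; valid keys: {sorted(_VALID_KEYS)}"
        )
    if ("simulate" in config) == ("libraries" in config):
        raise ConfigError("config must provide exactly one of 'simulate' or 'libraries'")
    if "libraries" in config and "annotation" not in config:
        raise ConfigError("'libraries' input requires an 'annotation' section")


def _sim_config_from_section(section: dict, seed: int) -> SimConfig:
    preset = section.get("preset", "paper-like")
    if preset not in ("paper-like", "default"):
        raise ConfigError(f"unknown simulation preset {preset!r}")
    base = preset_paper_like() if preset == "paper-like" else SimConfig()
    overrides = dict(section.get("overrides", {}))
    overrides["seed"] = seed
    return apply_overrides(base, overrides)


def _load_inputs(config: dict, outdir: Path, manifest: dict):
    seed = int(config.get("seed", 0))
    if "simulate" in config:
        sim_config = _sim_config_from_section(config["simulate"], seed)
        reference = make_reference(sim_config)
        sim_dir = outdir / "sim"
        ref_paths = write_reference(reference, sim_dir)
        sim_out = simulate_libraries(sim_config, reference, outdir=sim_dir)
        manifest["inputs"]["simulated"] = {
            str(k): str(v) for k, v in ref_paths.items()
        }
        libraries = sim_out.libraries
        annotation = reference.annotation
    else:
        ann_section = config["annotation"]
        for key in ("gff3",):
            if key not in ann_section:
                raise ConfigError("annotation section requires a 'gff3' path")
        for key, val in ann_section.items():
            if key.endswith("contig"):
                continue
            if not Path(val).exists():
                raise FileNotFoundError(f"annotation stage: missing input {val}")
            manifest["inputs"][f"annotation.{key}"] = sha256_file(val)
        annotation = load_annotation(
            ann_section["gff3"],
            sidecar_tsv_path=ann_section.get("sidecar"),
            rdna_segments_path=ann_section.get("rdna_segments"),
            rdna_contig=ann_section.get("rdna_contig", "rDNA"),
        )
        libraries = {}
        for lib_spec in config["libraries"]:
            for key in ("compartment", "alignments", "raw_read_count"):
                if key not in lib_spec:
                    raise ConfigError(f"library spec missing {key!r}: {lib_spec}")
            if not Path(lib_spec["alignments"]).exists():
                raise FileNotFoundError(
                    f"ingest stage: missing alignment file {lib_spec['alignments']}"
                )
            manifest["inputs"][f"library.{lib_spec['compartment']}"] = sha256_file(
                lib_spec["alignments"]
            )
            libraries[lib_spec["compartment"]] = load_library(
                lib_spec["alignments"],
                lib_spec["compartment"],
                int(lib_spec["raw_read_count"]),
                seq_source=lib_spec.get("reads"),
            )
    return libraries, annotation


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full analysis; returns the manifest dict.

    Output directory contents: table1.tsv (alignment summary), table2.tsv
    (biotype breakdown), sizes.tsv (length histograms), calls.tsv (per-read
    sdRNA calls), locus_table.tsv, fiveprime_comparison.tsv,
    correlations.json, manifest.json (written last).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "sdrnakit",
        "version": __version__,
        "config_sha256": sha256_text(json.dumps(config, sort_keys=True, default=str)),
        "seed": int(config.get("seed", 0)),
        "started": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "stage_counts": {},
        "outputs": {},
    }

    libraries, annotation = _load_inputs(config, outdir, manifest)
    min_overlap = float(config.get("min_overlap_frac", 0.8))
    min_reads = int(config.get("min_reads", 10))
    uniform_denominator = bool(config.get("uniform_denominator", False))
    end_rule = str(config.get("end_rule", "midpoint"))

    table1_rows, table2_rows, size_rows, call_rows = [], [], [], []
    all_calls = []
    for comp, lib in libraries.items():
        counts = {"ingested": len(lib.reads)}
        unique = filter_unique(lib)
        counts["unique"] = len(unique.reads)
        counts["multimapped_dropped"] = counts["ingested"] - counts["unique"]
        assignments = assign_reads(unique, annotation, min_overlap_frac=min_overlap)
        counts["assigned"] = sum(
            1 for a in assignments if a.status is AssignmentStatus.ASSIGNED
        )
        counts["unannotated"] = sum(
            1 for a in assignments if a.status is AssignmentStatus.UNANNOTATED
        )
        counts["ambiguous"] = sum(
            1 for a in assignments if a.status is AssignmentStatus.AMBIGUOUS
        )
        summary = summarize_alignment(
            unique, assignments, uniform_denominator=uniform_denominator
        )
        table1_rows.append(dataclasses.asdict(summary))
        breakdown = biotype_breakdown(comp, assignments)
        table2_rows.append(
            {
                "compartment": comp,
                "srna_reads": breakdown.srna_reads,
                **{f"{k}_reads": v for k, v in breakdown.counts.items()},
                **{f"pct_{k}": v for k, v in breakdown.pct.items()},
            }
        )
        hist = size_histogram(comp, assignments)
        size_rows.extend(
            {"compartment": comp, "length": n, "count": c} for n, c in hist.counts.items()
        )
        calls, n_flanking = call_reads(assignments, annotation, comp, end_rule=end_rule)
        counts["sdrna_calls"] = len(calls)
        counts["snorna_flanking"] = n_flanking
        all_calls.extend(calls)
        for c in calls:
            sno = annotation.features[c.sno_id]
            call_rows.append(
                {
                    "read_id": c.read_id,
                    "compartment": c.compartment,
                    "sno_id": c.sno_id,
                    "end_class": c.end_class.value,
                    "boxes": ",".join(sorted(c.boxes_found)),
                    "box_positions": ";".join(c.box_position_labels(sno)),
                    "guide_retained": c.guide_retained,
                    "read_length": c.read_length,
                }
            )
        manifest["stage_counts"][comp] = counts

    locus_table = build_locus_table(all_calls)
    filtered = filter_loci(locus_table, min_reads=min_reads)

    outputs = {
        "table1.tsv": pd.DataFrame(table1_rows),
        "table2.tsv": pd.DataFrame(table2_rows),
        "sizes.tsv": pd.DataFrame(size_rows, columns=["compartment", "length", "count"]),
        "calls.tsv": pd.DataFrame(
            call_rows,
            columns=[
                "read_id", "compartment", "sno_id", "end_class", "boxes",
                "box_positions", "guide_retained", "read_length",
            ],
        ),
        "locus_table.tsv": locus_table,
        "locus_table_min%d.tsv" % min_reads: filtered,
    }

    comps = sorted(libraries)
    correlations = {}
    fp_rows = []
    for i, ca in enumerate(comps):
        for cb in comps[i + 1 :]:
            key = f"{ca}_vs_{cb}"
            try:
                res = compartment_correlation(locus_table, ca, cb)
                correlations[key] = {
                    "r": res.r, "r2": res.r_squared, "n_loci": res.n_loci
                }
            except ValueError as exc:
                correlations[key] = {"error": str(exc)}
            pairs = five_prime_fraction_comparison(locus_table, ca, cb, min_reads=min_reads)
            for _, row in pairs.iterrows():
                fp_rows.append({"comp_a": ca, "comp_b": cb, **row.to_dict()})
    outputs["fiveprime_comparison.tsv"] = pd.DataFrame(
        fp_rows,
        columns=["comp_a", "comp_b", "sno_id", "fraction_a", "fraction_b",
                 "read_count_a", "read_count_b"],
    )

    for name, df in outputs.items():
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = sha256_file(path)
    corr_path = outdir / "correlations.json"
    corr_path.write_text(json.dumps(correlations, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["correlations.json"] = sha256_file(corr_path)

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("pipeline finished; outputs in %s", outdir)
    return manifest
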