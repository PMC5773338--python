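"""End-to-end orchestration: demux -> merge -> genotype -> popgen.

A run is driven by a single config mapping (usually loaded from YAML),
executes every stage under one output directory, and writes a manifest
recording the package version, the full configuration, input checksums
and per-stage read counts.  Read-count conservation (the demux
partition and the merge input/output balance) is asserted and fails the
run if violated, so a manifest is also a proof of bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from typing import Mapping

from . import __version__
from .genotyper import GenotypeRules, genotype_experiment
from .popgen_stats import DEFAULT_MC_REPS, summarize_all
from .read_merge import merge_directory
from .scheme_demux import demux_stream, load_scheme


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the context."""


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_locus_motifs(path) -> dict[str, list[str]]:
    """TSV mapping amplicon name -> comma-separated ordered repeat units."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, units = line.split("\t")[:2]
            out[name] = [u.strip().upper() for u in units.split(",")]
    return out


def write_locus_motifs(motifs: Mapping[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, units in motifs.items():
            fh.write(f"{name}\t{','.join(units)}\n")


def _log(stage: str, **kv) -> None:
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"{stamp} stage={stage} {pairs}")


def run_pipeline(config: Mapping) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    Required config keys: ``r1``, ``r2``, ``scheme``, ``outdir``,
    ``locus_motifs`` (mapping or TSV path), ``seed``.  Optional
    per-stage parameter mappings: ``demux``, ``merge``, ``genotype``,
    ``popgen``.
    """
    for key in ("r1", "r2", "scheme", "outdir", "seed"):
        if key not in config:
            raise PipelineError(f"config: missing required key {key!r}")
    for key in ("r1", "r2", "scheme"):
        if not os.path.exists(config[key]):
            raise PipelineError(f"config: input file {config[key]!r} does not exist")
    motifs = config.get("locus_motifs")
    if motifs is None:
        raise PipelineError("config: missing required key 'locus_motifs'")
    if isinstance(motifs, (str, os.PathLike)):
        motifs = load_locus_motifs(motifs)

    outdir = config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    scheme = load_scheme(config["scheme"])
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in config.items() if k != "locus_motifs"},
        "locus_motifs": motifs,
        "inputs": {
            k: {"path": str(config[k]), "sha256": _sha256(config[k])}
            for k in ("r1", "r2", "scheme")
        },
        "stages": {},
    }

    demux_params = dict(config.get("demux", {}))
    demux_dir = os.path.join(outdir, "demux")
    _log("demux", r1=config["r1"], r2=config["r2"])
    counts = demux_stream(config["r1"], config["r2"], scheme, demux_dir, **demux_params)
    n_pairs = int(counts["pairs"].sum()) if len(counts) else 0
    assigned = int(counts[counts["reason"] == "ok"]["pairs"].sum()) if len(counts) else 0
    manifest["stages"]["demux"] = {
        "pairs_in": n_pairs,
        "assigned": assigned,
        "unassigned": n_pairs - assigned,
        "params": demux_params,
    }
    _log("demux", pairs=n_pairs, assigned=assigned)

    merge_params = dict(config.get("merge", {}))
    merged_dir = os.path.join(outdir, "merged")
    stats = merge_directory(demux_dir, merged_dir, **merge_params)
    merged_in = int(stats["input"].sum()) if len(stats) else 0
    merged_out = int(stats["merged"].sum()) if len(stats) else 0
    if merged_in != assigned:
        raise PipelineError(
            f"merge: read-count conservation violated ({merged_in} != {assigned})"
        )
    manifest["stages"]["merge"] = {
        "pairs_in": merged_in,
        "merged": merged_out,
        "unmerged": merged_in - merged_out,
        "params": merge_params,
    }
    _log("merge", pairs=merged_in, merged=merged_out)

    geno_params = dict(config.get("genotype", {}))
    rules = GenotypeRules(**geno_params)
    matrix, report = genotype_experiment(merged_dir, motifs, rules)
    matrix_path = os.path.join(outdir, "genotypes.tsv")
    report_path = os.path.join(outdir, "curation_report.tsv")
    matrix.to_csv(matrix_path, sep="\t", index=False)
    report.to_csv(report_path, sep="\t", index=False)
    manifest["stages"]["genotype"] = {
        "calls": int(len(matrix)),
        "called": int((matrix["status"] == "called").sum()),
        "params": geno_params,
    }
    _log("genotype", calls=len(matrix))

    popgen_params = dict(config.get("popgen", {}))
    summary = summarize_all(
        matrix,
        mc_reps=int(popgen_params.get("mc_reps", DEFAULT_MC_REPS)),
        seed=int(config["seed"]),
        unbiased_he=bool(popgen_params.get("unbiased_he", False)),
    )
    summary_path = os.path.join(outdir, "locus_summary.tsv")
    summary.to_csv(summary_path, sep="\t", index=False)
    manifest["stages"]["popgen"] = {
        "loci": int((summary["locus"] != "Mean").sum()),
        "params": popgen_params,
    }
    _log("popgen", loci=manifest["stages"]["popgen"]["loci"])

    manifest["outputs"] = {
        "genotypes": matrix_path,
        "curation_report": report_path,
        "locus_summary": summary_path,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
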