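"""End-to-end pipeline: simulate (or load) counts -> normalize -> call ->
summarize -> plot, with a JSON manifest recording versions and parameters.

A pipeline configuration is a YAML file (or an equivalent dict) with either
a ``simulate`` section (a simulation config, see
:func:`gbskaryo.simulate.load_config`) or a ``counts`` section naming a
count matrix, sample sheet and genome on disk, plus optional ``loci`` and
``params`` (pseudo, min_control_cpm, ratio_floor, penalty, min_seg_bins)
and ``plots`` (list of sample names, or "all").

On a stage failure, outputs written so far are moved under ``failed/`` and
the error is re-raised with the stage name.
"""

from __future__ import annotations

import json
import shutil
import sys
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .caller import call_cohort, write_events, write_segments
from .counts import (
    read_count_matrix,
    read_samplesheet,
    write_count_matrix,
    write_samplesheet,
)
from .genome import make_bins, read_genome, read_loci, write_genome
from .normalize import normalize_counts, write_normalized
from .plotting import plot_genome
from .report import recovery_table, summarize, write_reports
from .simulate import demo_config, load_config, simulate_cohort, write_truth


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path) -> Path:
    """Execute the full pipeline and return the output directory."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        params = dict(config.get("params", {}))
        truth = None
        if "simulate" in config:
            stage = "simulate"
            sim_spec = config["simulate"]
            if sim_spec == "demo":
                sim_config = demo_config(seed=int(config.get("seed", 1)))
            elif isinstance(sim_spec, (str, Path)):
                sim_config = load_config(sim_spec)
            else:
                # inline simulation config: write out and reuse the loader
                tmp = out / "simulate.config.yaml"
                tmp.write_text(yaml.safe_dump(sim_spec))
                sim_config = load_config(tmp)
            genome = sim_config.genome
            matrix, sheet, truth = simulate_cohort(sim_config)
            write_genome(genome, out / "genome.tsv")
            write_count_matrix(matrix, out / "counts.tsv")
            write_samplesheet(sheet, out / "samplesheet.tsv")
            write_truth(truth, genome, out / "truth.events.tsv", out / "truth.summary.tsv")
            seed = sim_config.seed
        else:
            stage = "load"
            genome = read_genome(config["genome"])
            grid = make_bins(genome, int(config.get("bin_width", 1_000_000)))
            matrix = read_count_matrix(config["counts"], grid)
            sheet = read_samplesheet(config["samplesheet"])
            seed = None

        loci = read_loci(config["loci"], genome) if config.get("loci") else []

        stage = "normalize"
        norm = normalize_counts(
            matrix,
            sheet,
            pseudo=float(params.get("pseudo", 0.5)),
            ratio_floor=float(params.get("ratio_floor", -5.0)),
            min_control_cpm=float(params.get("min_control_cpm", 1.0)),
        )
        write_normalized(norm, out / "normalized.tsv")

        stage = "call"
        calls = call_cohort(
            norm,
            sheet,
            genome,
            penalty=params.get("penalty", "auto"),
            min_seg_bins=int(params.get("min_seg_bins", 3)),
        )
        write_segments(calls.segments, out / "segments.tsv")
        write_events(calls.events, out / "events.tsv")

        stage = "summarize"
        reports = summarize(calls, genome, sheet, loci)
        write_reports(reports, out / "reports")
        if truth is not None:
            recovery_table(reports, truth, genome).to_csv(
                out / "recovery.tsv", sep="\t", index=False
            )

        stage = "plot"
        plot_samples = config.get("plots", [])
        if plot_samples == "all":
            plot_samples = list(norm.samples)
        plots = out / "plots"
        if plot_samples:
            plots.mkdir(exist_ok=True)
        for sample in plot_samples:
            plot_genome(norm, sample, genome, plots / f"{sample}.png")

        stage = "manifest"
        manifest = {
            "gbskaryo_version": __version__,
            "python": sys.version.split()[0],
            "seed": seed,
            "penalty": calls.penalty,
            "params": params,
            "n_samples": len(norm.samples),
            "n_bins": norm.grid.n_bins,
            "bin_width": norm.grid.width,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(out.iterdir()):
            if item.name != "failed":
                shutil.move(str(item), str(failed / item.name))
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
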