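"""End-to-end workflows composing the pipeline stages.

Two compositions: image -> co-expression summary, and alignments ->
insertion report. Both are deterministic functions of (inputs, config,
seed) and embed their resolved configuration in every output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coexpression_stats import (
    CoexpressionSummary,
    background_rate,
    call_positive,
    count_puncta_per_nucleus,
    specificity_consistency,
)
from .insertion_locator import (
    cluster_insertion_loci,
    read_sam_pairs,
    single_insertion_verdict,
)
from .io import Manifest, RunConfig, read_fish_tiff, write_report
from .nucleus_segmentation import segment_nuclei
from .puncta_detection import detect_puncta
from .synthetic_data import FISHImage


def quantify_fish_image(
    image: FISHImage, manifest: Manifest, config: RunConfig | None = None
) -> tuple[pd.DataFrame, CoexpressionSummary]:
    """segment -> detect (per probe) -> count -> threshold -> call -> summarize."""
    cfg = config or RunConfig()
    manifest.validate(image)
    labels = segment_nuclei(image.channels[manifest.dapi_channel],
                            cfg.segmentation)
    puncta = {
        probe: detect_puncta(image.channels[probe], cfg.puncta, channel=probe)
        for probe in manifest.probe_channels()
    }
    profiles = count_puncta_per_nucleus(labels, puncta)
    rates = {probe: background_rate(pset, labels)
             for probe, pset in puncta.items()}
    called = call_positive(profiles, rates, cfg.percentile,
                           cfg.override_threshold or None)
    summary = specificity_consistency(
        called,
        cre_probe=manifest.cre_probe,
        target_probe=manifest.target_probe,
        offtarget_probe=manifest.offtarget_probe,
        region=manifest.region,
        genotype=manifest.line,
    )
    called.attrs["background_rates"] = rates
    return called, summary


def run_fish_pipeline(
    manifest: Manifest,
    config: RunConfig | None = None,
    out_dir: str | Path = ".",
    seed: int | None = None,
    timestamp: str | None = None,
) -> tuple[Path, Path]:
    """File-level FISH workflow: per-cell CSV + summary JSON on disk."""
    cfg = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = read_fish_tiff(manifest.image)
    called, summary = quantify_fish_image(image, manifest, cfg)

    cells_path = out_dir / f"{manifest.sample_id}_cells.csv"
    called.to_csv(cells_path)
    summary_path = out_dir / f"{manifest.sample_id}_summary.json"
    payload = {
        "sample": dataclasses.asdict(manifest),
        "summary": {
            "specificity_pct": summary.specificity,
            "consistency_pct": summary.consistency,
            "offtarget_specificity_pct": summary.offtarget_specificity,
            "offtarget_consistency_pct": summary.offtarget_consistency,
            "r2": {f"{a}~{b}": v for (a, b), v in summary.r2.items()},
            "n_cells": summary.n_cells,
        },
        "background_rates": called.attrs.get("background_rates", {}),
    }
    write_report(payload, summary_path, cfg, seed, timestamp)
    return cells_path, summary_path


def run_insertion_workflow(
    sam_path: str | Path,
    cassette_name: str,
    expected: tuple[str, int] | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path = ".",
    seed: int | None = None,
    timestamp: str | None = None,
) -> Path:
    """alignments -> anchored pairs -> loci -> verdict -> JSON report + BED."""
    from .io import write_loci_bed

    cfg = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = read_sam_pairs(str(sam_path), cassette_name, cfg.min_match)
    loci = cluster_insertion_loci(pairs, cfg.cluster_window)
    payload: dict = {
        "cassette": cassette_name,
        "n_anchored_pairs": len(pairs),
        "loci": [
            {
                "contig": l.contig,
                "position": l.position,
                "support": l.support,
                "span": l.span,
            }
            for l in loci
        ],
    }
    if expected is not None:
        verdict = single_insertion_verdict(loci, expected,
                                           cfg.verdict_tolerance)
        payload["verdict"] = {
            "passed": verdict.passed,
            "n_loci": verdict.n_loci,
            "expected_contig": expected[0],
            "expected_pos": expected[1],
            "off_site_loci": [
                {"contig": l.contig, "position": l.position,
                 "support": l.support}
                for l in verdict.off_site_loci
            ],
        }
    stem = Path(sam_path).stem
    report_path = out_dir / f"{stem}_insertion.json"
    write_report(payload, report_path, cfg, seed, timestamp)
    write_loci_bed(loci, out_dir / f"{stem}_loci.bed")
    return report_path
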