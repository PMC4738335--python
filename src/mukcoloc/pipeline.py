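"""Stage orchestration: deterministic artifact directories per analysis.

Each stage reads its inputs from a directory, writes its outputs plus the
exact resolved configuration and a JSON summary into the output directory,
and fails with a structured error naming the offending input or field.
Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import chipseq, cohesion, colocalization, io, repletion
from .config import RunConfig
from .errors import InvalidSpecError, MissingInputError
from .simulate import (
    SimChipSpec,
    SimImagingSpec,
    SimRepletionSpec,
    SimTimelapseSpec,
    generate_cells,
    generate_chipseq,
    generate_timelapse,
    render_images,
    simulate_repletion,
    truth_focus_table,
)

STAGES = ("simulate", "coloc", "cohesion", "repletion", "chip")


def _write_summary(outdir: Path, config: RunConfig, summary: dict) -> None:
    config.to_yaml(outdir / "config.yaml")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def run_pipeline(
    config: RunConfig, stage: str, indir: str | Path | None = None, outdir: str | Path = "out"
) -> Path:
    """Run one stage; returns the artifact directory."""
    config.validate()
    if stage not in STAGES:
        raise InvalidSpecError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(indir) if indir is not None else outdir
    handler = {
        "simulate": _stage_simulate,
        "coloc": _stage_coloc,
        "cohesion": _stage_cohesion,
        "repletion": _stage_repletion,
        "chip": _stage_chip,
    }[stage]
    handler(config, indir, outdir)
    return outdir


def _stage_simulate(config: RunConfig, indir: Path, outdir: Path) -> None:
    seed = config.seed
    cells, truth = generate_cells(SimImagingSpec(pixel_size_nm=config.pixel_size_nm, seed=seed))
    io.write_focus_table(truth_focus_table(truth), outdir / "foci.tsv")
    truth.to_csv(outdir / "imaging_truth.tsv", sep="\t", index=False)
    io.write_label_tiff(cells, outdir / "masks.tif")
    spec = SimImagingSpec(pixel_size_nm=config.pixel_size_nm, seed=seed)
    io.write_image_stack(render_images(cells, truth, spec), outdir / "images.tif")

    tracks, track_truth = generate_timelapse(
        SimTimelapseSpec(
            frame_interval_min=config.frame_interval_min,
            k_persist=config.k_persist,
            seed=seed + 1,
        )
    )
    io.write_tracks(tracks, outdir / "tracks.tsv")
    track_truth.to_csv(outdir / "timelapse_truth.tsv", sep="\t", index=False)

    rep_table = simulate_repletion(SimRepletionSpec(seed=seed + 2))
    rep_table.to_csv(outdir / "repletion_cells.tsv", sep="\t", index=False)

    length = 500_000  # compact synthetic chromosome for the smoke pipeline
    rng = np.random.default_rng(seed + 3)
    sites = tuple(np.sort(rng.choice(length // 1000, size=12, replace=False) * 1000 + 500))
    ip, mock, site_truth = generate_chipseq(
        SimChipSpec(
            genome_length_bp=length,
            bin_bp=config.chip_bin_bp,
            site_positions=sites,
            seed=seed + 3,
        )
    )
    for track in (*ip, *mock):
        io.write_bedgraph(track, outdir / f"{track.sample_id}.bedgraph")
    io.write_bed(
        site_truth.assign(
            chrom="synthetic_genome",
            start=site_truth["position_bp"],
            end=site_truth["position_bp"] + 13,
            name="planted_site",
            score=site_truth["fold"],
        ),
        outdir / "sites.bed",
    )
    _write_summary(
        outdir,
        config,
        {
            "stage": "simulate",
            "n_cells": len(cells),
            "n_tracks": len(tracks),
            "n_chip_sites": len(sites),
        },
    )


def _stage_coloc(config: RunConfig, indir: Path, outdir: Path) -> None:
    table = io.read_focus_table(indir / "foci.tsv")
    masks = indir / "masks.tif"
    result = colocalization.colocalization_fraction(
        table, "a", "b", config.coloc_threshold_nm, config.pixel_size_nm
    )
    summary = {
        "stage": "coloc",
        "n_cells_used": result.n_cells_used,
        "n_cells_total": result.n_cells_total,
        "percent_colocalized": result.percent_colocalized,
        "threshold_nm": result.threshold_nm,
    }
    if masks.exists():
        import tifffile

        cells = io.cells_from_label_image(tifffile.imread(str(masks)), config.pixel_size_nm)
        null, null_percent = colocalization.random_pixel_null(
            cells,
            table,
            "a",
            config.null_draws_per_cell,
            config.coloc_threshold_nm,
            config.pixel_size_nm,
            seed=config.seed,
        )
        summary["null_percent"] = null_percent
        colocalization.distance_ecdf(null).to_csv(
            outdir / "null_ecdf.tsv", sep="\t", index=False
        )
    colocalization.distance_ecdf(result.distances_nm).to_csv(
        outdir / "distance_ecdf.tsv", sep="\t", index=False
    )
    _write_summary(outdir, config, summary)


def _stage_cohesion(config: RunConfig, indir: Path, outdir: Path) -> None:
    tracks = io.read_tracks(indir / "tracks.tsv")
    params = cohesion.CohesionParams(
        config.k_persist, config.cohesion_offset_min, config.min_separation_px
    )
    calls = cohesion.score_tracks(tracks, params)
    cohesion.calls_to_frame(calls).to_csv(outdir / "cohesion_calls.tsv", sep="\t", index=False)
    curve = cohesion.population_segregation(calls)
    curve.to_frame().to_csv(outdir / "segregation_curve.tsv", sep="\t", index=False)
    _write_summary(
        outdir,
        config,
        {
            "stage": "cohesion",
            "n_tracks": len(tracks),
            "n_censored": curve.n_censored,
            "t50_min": curve.t50_min,
        },
    )


def _stage_repletion(config: RunConfig, indir: Path, outdir: Path) -> None:
    path = indir / "repletion_cells.tsv"
    if not path.exists():
        raise MissingInputError(f"repletion cell table not found: {path}")
    import pandas as pd

    series = repletion.build_timecourse(pd.read_csv(path, sep="\t"))
    series.to_csv(outdir / "timecourse.tsv", sep="\t", index=False)
    rates = {
        metric: repletion.fit_initial_rate(series, metric).slope_per_min
        for metric in ("brightest_pixel", "focus_fraction")
    }
    _write_summary(outdir, config, {"stage": "repletion", "initial_rates_per_min": rates})


def _stage_chip(config: RunConfig, indir: Path, outdir: Path) -> None:
    ip_paths = sorted(indir.glob("IP_*.bedgraph"))
    mock_paths = sorted(indir.glob("mock_*.bedgraph"))
    if not ip_paths or not mock_paths:
        raise MissingInputError(f"need IP_*.bedgraph and mock_*.bedgraph in {indir}")
    ip = [io.read_bedgraph(p, role="IP", replicate=i) for i, p in enumerate(ip_paths)]
    mock = [io.read_bedgraph(p, role="mock", replicate=i) for i, p in enumerate(mock_paths)]
    ratio = chipseq.median_ratio_track(ip, mock, config.chip_pseudocount)
    smoothed = chipseq.smooth_track(ratio, config.chip_window_bp)
    io.write_bedgraph(ratio, outdir / "enrichment.bedgraph")
    io.write_bedgraph(smoothed, outdir / "enrichment_smoothed.bedgraph")
    peaks = chipseq.call_top_peaks(smoothed, config.chip_top_n, config.chip_window_bp)
    io.write_bed(io.peaks_to_bed(peaks, ratio.reference, ratio.bin_bp), outdir / "peaks.bed")
    summary: dict = {
        "stage": "chip",
        "n_peaks": len(peaks),
        "genomewide_median_ratio": float(np.median(ratio.values)),
    }
    genome_path = indir / "genome.fasta"
    if genome_path.exists():
        genome = next(iter(io.read_fasta(genome_path).values()))
        hits = chipseq.scan_motif(genome, config.motif_consensus, config.motif_max_mismatch)
        hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        annotation = chipseq.annotate_peaks(
            peaks, hits, genome_length_bp=ratio.length_bp
        )
        annotation.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
        summary["n_peaks_at_motif"] = int(annotation["at_motif"].sum())
    if peaks:
        profile = chipseq.anchored_profile(
            smoothed, [p.position_bp for p in peaks], config.chip_window_bp
        )
        profile.to_csv(outdir / "anchored_profile.tsv", sep="\t", index=False)
        summary["profile_flatness"] = chipseq.profile_flatness(profile)
    _write_summary(outdir, config, summary)
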