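"""Readers and writers for the pipeline's interchange formats.

TSV is the lingua franca between stages; standard genomic formats (FASTA,
BED, bedGraph — 0-based half-open) sit at the domain boundaries, and TIFF
carries images and label masks.  Every writer's output is parseable by the
corresponding reader with lossless field values, and parse errors name the
offending line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .chipseq import CoverageTrack, EnrichmentTrack, Peak
from .cohesion import CellTrack
from .errors import MissingInputError, ParseError, SchemaError
from .imaging import CellRegion

FOCUS_COLUMNS = ["cell_id", "frame", "channel", "row", "col", "amplitude", "sd", "qc"]
TRACK_COLUMNS = ["cell_id", "frame", "time_min", "replisome_count", "locus_count"]


# ---------------------------------------------------------------- TSV tables

def write_focus_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FOCUS_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"focus table lacks column(s): {', '.join(missing)}")
    table[FOCUS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_focus_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"focus table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in FOCUS_COLUMNS[:5] if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: focus table lacks column(s): {', '.join(missing)}")
    return table


def write_tracks(tracks: Sequence[CellTrack], path: str | Path) -> None:
    rows = []
    for track in tracks:
        for j, t in enumerate(track.frame_times_min):
            rows.append(
                {
                    "cell_id": track.cell_id,
                    "frame": j,
                    "time_min": t,
                    "replisome_count": track.replisome_counts[j],
                    "locus_count": track.locus_counts[j],
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> list[CellTrack]:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"track table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: track table lacks column(s): {', '.join(missing)}")
    tracks = []
    for cell_id, group in table.groupby("cell_id"):
        group = group.sort_values("frame")
        tracks.append(
            CellTrack(
                int(cell_id),
                group["time_min"].to_numpy(),
                group["replisome_count"].to_numpy(),
                group["locus_count"].to_numpy(),
            )
        )
    return tracks


# ----------------------------------------------------------- genomic formats

def write_bedgraph(track: CoverageTrack | EnrichmentTrack, path: str | Path) -> None:
    """0-based half-open bedGraph; the last bin is clipped to the reference end."""
    values = track.counts if isinstance(track, CoverageTrack) else track.values
    with open(path, "w") as fh:
        for i, value in enumerate(values):
            start = i * track.bin_bp
            end = min(start + track.bin_bp, track.length_bp)
            fh.write(f"{track.reference}\t{start}\t{end}\t{value:.6g}\n")


def read_bedgraph(
    path: str | Path,
    sample_id: str = "",
    role: str = "IP",
    replicate: int = 0,
    circular: bool = True,
) -> CoverageTrack:
    """Parse a single-reference, uniformly binned bedGraph into a track."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"bedGraph not found: {path}")
    references, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path} line {lineno}: expected 4 tab-separated fields")
            try:
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
                values.append(float(parts[3]))
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from None
            references.append(parts[0])
    if not references:
        raise ParseError(f"{path}: no data lines")
    if len(set(references)) != 1:
        raise ParseError(f"{path}: multiple references; expected one")
    widths = {e - s for s, e in zip(starts, ends)}
    bin_bp = max(widths)  # the terminal bin may be clipped
    length_bp = max(ends)
    n_bins = -(-length_bp // bin_bp)
    counts = np.zeros(n_bins)
    counts[np.asarray(starts) // bin_bp] = values
    return CoverageTrack(
        references[0], length_bp, bin_bp, counts, sample_id or path.stem, role, replicate, circular
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a BED file from columns (chrom, start, end[, name[, score]])."""
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in intervals.columns]
    if cols[:3] != ["chrom", "start", "end"]:
        raise SchemaError("BED frame needs chrom, start, end columns")
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"BED not found: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path} line {lineno}: expected >= 3 fields")
            try:
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "name": parts[3] if len(parts) > 3 else "",
                        "score": float(parts[4]) if len(parts) > 4 else np.nan,
                    }
                )
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def peaks_to_bed(peaks: Sequence[Peak], reference: str, bin_bp: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": reference,
            "start": [int(p.position_bp - bin_bp / 2) for p in peaks],
            "end": [int(p.position_bp + bin_bp / 2) for p in peaks],
            "name": [f"peak_{p.rank}" for p in peaks],
            "score": [p.score for p in peaks],
        }
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"FASTA not found: {path}")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ------------------------------------------------------------------- images

def label_image(cells: Sequence[CellRegion], shape: tuple[int, int] | None = None) -> np.ndarray:
    """Render cells into a 16-bit label image (cell_id + 1; 0 = background)."""
    if shape is None:
        shape = (
            max(c.origin[0] + c.mask.shape[0] for c in cells) + 5,
            max(c.origin[1] + c.mask.shape[1] for c in cells) + 5,
        )
    labels = np.zeros(shape, np.uint16)
    for cell in cells:
        rows, cols = cell.frame_pixels()
        labels[rows, cols] = cell.cell_id + 1
    return labels


def cells_from_label_image(labels: np.ndarray, pixel_size_nm: float = 129.0) -> list[CellRegion]:
    """Recover CellRegions from a label image (labels are cell_id + 1)."""
    cells = []
    for label in np.unique(labels):
        if label == 0:
            continue
        rows, cols = np.nonzero(labels == label)
        origin = (int(rows.min()), int(cols.min()))
        mask = np.zeros((rows.max() - origin[0] + 1, cols.max() - origin[1] + 1), bool)
        mask[rows - origin[0], cols - origin[1]] = True
        cells.append(CellRegion(int(label) - 1, origin, mask, pixel_size_nm))
    return cells


def write_image_stack(channels: dict[str, np.ndarray], path: str | Path) -> None:
    """Channels as separate planes of one TIFF, in sorted channel order."""
    stack = np.stack([channels[k] for k in sorted(channels)]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"channels": sorted(channels)})


def read_image_stack(path: str | Path, channel_names: Sequence[str] | None = None):
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"TIFF not found: {path}")
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    names = list(channel_names) if channel_names else [f"ch{i}" for i in range(len(stack))]
    return {name: plane.astype(float) for name, plane in zip(names, stack)}


def write_label_tiff(cells: Sequence[CellRegion], path: str | Path, shape=None) -> None:
    tifffile.imwrite(path, label_image(cells, shape))
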