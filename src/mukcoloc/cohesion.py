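"""Sister-locus cohesion-time scoring from time-lapse focus tracks.

In time-lapse movies of replicating cells, the replisome (marked by the
sliding clamp DnaN) appears as a focus that vanishes when replication
terminates, and a fluorescently tagged chromosomal locus near the terminus
splits from one focus into two when the newly replicated sisters separate.
Because sister loci can transiently separate and re-associate while still
catenated, separation is only called *persistent* when the two foci remain
apart for K consecutive frames (default 3 frames at 5-min spacing).

The "cohesion time" of a cell is::

    cohesion = (segregation - replisome_end) + offset

with a default offset of 7 min compensating for the locus replicating ~2 min
before termination and the clamp taking ~5 min to unload.  The measured
interval may be negative (segregation before replisome disappearance);
cohesion times as short as ~2 min then arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidSpecError


@dataclass
class CohesionParams:
    """Scoring parameters.

    k_persist
        Number of consecutive separated frames required to call segregation
        (default 3).
    offset_min
        Constant added to the measured interval (default 7 min).
    min_separation_px
        Minimum inter-focus centroid distance for two foci to count as
        "separate" when centroid distances are available (default 2 px).
    """

    k_persist: int = 3
    offset_min: float = 7.0
    min_separation_px: float = 2.0

    def __post_init__(self) -> None:
        if self.k_persist < 1:
            raise InvalidSpecError("k_persist must be >= 1")
        if self.offset_min < 0:
            raise InvalidSpecError("offset_min must be >= 0")


@dataclass
class CellTrack:
    """Per-cell focus counts per channel across uniformly spaced frames."""

    cell_id: int
    frame_times_min: np.ndarray
    replisome_counts: np.ndarray
    locus_counts: np.ndarray
    locus_separation_px: np.ndarray | None = None  # inter-focus distance, NaN if <2 foci

    def __post_init__(self) -> None:
        self.frame_times_min = np.asarray(self.frame_times_min, float)
        self.replisome_counts = np.asarray(self.replisome_counts, int)
        self.locus_counts = np.asarray(self.locus_counts, int)
        t = self.frame_times_min
        if t.size < 2:
            raise InvalidSpecError(f"track {self.cell_id}: need >= 2 frames")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise InvalidSpecError(
                f"track {self.cell_id}: frame times must be strictly increasing and uniform"
            )
        for name in ("replisome_counts", "locus_counts"):
            arr = getattr(self, name)
            if arr.shape != t.shape:
                raise InvalidSpecError(f"track {self.cell_id}: {name} length mismatch")
            if np.any(arr < 0):
                raise InvalidSpecError(f"track {self.cell_id}: {name} must be >= 0")

    @property
    def dt_min(self) -> float:
        return float(self.frame_times_min[1] - self.frame_times_min[0])


@dataclass
class CohesionCall:
    """One scored cell; censored calls carry no cohesion time."""

    cell_id: int
    replisome_end_min: float | None
    segregation_min: float | None
    measured_interval_min: float | None
    cohesion_time_min: float | None
    censored: bool


def call_replisome_end(track: CellTrack) -> float | None:
    """Time of the first frame of the *terminal* focus-free run.

    Single-frame dropouts followed by reappearance do not end the replisome
    (focus blinking is common).  Returns ``None`` (censored) when the focus
    is still present in the last frame.
    """
    counts = track.replisome_counts
    if not counts.any():
        raise InvalidSpecError(f"track {track.cell_id}: replisome focus never present")
    if counts[-1] > 0:
        return None
    last_present = int(np.max(np.nonzero(counts > 0)))
    return float(track.frame_times_min[last_present + 1])


def _separation_flags(track: CellTrack, params: CohesionParams) -> np.ndarray:
    flags = track.locus_counts >= 2
    if track.locus_separation_px is not None:
        sep = np.asarray(track.locus_separation_px, float)
        flags = flags & (np.nan_to_num(sep, nan=0.0) >= params.min_separation_px)
    return flags


def call_segregation(track: CellTrack, params: CohesionParams | None = None) -> float | None:
    """Time of the first frame of the first run of ≥ K separated frames.

    Runs shorter than K are transient and ignored.  Returns ``None``
    (censored) when no qualifying run exists within the track.
    """
    params = params or CohesionParams()
    flags = _separation_flags(track, params)
    run = 0
    for i, flag in enumerate(flags):
        run = run + 1 if flag else 0
        if run >= params.k_persist:
            return float(track.frame_times_min[i - params.k_persist + 1])
    return None


def cohesion_time(track: CellTrack, params: CohesionParams | None = None) -> CohesionCall:
    """Score one cell: measured interval (may be negative) plus the offset."""
    params = params or CohesionParams()
    replisome_end = call_replisome_end(track)
    segregation = call_segregation(track, params)
    if replisome_end is None or segregation is None:
        return CohesionCall(track.cell_id, replisome_end, segregation, None, None, True)
    measured = segregation - replisome_end
    return CohesionCall(
        track.cell_id, replisome_end, segregation, measured, measured + params.offset_min, False
    )


def score_tracks(
    tracks: Iterable[CellTrack], params: CohesionParams | None = None
) -> list[CohesionCall]:
    params = params or CohesionParams()
    return [cohesion_time(t, params) for t in tracks]


@dataclass
class SegregationCurve:
    """Cumulative fraction segregated vs cohesion time (step curve)."""

    times_min: np.ndarray
    cumulative_fraction: np.ndarray
    t50_min: float | None
    n_used: int
    n_censored: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cohesion_time_min": self.times_min, "cumulative_fraction": self.cumulative_fraction}
        )


def population_segregation(
    calls: Sequence[CohesionCall], censored_as_unsegregated: bool = False
) -> SegregationCurve:
    """Population step curve and the first time ≥50% of loci have segregated.

    Censored cells are excluded from the denominator by default; with
    ``censored_as_unsegregated=True`` they enter the denominator as
    never-segregating, which can leave t50 undefined.
    """
    uncensored = sorted(c.cohesion_time_min for c in calls if not c.censored)
    n_censored = sum(c.censored for c in calls)
    if not uncensored:
        raise EmptyResultError("all cells censored; no segregation curve")
    denominator = len(uncensored) + (n_censored if censored_as_unsegregated else 0)
    times, counts = np.unique(np.asarray(uncensored, float), return_counts=True)
    cumulative = np.cumsum(counts) / denominator
    reached = np.nonzero(cumulative >= 0.5)[0]
    t50 = float(times[reached[0]]) if reached.size else None
    return SegregationCurve(times, cumulative, t50, len(uncensored), int(n_censored))


def calls_to_frame(calls: Sequence[CohesionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "replisome_end_min": [c.replisome_end_min for c in calls],
            "segregation_min": [c.segregation_min for c in calls],
            "measured_interval_min": [c.measured_interval_min for c in calls],
            "cohesion_time_min": [c.cohesion_time_min for c in calls],
            "censored": [c.censored for c in calls],
        }
    )
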