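"""Synthetic time-lapse tracks: replisome disappearance and sister-locus splitting.

Per cell, a continuous replisome-end time is drawn; the replisome focus is
present at every frame strictly before that time (with occasional blink
dropouts) and absent from the first frame at or after it.  The locus splits
persistently at the replisome-end time plus a decatenation delay (which may
be negative — the locus replicates before clamp unloading completes).
Transient separations (before the persistent split) and transient re-merges
(after it) are planted as runs strictly shorter than the persistence length
K, placed so that the truth label is unambiguous: a cohesive frame always
precedes the persistent split, and re-merges begin only after the first K
separated frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidSpecError
from ..cohesion import CellTrack

#: distributions accepted for spec fields: a float (constant) or a tuple
#: ("uniform", lo, hi) | ("normal", mu, sd) | ("exponential", scale)
Distribution = float | tuple


def _draw(dist: Distribution, rng: np.random.Generator) -> float:
    if isinstance(dist, (int, float)):
        return float(dist)
    name, *params = dist
    if name == "uniform":
        return float(rng.uniform(*params))
    if name == "normal":
        return float(rng.normal(*params))
    if name == "exponential":
        return float(rng.exponential(*params))
    raise InvalidSpecError(f"unknown distribution {name!r}")


@dataclass
class SimTimelapseSpec:
    """Study conditions for the time-lapse generator.

    Defaults emulate imaging every 5 min for 2 h (24 frames) of an
    asynchronous population whose replication terminations fall mid-movie,
    with a 2-min decatenation delay (the wild-type condition).
    """

    n_cells: int = 50
    frame_interval_min: float = 5.0
    n_frames: int = 24
    replisome_end_time: Distribution = ("uniform", 20.0, 60.0)
    decatenation_delay_min: Distribution = 2.0
    transient_split_prob: float = 0.10
    transient_merge_prob: float = 0.10
    replisome_dropout_prob: float = 0.03
    k_persist: int = 3  # transient runs are capped strictly below this
    seed: int = 0

    def validate(self) -> None:
        if self.frame_interval_min <= 0:
            raise InvalidSpecError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise InvalidSpecError("n_frames must be >= 2")
        if self.k_persist < 1:
            raise InvalidSpecError("k_persist must be >= 1")
        for name in ("transient_split_prob", "transient_merge_prob", "replisome_dropout_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidSpecError(f"{name} must be in [0, 1]")


def _transient_run_length(rng: np.random.Generator, p_continue: float, cap: int) -> int:
    """Geometric run length (>=1), capped strictly below the persistence length."""
    length = 1
    while length < cap and rng.random() < p_continue:
        length += 1
    return length


def generate_timelapse(spec: SimTimelapseSpec) -> tuple[list[CellTrack], pd.DataFrame]:
    """Generate per-cell tracks plus a truth table of planted event times.

    Truth columns: the continuous replisome-end and split times, their
    frame-quantized counterparts (first frame at/after the event), the
    planted delay, and censoring flags for events falling beyond the movie.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x3C]))
    dt = spec.frame_interval_min
    times = np.arange(spec.n_frames) * dt
    cap = spec.k_persist - 1
    tracks: list[CellTrack] = []
    records = []
    for i in range(spec.n_cells):
        t_end = _draw(spec.replisome_end_time, rng)
        delay = _draw(spec.decatenation_delay_min, rng)
        t_split = t_end + delay
        f_end = int(np.ceil(t_end / dt))  # first focus-free frame
        f_split = max(int(np.ceil(t_split / dt)), 0)

        replisome = (times < t_end).astype(int)
        # blink dropouts: never frame 0, the last frame, or the frame
        # preceding the terminal absence run
        for j in range(1, min(f_end - 1, spec.n_frames - 1)):
            if rng.random() < spec.replisome_dropout_prob:
                replisome[j] = 0

        locus = np.where(np.arange(spec.n_frames) >= f_split, 2, 1)

        # transient separations: runs < K, each followed by >=1 cohesive frame
        if cap >= 1 and spec.transient_split_prob > 0:
            j = 0
            while j < f_split - 1:
                if locus[j] == 1 and rng.random() < spec.transient_split_prob:
                    run = _transient_run_length(rng, spec.transient_split_prob, cap)
                    run = min(run, f_split - 1 - j)  # leave a cohesive frame before the split
                    locus[j : j + run] = 2
                    j += run + 1  # the +1 keeps the following frame cohesive
                else:
                    j += 1
        # transient re-merges: only after the first K separated frames
        if cap >= 1 and spec.transient_merge_prob > 0:
            j = f_split + spec.k_persist
            while j < spec.n_frames:
                if rng.random() < spec.transient_merge_prob:
                    run = _transient_run_length(rng, spec.transient_merge_prob, cap)
                    run = min(run, spec.n_frames - j)
                    locus[j : j + run] = 1
                    j += run + 1
                else:
                    j += 1

        tracks.append(CellTrack(i, times, replisome, locus))
        records.append(
            {
                "cell_id": i,
                "t_replisome_end_min": t_end,
                "t_split_min": t_split,
                "delay_min": delay,
                "replisome_end_frame_min": f_end * dt,
                "split_frame_min": f_split * dt,
                "replisome_censored": f_end >= spec.n_frames,
                "split_censored": f_split > spec.n_frames - spec.k_persist,
            }
        )
    return tracks, pd.DataFrame(records)
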