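"""IP/mock enrichment tracks, top-N peaks, motif scanning and anchored profiles.

The enrichment statistic is the per-bin ratio of the *median* normalized
coverage across immunoprecipitation (IP) replicates to the median across
mock replicates from an untagged strain — median first, then ratio.  Tracks
are binned (50 bp by default), normalized to counts per million, and the
ratio is stabilized with a small pseudocount.  A centred moving average
(2 kb by default, wrapping across the origin of a circular chromosome)
produces the display/peak-calling track.

Downstream operations: greedy top-N peak calling with exclusion zones,
degenerate-consensus motif scanning on both strands (for 13-bp matS-like
sites), peak↔motif annotation, and metagene-style profiles anchored at a
peak set — used e.g. to compare the enrichment of different protein variants
at the same anchor positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import InvalidSpecError, SchemaError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(pattern: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise InvalidSpecError(f"invalid IUPAC code {exc.args[0]!r} in pattern") from None


@dataclass
class CoverageTrack:
    """Binned read counts for one sample on one reference."""

    reference: str
    length_bp: int
    bin_bp: int
    counts: np.ndarray
    sample_id: str = ""
    role: str = "IP"  # or "mock"
    replicate: int = 0
    circular: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        expected = -(-self.length_bp // self.bin_bp)  # ceil division
        if self.counts.shape != (expected,):
            raise InvalidSpecError(
                f"track {self.sample_id!r}: expected {expected} bins "
                f"(length {self.length_bp}, bin {self.bin_bp}), got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise InvalidSpecError(f"track {self.sample_id!r}: negative counts")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def bin_centers_bp(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_bp + self.bin_bp / 2.0


@dataclass
class EnrichmentTrack:
    """Per-bin IP/mock ratio-of-medians with its provenance metadata."""

    reference: str
    length_bp: int
    bin_bp: int
    values: np.ndarray
    pseudocount: float
    circular: bool = True
    smoothed_window_bp: int | None = None
    ip_samples: tuple[str, ...] = ()
    mock_samples: tuple[str, ...] = ()

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_centers_bp(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_bp + self.bin_bp / 2.0


@dataclass
class Peak:
    position_bp: float
    score: float
    rank: int


def normalize_coverage(
    tracks: Sequence[CoverageTrack], scale: float = 1e6
) -> tuple[list[CoverageTrack], dict[str, float]]:
    """Scale each track to counts-per-``scale`` of its library total.

    Returns the normalized tracks and a log of the per-sample scaling
    factors.  A zero-total track is an error, never silently all-zero.
    """
    normalized, factors = [], {}
    for track in tracks:
        total = float(track.counts.sum())
        if total <= 0:
            raise InvalidSpecError(f"track {track.sample_id!r} has zero total counts")
        factor = scale / total
        factors[track.sample_id] = factor
        normalized.append(
            CoverageTrack(
                track.reference, track.length_bp, track.bin_bp, track.counts * factor,
                track.sample_id, track.role, track.replicate, track.circular,
            )
        )
    return normalized, factors


def median_ratio_track(
    ip_tracks: Sequence[CoverageTrack],
    mock_tracks: Sequence[CoverageTrack],
    pseudocount: float = 0.5,
    normalize: bool = True,
) -> EnrichmentTrack:
    """Per-bin (median IP + ε) / (median mock + ε) on normalized counts."""
    if not ip_tracks or not mock_tracks:
        raise InvalidSpecError("need >= 1 replicate per role (IP and mock)")
    ref = ip_tracks[0]
    for track in (*ip_tracks, *mock_tracks):
        if (track.n_bins, track.bin_bp) != (ref.n_bins, ref.bin_bp):
            raise InvalidSpecError(
                f"track {track.sample_id!r}: bin layout mismatch "
                f"({track.n_bins}x{track.bin_bp} vs {ref.n_bins}x{ref.bin_bp})"
            )
    if normalize:
        ip_tracks, _ = normalize_coverage(ip_tracks)
        mock_tracks, _ = normalize_coverage(mock_tracks)
    ip_median = np.median(np.stack([t.counts for t in ip_tracks]), axis=0)
    mock_median = np.median(np.stack([t.counts for t in mock_tracks]), axis=0)
    values = (ip_median + pseudocount) / (mock_median + pseudocount)
    return EnrichmentTrack(
        ref.reference, ref.length_bp, ref.bin_bp, values, pseudocount, ref.circular,
        ip_samples=tuple(t.sample_id for t in ip_tracks),
        mock_samples=tuple(t.sample_id for t in mock_tracks),
    )


def smooth_track(track: EnrichmentTrack, window_bp: int = 2000) -> EnrichmentTrack:
    """Centred moving average; wraps across the origin when circular."""
    if window_bp < track.bin_bp:
        raise InvalidSpecError(f"smoothing window {window_bp} bp < bin size {track.bin_bp} bp")
    size = max(int(round(window_bp / track.bin_bp)), 1)
    mode = "wrap" if track.circular else "nearest"
    smoothed = uniform_filter1d(track.values, size=size, mode=mode)
    return EnrichmentTrack(
        track.reference, track.length_bp, track.bin_bp, smoothed, track.pseudocount,
        track.circular, smoothed_window_bp=window_bp,
        ip_samples=track.ip_samples, mock_samples=track.mock_samples,
    )


def call_top_peaks(
    enrichment: EnrichmentTrack,
    n: int = 26,
    min_separation_bp: int = 2000,
    refine_with: EnrichmentTrack | None = None,
) -> list[Peak]:
    """Greedy top-N local maxima with exclusion zones.

    Local maxima (circular neighbours when the reference is circular) are
    ranked by descending score; each accepted peak excludes further peaks
    within ``min_separation_bp``.  Returns at most ``n`` peaks — a flat
    track yields a short list, never padding.

    Smoothing a site narrower than the window produces a plateau whose
    argmax is arbitrary within ~half a window; passing the *unsmoothed*
    ratio as ``refine_with`` snaps each peak position to the raw maximum
    within ±``min_separation_bp``/2 of the smoothed one (score is kept from
    the ranking track).
    """
    v = enrichment.values
    if enrichment.circular:
        left, right = np.roll(v, 1), np.roll(v, -1)
        is_max = (v > left) & (v >= right)
    else:
        left = np.r_[np.inf, v[:-1]]
        right = np.r_[v[1:], np.inf]
        is_max = (v > left) & (v >= right)
    candidates = np.nonzero(is_max)[0]
    order = candidates[np.argsort(-v[candidates], kind="stable")]
    centers = enrichment.bin_centers_bp()
    length = enrichment.length_bp
    peaks: list[Peak] = []
    taken: list[float] = []
    for idx in order:
        pos = centers[idx]
        if enrichment.circular:
            clear = all(min(abs(pos - p), length - abs(pos - p)) >= min_separation_bp for p in taken)
        else:
            clear = all(abs(pos - p) >= min_separation_bp for p in taken)
        if clear:
            pos_refined = pos
            if refine_with is not None:
                half = max(int((min_separation_bp / 2) // refine_with.bin_bp), 1)
                window = np.arange(idx - half, idx + half + 1)
                if refine_with.circular:
                    local = refine_with.values.take(window, mode="wrap")
                else:
                    window = window[(window >= 0) & (window < refine_with.n_bins)]
                    local = refine_with.values[window]
                best = window[int(np.argmax(local))] % refine_with.n_bins
                pos_refined = float(refine_with.bin_centers_bp()[best])
            peaks.append(Peak(float(pos_refined), float(v[idx]), len(peaks) + 1))
            taken.append(pos)
            if len(peaks) == n:
                break
    return peaks


@dataclass
class MotifHit:
    start: int
    strand: str
    mismatches: int
    sequence: str


def _mismatch_profile(seq_array: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` at every start position (vectorized)."""
    m = len(pattern)
    n_pos = seq_array.size - m + 1
    if n_pos <= 0:
        return np.empty(0, np.int16)
    mismatches = np.zeros(n_pos, np.int16)
    for j, code in enumerate(pattern):
        allowed = np.frombuffer(IUPAC[code].encode(), dtype="S1")
        mismatches += ~np.isin(seq_array[j : j + n_pos], allowed)
    return mismatches


def scan_motif(genome: str, consensus: str, max_mismatch: int = 1) -> pd.DataFrame:
    """Scan both strands for a degenerate IUPAC consensus.

    Characters outside ACGT in the genome are masked (they never match).  A
    palindromic consensus matching at the same start on both strands is
    collapsed to a single hit (forward strand reported).  Returns a
    DataFrame with columns ``start, strand, mismatches, sequence`` sorted by
    start.
    """
    consensus = consensus.upper()
    for code in consensus:
        if code not in IUPAC:
            raise InvalidSpecError(f"invalid IUPAC code {code!r} in consensus")
    seq = genome.upper()
    arr = np.frombuffer(seq.encode(), dtype="S1")
    m = len(consensus)
    hits: dict[int, tuple[str, int]] = {}
    for strand, pattern in (("+", consensus), ("-", reverse_complement(consensus))):
        mm = _mismatch_profile(arr, pattern)
        for start in np.nonzero(mm <= max_mismatch)[0]:
            start = int(start)
            record = (strand, int(mm[start]))
            prev = hits.get(start)
            if prev is None or record[1] < prev[1]:  # keep best; '+' scanned first
                hits[start] = record
    rows = [
        {"start": s, "strand": st, "mismatches": n_mm, "sequence": seq[s : s + m]}
        for s, (st, n_mm) in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["start", "strand", "mismatches", "sequence"])


def annotate_peaks(
    peaks: Sequence[Peak],
    motif_hits: pd.DataFrame,
    tolerance_bp: int = 500,
    genome_length_bp: int | None = None,
    exclude_positions: Sequence[float] = (),
    exclude_tolerance_bp: int = 500,
) -> pd.DataFrame:
    """Label each peak with its nearest motif hit within ``tolerance_bp``.

    ``exclude_positions`` removes known sites from consideration before
    matching (e.g. a site that shows no enrichment and is left out of the
    analysis).  Distances wrap when ``genome_length_bp`` is given (circular
    chromosome).  The summary count of peaks-at-motif is
    ``result["at_motif"].sum()``.
    """
    if "start" not in motif_hits.columns:
        raise SchemaError("motif_hits must have a 'start' column")
    starts = motif_hits["start"].to_numpy(float)
    if len(exclude_positions):
        keep = np.ones(starts.size, bool)
        for pos in exclude_positions:
            keep &= _distance(starts, pos, genome_length_bp) > exclude_tolerance_bp
        starts = starts[keep]
    records = []
    for peak in peaks:
        if starts.size:
            d = _distance(starts, peak.position_bp, genome_length_bp)
            i = int(np.argmin(d))
            at_motif = bool(d[i] <= tolerance_bp)
            nearest = float(starts[i]) if at_motif else np.nan
            dist = float(d[i]) if at_motif else np.nan
        else:
            at_motif, nearest, dist = False, np.nan, np.nan
        records.append(
            {
                "rank": peak.rank,
                "position_bp": peak.position_bp,
                "score": peak.score,
                "at_motif": at_motif,
                "motif_start": nearest,
                "distance_bp": dist,
            }
        )
    return pd.DataFrame(records)


def _distance(positions: np.ndarray, point: float, length: int | None) -> np.ndarray:
    d = np.abs(positions - point)
    if length is not None:
        d = np.minimum(d, length - d)
    return d


def anchored_profile(
    enrichment: EnrichmentTrack,
    anchors_bp: Sequence[float],
    half_window_bp: int = 2000,
    stat: str = "median",
) -> pd.DataFrame:
    """Across-anchor profile of enrichment around a set of anchor positions.

    Windows of ±``half_window_bp`` are extracted around each anchor, aligned
    by anchor centre, and summarized per offset with the across-anchor
    median (or mean).  On a circular reference windows wrap; on a linear one
    they are trimmed (missing bins ignored in the summary).
    """
    if not len(anchors_bp):
        raise InvalidSpecError("anchors_bp must be non-empty")
    if stat not in ("median", "mean"):
        raise InvalidSpecError("stat must be 'median' or 'mean'")
    nw = int(half_window_bp // enrichment.bin_bp)
    offsets = np.arange(-nw, nw + 1)
    rows = []
    for anchor in anchors_bp:
        center = int(anchor // enrichment.bin_bp)
        idx = center + offsets
        if enrichment.circular:
            rows.append(enrichment.values.take(idx, mode="wrap"))
        else:
            vals = np.full(idx.shape, np.nan)
            ok = (idx >= 0) & (idx < enrichment.n_bins)
            vals[ok] = enrichment.values[idx[ok]]
            rows.append(vals)
    stack = np.vstack(rows)
    summarize = np.nanmedian if stat == "median" else np.nanmean
    return pd.DataFrame(
        {"offset_bp": offsets * enrichment.bin_bp, "value": summarize(stack, axis=0)}
    )


def profile_fold_change(profile_num: pd.DataFrame, profile_den: pd.DataFrame) -> float:
    """Ratio of centred peak heights (profile maxima) between two conditions."""
    return float(profile_num["value"].max() / profile_den["value"].max())


def profile_flatness(profile: pd.DataFrame) -> float:
    """max/median over the window; ~1 for a profile with no real enrichment."""
    return float(profile["value"].max() / profile["value"].median())


def fragments_to_coverage(
    fragments: Iterable[tuple[int, int]],
    reference: str,
    length_bp: int,
    bin_bp: int = 50,
    sample_id: str = "",
    role: str = "IP",
    replicate: int = 0,
    circular: bool = True,
) -> CoverageTrack:
    """Helper: midpoint-count mapped fragment intervals into a binned track."""
    n_bins = -(-length_bp // bin_bp)
    counts = np.zeros(n_bins)
    for start, end in fragments:
        mid = ((start + end) // 2) % length_bp
        counts[mid // bin_bp] += 1
    return CoverageTrack(reference, length_bp, bin_bp, counts, sample_id, role, replicate, circular)
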