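"""Synthetic ChIP-seq coverage: replicated IP/mock tracks with planted sites.

Per-bin counts are drawn from a negative binomial whose mean is a
depth-proportional baseline times a local fold: planted sites raise the IP
mean within ±2 bins, while highly-transcribed-region (HTR) artifacts raise
IP *and* mock alike (formaldehyde-reactive regions give signal in every
sample, tagged or not, and cancel in the IP/mock ratio).  Replicates differ
by a sampled library-size factor.  A companion generator plants exact motif
instances into a random genome sequence for motif-scanning tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ..chipseq import IUPAC, CoverageTrack
from ..errors import InvalidSpecError


@dataclass
class SimChipSpec:
    """Study conditions for the coverage generator.

    Defaults: an MG1655-sized circular genome in 50-bp bins, three IP and
    three mock replicates at 1e6 reads each, negative-binomial dispersion 50
    (moderate replicate overdispersion), library-size factors lognormal with
    sd 0.1.  ``site_enrichment`` is a single fold or one fold per site.
    """

    genome_length_bp: int = 4_641_652
    bin_bp: int = 50
    site_positions: tuple[int, ...] = ()
    site_enrichment: float | tuple[float, ...] = 8.0
    site_halfwidth_bins: int = 2
    n_replicates: int = 3
    read_depth: float = 1e6
    dispersion: float = 50.0
    htr_artifacts: tuple[tuple[int, int, float], ...] = ()  # (start, end, fold)
    libsize_log_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length_bp <= 0 or self.bin_bp <= 0:
            raise InvalidSpecError("genome_length_bp and bin_bp must be > 0")
        if self.n_replicates < 1:
            raise InvalidSpecError("n_replicates must be >= 1")
        if self.dispersion <= 0:
            raise InvalidSpecError("dispersion must be > 0")
        folds = self.site_folds()
        if np.any(folds < 1):
            raise InvalidSpecError("site_enrichment folds must be >= 1")
        positions = np.asarray(self.site_positions, int)
        if positions.size and (positions.min() < 0 or positions.max() >= self.genome_length_bp):
            raise InvalidSpecError("site_positions must lie in [0, genome_length_bp)")
        bins = np.sort(positions // self.bin_bp)
        if bins.size > 1 and np.min(np.diff(bins)) < 2:
            raise InvalidSpecError("planted sites closer than 2 bins overlap; spread them out")
        for start, end, fold in self.htr_artifacts:
            if not 0 <= start < end <= self.genome_length_bp:
                raise InvalidSpecError(f"htr interval ({start}, {end}) outside the genome")
            if fold < 1:
                raise InvalidSpecError("htr folds must be >= 1")

    @property
    def n_bins(self) -> int:
        return -(-self.genome_length_bp // self.bin_bp)

    def site_folds(self) -> np.ndarray:
        if isinstance(self.site_enrichment, (int, float)):
            return np.full(len(self.site_positions), float(self.site_enrichment))
        folds = np.asarray(self.site_enrichment, float)
        if folds.size != len(self.site_positions):
            raise InvalidSpecError("site_enrichment length must match site_positions")
        return folds


def _fold_profiles(spec: SimChipSpec) -> tuple[np.ndarray, np.ndarray]:
    """(IP fold per bin, mock fold per bin); overlapping windows take the max."""
    ip_fold = np.ones(spec.n_bins)
    hw = spec.site_halfwidth_bins
    for pos, fold in zip(spec.site_positions, spec.site_folds()):
        center = pos // spec.bin_bp
        idx = (np.arange(center - hw, center + hw + 1)) % spec.n_bins
        ip_fold[idx] = np.maximum(ip_fold[idx], fold)
    shared = np.ones(spec.n_bins)
    for start, end, fold in spec.htr_artifacts:
        lo, hi = start // spec.bin_bp, -(-end // spec.bin_bp)
        shared[lo:hi] = np.maximum(shared[lo:hi], fold)
    return ip_fold * shared, shared


def _sample_track(
    rng: np.random.Generator, spec: SimChipSpec, fold: np.ndarray, role: str, replicate: int
) -> CoverageTrack:
    libfactor = float(np.exp(rng.normal(0.0, spec.libsize_log_sd)))
    mean = spec.read_depth / spec.n_bins * fold * libfactor
    p = spec.dispersion / (spec.dispersion + mean)
    counts = rng.negative_binomial(spec.dispersion, p)
    return CoverageTrack(
        "synthetic_genome",
        spec.genome_length_bp,
        spec.bin_bp,
        counts.astype(float),
        sample_id=f"{role}_rep{replicate}",
        role=role,
        replicate=replicate,
        circular=True,
    )


def generate_chipseq(
    spec: SimChipSpec,
) -> tuple[list[CoverageTrack], list[CoverageTrack], pd.DataFrame]:
    """IP replicates, mock replicates, and a truth table of planted sites."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x4D]))
    ip_fold, mock_fold = _fold_profiles(spec)
    ip = [_sample_track(rng, spec, ip_fold, "IP", r) for r in range(spec.n_replicates)]
    mock = [_sample_track(rng, spec, mock_fold, "mock", r) for r in range(spec.n_replicates)]
    truth = pd.DataFrame(
        {
            "position_bp": list(spec.site_positions),
            "bin": [p // spec.bin_bp for p in spec.site_positions],
            "fold": spec.site_folds(),
        }
    )
    return ip, mock, truth


def generate_genome_with_sites(
    length_bp: int,
    site_positions: Sequence[int],
    consensus: str,
    seed: int = 0,
    gc: float = 0.5,
) -> str:
    """Random ACGT sequence with exact consensus instances planted.

    Degenerate consensus positions are resolved uniformly among their
    allowed bases per site.  Sites must not overlap.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype="S1"), size=length_bp, p=[p_at, p_gc, p_gc, p_at]
    ).copy()
    positions = sorted(int(p) for p in site_positions)
    m = len(consensus)
    for prev, cur in zip(positions, positions[1:]):
        if cur - prev < m:
            raise InvalidSpecError("planted motif sites overlap")
    for pos in positions:
        if pos < 0 or pos + m > length_bp:
            raise InvalidSpecError(f"site at {pos} does not fit in the genome")
        for j, code in enumerate(consensus.upper()):
            allowed = IUPAC[code]
            bases[pos + j] = allowed[rng.integers(0, len(allowed))].encode()
    return bases.tobytes().decode()
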