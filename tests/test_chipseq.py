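"""Enrichment ratios, smoothing, peak calling, motif scanning, profiles."""

import numpy as np
import pandas as pd
import pytest

from mukcoloc import chipseq as ch
from mukcoloc.errors import InvalidSpecError
from mukcoloc.simulate import SimChipSpec, generate_chipseq, generate_genome_with_sites

CONSENSUS = "GTGACRNYGTCAC"


def _track(values, bin_bp=50, circular=True, role="IP", rep=0):
    values = np.asarray(values, float)
    return ch.CoverageTrack(
        "chr", len(values) * bin_bp, bin_bp, values, f"{role}{rep}", role, rep, circular
    )


def brute_force_scan(genome, consensus, max_mismatch):
    """Position-by-position oracle, independent of the vectorized scanner."""
    seq = genome.upper()
    m = len(consensus)
    hits = {}
    for strand, pattern in (("+", consensus), ("-", ch.reverse_complement(consensus))):
        for start in range(len(seq) - m + 1):
            mismatches = 0
            for base, code in zip(seq[start : start + m], pattern):
                if base not in ch.IUPAC[code]:
                    mismatches += 1
                    if mismatches > max_mismatch:
                        break
            else:
                prev = hits.get(start)
                if prev is None or mismatches < prev[1]:
                    hits[start] = (strand, mismatches)
    return {(s, st, mm) for s, (st, mm) in hits.items()}


class TestNormalization:
    def test_counts_per_million_arithmetic(self):
        track = _track(np.full(10_000, 200.0))  # total 2e6
        normalized, factors = ch.normalize_coverage([track])
        assert np.allclose(normalized[0].counts, 100.0)
        assert factors["IP0"] == pytest.approx(0.5)

    def test_global_factor_removed(self):
        a = _track(np.arange(1, 101, dtype=float))
        b = _track(2.0 * np.arange(1, 101, dtype=float), rep=1)
        normalized, _ = ch.normalize_coverage([a, b])
        assert np.allclose(normalized[0].counts, normalized[1].counts)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidSpecError):
            ch.normalize_coverage([_track(np.zeros(10))])

    def test_sampled_library_factors_cancel(self):
        spec = SimChipSpec(genome_length_bp=400_000, read_depth=2e6, libsize_log_sd=0.3, seed=2)
        ip, _, _ = generate_chipseq(spec)
        normalized, _ = ch.normalize_coverage(ip)
        means = [t.counts.mean() for t in normalized]
        assert max(means) / min(means) == pytest.approx(1.0, abs=0.02)


class TestMedianRatio:
    def test_identical_tracks_give_unit_ratio(self):
        tracks = [_track(np.full(100, 7.0), rep=i) for i in range(3)]
        mocks = [_track(np.full(100, 7.0), role="mock", rep=i) for i in range(3)]
        ratio = ch.median_ratio_track(tracks, mocks)
        assert np.allclose(ratio.values, 1.0)

    def test_hand_median_arithmetic(self):
        ip = [_track([10.0]), _track([12.0], rep=1), _track([14.0], rep=2)]
        mock = [_track([5.0], role="mock"), _track([6.0], role="mock", rep=1),
                _track([7.0], role="mock", rep=2)]
        ratio = ch.median_ratio_track(ip, mock, pseudocount=0.0, normalize=False)
        assert ratio.values[0] == pytest.approx(12.0 / 6.0)

    def test_bin_layout_mismatch_rejected(self):
        with pytest.raises(InvalidSpecError):
            ch.median_ratio_track([_track(np.ones(10))], [_track(np.ones(20), role="mock")])

    def test_planted_fold_visible_at_site(self):
        """Ratio at a fold-8 site bin lands in [6.5, 9.5], typical across seeds."""
        values = []
        for seed in range(5):
            spec = SimChipSpec(
                genome_length_bp=500_000, site_positions=(250_025,), site_enrichment=8.0,
                read_depth=5e6, seed=seed,
            )
            ip, mock, truth = generate_chipseq(spec)
            ratio = ch.median_ratio_track(ip, mock)
            values.append(ratio.values[int(truth["bin"].iloc[0])])
        assert 6.5 <= np.median(values) <= 9.5


class TestSmoothing:
    def test_constant_track_unchanged(self):
        enr = ch.EnrichmentTrack("chr", 5000, 50, np.full(100, 3.0), 0.5)
        assert np.allclose(ch.smooth_track(enr, 2000).values, 3.0)

    def test_impulse_spread_over_window_bins(self):
        values = np.zeros(200)
        values[100] = 1.0
        enr = ch.EnrichmentTrack("chr", 10_000, 50, values, 0.5)
        smoothed = ch.smooth_track(enr, 2000).values
        assert np.count_nonzero(smoothed) == 40
        assert smoothed[smoothed > 0] == pytest.approx(1.0 / 40.0)

    def test_circular_wrap_at_origin(self):
        values = np.zeros(200)
        values[0] = 1.0
        enr = ch.EnrichmentTrack("chr", 10_000, 50, values, 0.5, circular=True)
        smoothed = ch.smooth_track(enr, 2000).values
        assert smoothed[-1] > 0  # impulse at bin 0 bleeds into terminal bins

    def test_mass_conserved_in_circular_mode(self, rng):
        values = rng.gamma(2.0, 1.0, 500)
        enr = ch.EnrichmentTrack("chr", 25_000, 50, values, 0.5, circular=True)
        smoothed = ch.smooth_track(enr, 2000).values
        assert smoothed.sum() == pytest.approx(values.sum(), rel=1e-9)

    def test_window_below_bin_rejected(self):
        enr = ch.EnrichmentTrack("chr", 5000, 50, np.ones(100), 0.5)
        with pytest.raises(InvalidSpecError):
            ch.smooth_track(enr, 10)


class TestPeaks:
    def test_flat_track_yields_no_padding(self):
        enr = ch.EnrichmentTrack("chr", 50_000, 50, np.ones(1000), 0.5)
        assert ch.call_top_peaks(enr, n=26) == []

    def test_exclusion_keeps_only_higher_of_close_pair(self):
        values = np.ones(1000)
        values[100] = 5.0
        values[110] = 4.0  # 500 bp away — inside the exclusion zone
        values[600] = 3.0
        enr = ch.EnrichmentTrack("chr", 50_000, 50, values, 0.5)
        peaks = ch.call_top_peaks(enr, n=10, min_separation_bp=2000)
        positions = sorted(p.position_bp for p in peaks)
        assert positions == [100 * 50 + 25, 600 * 50 + 25]
        assert peaks[0].rank == 1 and peaks[0].score == 5.0

    def test_planted_sites_recovered_in_top_n(self):
        sites = tuple(range(50_000, 450_000, 17_000))
        spec = SimChipSpec(
            genome_length_bp=500_000, site_positions=sites, site_enrichment=6.0,
            read_depth=2e6, seed=8,
        )
        ip, mock, _ = generate_chipseq(spec)
        ratio = ch.median_ratio_track(ip, mock)
        smoothed = ch.smooth_track(ratio, 2000)
        peaks = ch.call_top_peaks(smoothed, n=len(sites) + 3, refine_with=ratio)
        # recovery within 2 bins: compare bin indices, since the planted
        # enrichment plateau spans the site bin +/- 2 bins
        peak_bins = {int(p.position_bp // spec.bin_bp) for p in peaks}
        recovered = sum(
            any(abs(b - s // spec.bin_bp) <= 2 for b in peak_bins) for s in sites
        )
        assert recovered == len(sites)


class TestMotifScan:
    def test_consensus_matches_itself(self):
        hits = ch.scan_motif(CONSENSUS.replace("R", "A").replace("N", "C").replace("Y", "T"),
                             CONSENSUS, max_mismatch=0)
        assert len(hits) == 1 and hits["start"].iloc[0] == 0

    def test_invalid_iupac_rejected(self):
        with pytest.raises(InvalidSpecError):
            ch.scan_motif("ACGT", "AXGT")

    def test_strand_symmetry(self):
        genome = generate_genome_with_sites(5000, [1200], "GTGACTTTTTCAC", seed=3)
        forward = ch.scan_motif(genome, "GTGACTTTTTCAC", 0)
        from Bio.Seq import Seq

        reverse = ch.scan_motif(str(Seq(genome).reverse_complement()), "GTGACTTTTTCAC", 0)
        assert len(forward) == len(reverse) == 1
        assert reverse["start"].iloc[0] == 5000 - 1200 - 13

    def test_planted_sites_found_exactly(self):
        sites = [500, 10_000, 33_333]
        genome = generate_genome_with_sites(50_000, sites, CONSENSUS, seed=6)
        hits = ch.scan_motif(genome, CONSENSUS, max_mismatch=0)
        planted = hits[hits["start"].isin(sites)]
        assert len(planted) == 3
        extras = hits[~hits["start"].isin(sites)]
        assert (extras["mismatches"] == 0).all()  # chance hits are real matches

    def test_matches_brute_force_oracle(self):
        genome = generate_genome_with_sites(3000, [700], CONSENSUS, seed=7)
        hits = ch.scan_motif(genome, CONSENSUS, max_mismatch=1)
        ours = set(zip(hits["start"], hits["strand"], hits["mismatches"]))
        assert ours == brute_force_scan(genome, CONSENSUS, 1)


class TestAnnotation:
    def test_peak_on_hit_annotated_with_zero_distance(self):
        peaks = [ch.Peak(1000.0, 5.0, 1)]
        hits = pd.DataFrame({"start": [1000]})
        table = ch.annotate_peaks(peaks, hits)
        assert table["at_motif"].iloc[0] and table["distance_bp"].iloc[0] == 0.0

    def test_tolerance_boundary(self):
        peaks = [ch.Peak(1600.0, 5.0, 1)]
        hits = pd.DataFrame({"start": [1000]})
        assert not ch.annotate_peaks(peaks, hits, tolerance_bp=500)["at_motif"].iloc[0]
        assert ch.annotate_peaks(peaks, hits, tolerance_bp=600)["at_motif"].iloc[0]

    def test_excluded_site_not_matched(self):
        peaks = [ch.Peak(1000.0, 5.0, 1)]
        hits = pd.DataFrame({"start": [1000, 50_000]})
        table = ch.annotate_peaks(peaks, hits, exclude_positions=[1000])
        assert not table["at_motif"].iloc[0]

    def test_motif_anchored_peaks_counted_against_artifacts(self):
        """23 motif-anchored sites + artifact peaks: the motif count is 23."""
        rng = np.random.default_rng(10)
        site_positions = tuple(np.sort(rng.choice(1_000_000 // 4000, 23, replace=False)) * 4000 + 2000)
        artifact_positions = (1_500_000, 1_600_000, 1_700_000)
        spec = SimChipSpec(
            genome_length_bp=2_000_000,
            site_positions=site_positions + artifact_positions,
            site_enrichment=(8.0,) * 23 + (6.0,) * 3,
            read_depth=4e6,
            seed=11,
        )
        ip, mock, _ = generate_chipseq(spec)
        ratio = ch.median_ratio_track(ip, mock)
        smoothed = ch.smooth_track(ratio, 2000)
        peaks = ch.call_top_peaks(smoothed, n=26, refine_with=ratio)
        hits = pd.DataFrame({"start": list(site_positions)})
        table = ch.annotate_peaks(peaks, hits, genome_length_bp=spec.genome_length_bp)
        assert len(peaks) == 26
        assert int(table["at_motif"].sum()) == 23


class TestAnchoredProfile:
    def test_symmetric_profile_around_single_planted_peak(self):
        spec = SimChipSpec(
            genome_length_bp=200_000, site_positions=(100_025,), site_enrichment=6.0,
            read_depth=1e7, seed=13,
        )
        ip, mock, _ = generate_chipseq(spec)
        ratio = ch.median_ratio_track(ip, mock)
        profile = ch.anchored_profile(ratio, [100_025], half_window_bp=2000)
        # planted enrichment spans the anchor bin +/- 2 bins: the maximum
        # sits inside that plateau and the flanks are mirror-symmetric
        argmax_offset = profile.loc[profile["value"].idxmax(), "offset_bp"]
        assert abs(argmax_offset) <= 2 * 50
        left = profile[profile["offset_bp"] < -200]["value"].mean()
        right = profile[profile["offset_bp"] > 200]["value"].mean()
        assert left == pytest.approx(right, rel=0.15)

    def test_fold_change_between_planted_heights(self):
        rng = np.random.default_rng(14)
        anchors = tuple(np.sort(rng.choice(1_000_000 // 4000, 26, replace=False)) * 4000 + 2000)

        def ratio_for(fold, seed):
            spec = SimChipSpec(
                genome_length_bp=1_000_000, site_positions=anchors, site_enrichment=fold,
                read_depth=1e7, seed=seed,
            )
            ip, mock, _ = generate_chipseq(spec)
            return ch.median_ratio_track(ip, mock)

        low = ch.anchored_profile(ratio_for(3.0, 15), anchors, 2000)
        high = ch.anchored_profile(ratio_for(4.5, 16), anchors, 2000)
        assert ch.profile_fold_change(high, low) == pytest.approx(1.5, abs=0.1)

    def test_no_enrichment_condition_is_flat(self):
        spec = SimChipSpec(genome_length_bp=1_000_000, read_depth=1e7, seed=17)
        ip, mock, _ = generate_chipseq(spec)
        ratio = ch.median_ratio_track(ip, mock)
        anchors = np.arange(26) * 30_000 + 15_000
        profile = ch.anchored_profile(ch.smooth_track(ratio, 2000), anchors, 2000)
        assert ch.profile_flatness(profile) < 1.2
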