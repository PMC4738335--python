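"""Spot fitting, focus detection and brightest-pixel extraction."""

import numpy as np
import pytest

from mukcoloc.imaging import (
    QC_WEAK,
    CellRegion,
    DetectionParams,
    brightest_pixel,
    detect_foci,
    fit_spot_gaussian,
    foci_to_table,
)
from mukcoloc.simulate import SimImagingSpec, generate_cells, render_images


def _gaussian_window(shape, center, amplitude=200.0, sd=1.3, background=100.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sd * sd)
    )


class TestFitSpotGaussian:
    def test_noiseless_identity_recovery(self):
        window = _gaussian_window((11, 11), (5.0, 5.0))
        focus = fit_spot_gaussian(window, (5, 5))
        assert focus.row == pytest.approx(5.0, abs=1e-3)
        assert focus.col == pytest.approx(5.0, abs=1e-3)
        assert focus.amplitude == pytest.approx(200.0, rel=1e-3)
        assert focus.sd_px == pytest.approx(1.3, rel=1e-3)

    def test_subpixel_recovery_under_noise(self, rng):
        """RMS centroid error stays below 0.1 px at SNR ~20."""
        errors = []
        for _ in range(100):
            truth = (5.0 + rng.uniform(-0.5, 0.5), 5.0 + rng.uniform(-0.5, 0.5))
            window = _gaussian_window((11, 11), truth, sd=1.5) + rng.normal(0, 10, (11, 11))
            focus = fit_spot_gaussian(window, (5, 5), noise_sd=10.0)
            errors.append(np.hypot(focus.row - truth[0], focus.col - truth[1]))
        assert np.sqrt(np.mean(np.square(errors))) <= 0.1

    def test_flat_window_flagged_weak(self):
        focus = fit_spot_gaussian(np.full((9, 9), 50.0), (4, 4))
        assert focus.qc == QC_WEAK

    def test_never_raises_on_hostile_window(self):
        window = np.zeros((7, 7))
        window[0, 6] = 1e9  # single hot pixel at the corner
        focus = fit_spot_gaussian(window, (0, 6))
        assert focus.qc in ("weak", "edge", "ok")


class TestDetectFoci:
    def test_single_planted_focus_recovered(self, small_imaging_run):
        spec, cells, truth, images = small_imaging_run
        foci = detect_foci(images["a"], cells, "a")
        by_cell = {f.cell_id: f for f in foci}
        assert len(by_cell) == len(cells)
        for row in truth.itertuples():
            focus = by_cell[row.cell_id]
            assert np.hypot(focus.row - row.a_row, focus.col - row.a_col) < 0.2

    def test_two_foci_six_pixels_apart_both_found(self):
        spec = SimImagingSpec(n_cells=1, noise_model="none", seed=1)
        cells, truth = generate_cells(spec)
        images = render_images(cells, truth, spec)
        frame = images["a"].copy()
        # plant a second identical focus 6 px along the cell axis
        row = truth.iloc[0]
        r0, c0 = row.a_row, row.a_col
        c1 = c0 + 6 if cells[0].contains(r0, c0 + 6) else c0 - 6
        rr, cc = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
        frame += spec.focus_amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c1) ** 2) / (2 * spec.psf_sigma_px**2)
        )
        foci = detect_foci(frame, cells, "a")
        assert len(foci) == 2

    def test_blank_frame_detects_nothing(self, small_imaging_run):
        _, cells, _, images = small_imaging_run
        blank = np.full_like(images["a"], 100.0)
        assert detect_foci(blank, cells, "a") == []

    def test_translation_equivariance(self):
        spec = SimImagingSpec(n_cells=6, seed=13)
        cells, truth = generate_cells(spec)
        images = render_images(cells, truth, spec)
        dr, dc = 3, 7
        shifted_frame = np.zeros(
            (images["a"].shape[0] + dr, images["a"].shape[1] + dc)
        ) + images["a"].min()
        shifted_frame[dr:, dc:] = images["a"]
        shifted_cells = [
            CellRegion(c.cell_id, (c.origin[0] + dr, c.origin[1] + dc), c.mask, c.pixel_size_nm)
            for c in cells
        ]
        original = detect_foci(images["a"], cells, "a")
        shifted = detect_foci(shifted_frame, shifted_cells, "a")
        assert len(original) == len(shifted)
        for a, b in zip(original, shifted):
            assert b.row - a.row == pytest.approx(dr, abs=1e-9)
            assert b.col - a.col == pytest.approx(dc, abs=1e-9)

    def test_detection_recall_precision_on_generator_images(self):
        """Recall and precision >= 0.95 against planted foci at SNR >= 10."""
        spec = SimImagingSpec(n_cells=500, seed=17)
        cells, truth = generate_cells(spec)
        images = render_images(cells, truth, spec)
        foci = detect_foci(images["b"], cells, "b")
        planted = {r.cell_id: (r.b_row, r.b_col) for r in truth.itertuples() if r.has_b}
        matched = sum(
            1
            for f in foci
            if f.cell_id in planted
            and np.hypot(f.row - planted[f.cell_id][0], f.col - planted[f.cell_id][1]) < 1.5
        )
        assert matched / len(planted) >= 0.95  # recall
        assert matched / len(foci) >= 0.95  # precision


class TestBrightestPixel:
    def test_unique_maximum(self):
        mask = np.ones((3, 5), bool)
        cell = CellRegion(0, (2, 2), mask)
        frame = np.zeros((10, 10))
        frame[3, 4] = 7.0
        result = brightest_pixel(frame, cell)
        assert (result.row, result.col, result.intensity) == (3, 4, 7.0)

    def test_tie_broken_lexicographically(self):
        mask = np.ones((3, 3), bool)
        cell = CellRegion(0, (0, 0), mask)
        frame = np.zeros((5, 5))
        frame[2, 1] = frame[1, 2] = 9.0
        result = brightest_pixel(frame, cell)
        assert (result.row, result.col) == (1, 2)

    def test_within_one_pixel_of_planted_focus(self, small_imaging_run):
        _, cells, truth, images = small_imaging_run
        for row in truth.head(10).itertuples():
            result = brightest_pixel(images["a"], cells[row.cell_id], "a")
            assert np.hypot(result.row - row.a_row, result.col - row.a_col) <= 1.5

    def test_exactly_one_per_cell(self, small_imaging_run):
        _, cells, _, images = small_imaging_run
        results = [brightest_pixel(images["a"], c) for c in cells]
        assert len({r.cell_id for r in results}) == len(cells)


def test_foci_table_roundtrip_schema(small_imaging_run):
    _, cells, _, images = small_imaging_run
    table = foci_to_table(detect_foci(images["a"], cells[:5], "a"))
    assert list(table.columns) == ["cell_id", "frame", "channel", "row", "col", "amplitude", "sd", "qc"]
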