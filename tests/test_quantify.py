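"""Segmentation backends, the window calling rule, and per-core counting."""

import dataclasses
import math

import numpy as np
import pytest

from tmaquant.geometry import CoreImage
from tmaquant.quantify import (
    CellObject,
    CoreResult,
    GroundTruthBackend,
    LogBlobBackend,
    QuantifyConfig,
    call_positive,
    cutoff_sensitivity,
    get_backend,
    quantify_core,
    segment_nuclei,
)
from tmaquant.stains import BinaryMask, StainMatrix, deconvolve, od_to_rgb, rgb_to_od
from tmaquant.synthetic import SyntheticCoreSpec, render_core, save_ground_truth


def window_fraction_bruteforce(mask, x, y, grid_size=16):
    """Independent per-pixel count of the calling window."""
    cx, cy = math.floor(x + 0.5), math.floor(y + 0.5)
    half = grid_size // 2
    count = denom = 0
    for yy in range(cy - half, cy - half + grid_size):
        for xx in range(cx - half, cx - half + grid_size):
            if 0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]:
                denom += 1
                count += bool(mask[yy, xx])
    return count / denom if denom else 0.0


class TestCallPositive:
    @pytest.mark.parametrize("n_true, expected", [(26, True), (25, False)])
    def test_strict_ten_percent_boundary(self, n_true, expected):
        """26/256 window pixels (10.16%) is positive; 25/256 (9.77%) is not."""
        mask = np.zeros((64, 64), dtype=bool)
        flat = np.zeros(256, dtype=bool)
        flat[:n_true] = True
        mask[24:40, 24:40] = flat.reshape(16, 16)
        cell = call_positive(CellObject(x=32.0, y=32.0, radius=5.0), BinaryMask(mask, 0.1))
        assert cell.positive is expected
        assert cell.positive_pixel_fraction == pytest.approx(n_true / 256)

    def test_all_false_mask_means_negative(self):
        cell = call_positive(
            CellObject(x=10.0, y=10.0, radius=5.0), BinaryMask(np.zeros((32, 32), bool), 0.1)
        )
        assert cell.positive is False
        assert cell.positive_pixel_fraction == 0.0

    def test_border_window_uses_clipped_denominator(self):
        mask = np.ones((64, 64), dtype=bool)
        cell = call_positive(CellObject(x=0.0, y=0.0, radius=5.0), BinaryMask(mask, 0.1))
        # the window is clipped to 8x8 at the corner but stays all-true
        assert cell.positive_pixel_fraction == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < rng.uniform(0, 0.3)
        for _ in range(20):
            x = rng.uniform(-4, 51)
            y = rng.uniform(-4, 51)
            cell = call_positive(CellObject(x=x, y=y, radius=4.0), BinaryMask(mask, 0.1))
            expected = window_fraction_bruteforce(mask, x, y)
            assert cell.positive_pixel_fraction == pytest.approx(expected)
            assert cell.positive is (expected > 0.10)

    def test_adding_mask_pixels_never_demotes(self):
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) < 0.05
        cells = [CellObject(x=float(x), y=float(y), radius=4.0) for x, y in rng.uniform(0, 40, (30, 2))]
        before = [call_positive(c, BinaryMask(mask, 0.1)).positive for c in cells]
        grown = mask | (rng.random((40, 40)) < 0.1)
        after = [call_positive(c, BinaryMask(grown, 0.1)).positive for c in cells]
        assert all(b <= a for b, a in zip(before, after))


class TestBackends:
    def test_unknown_backend_is_configuration_error(self):
        with pytest.raises(ValueError, match="unknown segmentation backend"):
            get_backend("voronoi")

    def test_injection_without_source_raises(self, small_core):
        image, _ = small_core
        channels = deconvolve(rgb_to_od(image.pixels))
        with pytest.raises(FileNotFoundError):
            segment_nuclei(image, channels, GroundTruthBackend())

    def test_injection_from_sidecar(self, tmp_path, small_core):
        image, gt = small_core
        prefix = tmp_path / "core.png"
        save_ground_truth(gt, prefix)
        channels = deconvolve(rgb_to_od(image.pixels))
        cells = segment_nuclei(image, channels, GroundTruthBackend(sidecar=str(prefix)))
        assert len(cells) == gt.n_total

    def test_empty_tissue_gives_no_cells(self):
        spec = SyntheticCoreSpec(image_size=512, core_radius=200, n_cells=0, seed=1)
        image, _ = render_core(spec)
        channels = deconvolve(rgb_to_od(image.pixels))
        cells = segment_nuclei(image, channels, LogBlobBackend())
        assert cells == []

    def test_default_backend_counts_well_separated_core(self):
        spec = SyntheticCoreSpec(seed=21, n_cells=200, positive_fraction=0.3)
        image, gt = render_core(spec)
        result = quantify_core(image, QuantifyConfig(backend=LogBlobBackend()))
        assert abs(result.n_total_cells - 200) <= 10

    def test_fused_pair_yields_at_least_one_cell(self):
        """Two heavily overlapping nuclei must not vanish entirely."""
        size = 128
        h = np.zeros((size, size))
        from skimage.draw import ellipse

        for cx in (60.0, 69.0):  # centre separation = 1.2 x radius
            rr, cc = ellipse(64, cx, 7.5, 7.5, shape=h.shape)
            h[rr, cc] = np.maximum(h[rr, cc], 0.6)
        m = StainMatrix()
        pixels = od_to_rgb(h[..., None] * np.asarray(m.hematoxylin))
        image = CoreImage(pixels=pixels)
        channels = deconvolve(rgb_to_od(pixels), m)
        cells = segment_nuclei(image, channels, LogBlobBackend())
        assert 1 <= len(cells) <= 2


class TestQuantifyCore:
    def test_injection_reproduces_ground_truth_exactly(self, small_core, small_result):
        _, gt = small_core
        assert small_result.n_total_cells == gt.n_total
        assert small_result.n_positive_cells == gt.n_positive

    def test_blank_core_is_flagged_without_counts(self):
        spec = SyntheticCoreSpec(image_size=512, core_radius=200, artifact="blank", seed=2)
        image, _ = render_core(spec)
        result = quantify_core(image, QuantifyConfig(backend=LogBlobBackend()))
        assert "no_circle" in result.flags
        assert result.n_total_cells is None
        assert result.n_positive_cells is None

    def test_counts_unset_invariant_enforced(self):
        with pytest.raises(ValueError):
            CoreResult(n_total_cells=5, n_positive_cells=1, flags={"no_circle"})

    def test_positive_bounded_by_total(self):
        with pytest.raises(ValueError):
            CoreResult(n_total_cells=5, n_positive_cells=7)

    def test_two_runs_identical(self, small_core):
        image, gt = small_core
        cfg = QuantifyConfig(backend=GroundTruthBackend(ground_truth=gt))
        r1 = quantify_core(image, cfg)
        r2 = quantify_core(image, cfg)
        assert r1 == r2


class TestCutoffSensitivity:
    def test_zero_cutoff_counts_any_touch(self, small_result):
        table = cutoff_sensitivity(small_result, cutoffs=(0.0,))
        touched = sum(c.positive_pixel_fraction > 0 for c in small_result.cells)
        assert table["n_positive"].iloc[0] == touched

    def test_counts_non_increasing_in_cutoff(self, small_result):
        table = cutoff_sensitivity(small_result)
        assert (table["n_positive"].diff().dropna() <= 0).all()

    def test_stable_counts_when_fractions_are_separated(self, small_result):
        """Synthetic positives sit far above 0.25 and negatives far below 0.05,
        so the whole default cutoff grid returns one count."""
        table = cutoff_sensitivity(small_result)
        assert table["n_positive"].nunique() == 1
        assert table["n_positive"].iloc[0] == small_result.n_positive_cells

    def test_flagged_core_rejected(self):
        flagged = CoreResult(flags={"no_circle"})
        with pytest.raises(ValueError):
            cutoff_sensitivity(flagged)
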