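"""ZOT detection: gradient primitives, refinement, transition extents, band."""

import logging
import math

import numpy as np
import pytest
from scipy.special import expit

from zotrad.io import RoiMask
from zotrad.phantom import PhantomSpec, generate_phantom
from zotrad.zot import (GradientLine, ZotConfig, ZOTUndetectableError,
                        compute_gradient_field, detect_zot,
                        find_transition_extent, refine_tumour_roi,
                        reconstruct_zot, select_largest_slice,
                        trace_gradient_lines)

_LOGISTIC_DFWHM = 2.0 * math.log(3.0 + 2.0 * math.sqrt(2.0))


def disc_image(shape=(96, 96), radius=20.0, inside=100.0, outside=40.0,
               rim=0.0):
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    dist = np.hypot(yy - cy, xx - cx)
    if rim <= 0:
        img = np.where(dist <= radius, inside, outside)
    else:
        k = rim / _LOGISTIC_DFWHM
        img = outside + (inside - outside) * expit((radius - dist) / k)
    return img.astype(float), dist, (cy, cx)


def band_stats(support, center, n_bins=36):
    """Per-angular-sector min/max radius and width of a band."""
    ys, xs = np.nonzero(support)
    r = np.hypot(ys - center[0], xs - center[1])
    th = np.arctan2(ys - center[0], xs - center[1])
    bins = np.floor((th + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    inner, outer, width = [], [], []
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            inner.append(r[sel].min())
            outer.append(r[sel].max())
            width.append(np.ptp(r[sel]))
    return np.mean(inner), np.mean(outer), np.mean(width)


class TestSelectLargestSlice:
    def test_picks_max_area(self):
        m = np.zeros((10, 10, 3), bool)
        m[:2, :5, 0] = True   # 10
        m[:5, :8, 1] = True   # 40
        m[:5, :5, 2] = True   # 25
        assert select_largest_slice(m) == 1

    def test_single_slice_and_2d(self):
        m = np.zeros((5, 5, 1), bool)
        m[1:3, 1:3, 0] = True
        assert select_largest_slice(m) == 0
        assert select_largest_slice(m[:, :, 0]) == 0

    def test_tie_breaks_low(self):
        m = np.zeros((8, 8, 2), bool)
        m[:5, :6, 0] = True
        m[:6, :5, 1] = True
        assert select_largest_slice(m) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_largest_slice(np.zeros((4, 4, 2), bool))


class TestGradientField:
    def test_constant_image_zero_magnitude(self):
        f = compute_gradient_field(np.full((16, 16), 7.0), 1.0)
        assert np.allclose(f.magnitude, 0.0)

    def test_linear_ramp_uniform_gradient(self):
        yy, xx = np.indices((20, 20))
        f = compute_gradient_field(3.0 * xx, smoothing_sigma=0.0)
        assert np.allclose(f.magnitude, 3.0)
        assert np.allclose(f.direction, 0.0)  # increase along +columns

    def test_disc_edge_maxima_on_circle(self):
        """Brute-force max-per-ray scan: the gradient crest of a disc step
        edge lies on the circle to within one pixel."""
        from scipy.ndimage import map_coordinates
        img, _, center = disc_image(radius=15.0)
        f = compute_gradient_field(img, 1.0)
        t = np.arange(5.0, 28.0, 0.25)
        for ang in np.linspace(0, 2 * np.pi, 24, endpoint=False):
            prof = map_coordinates(
                f.magnitude,
                [center[0] + t * np.sin(ang), center[1] + t * np.cos(ang)],
                order=1)
            assert abs(t[np.argmax(prof)] - 15.0) <= 1.0


class TestRefineTumourRoi:
    def test_fixed_point_on_sharp_edge(self):
        img, dist, _ = disc_image(radius=20.0)
        manual = dist <= 20.0
        refined = refine_tumour_roi(img, RoiMask(manual), 10, 1.0)
        mismatch = np.sum(refined.support ^ manual)
        assert mismatch <= 0.02 * manual.sum()

    def test_recovers_true_circle_from_inner_manual(self):
        """Manual circle drawn 3 px inside a sharp radius-20 edge: the
        refined boundary relocates to the true circle within 1 px (oracle =
        the analytic circle)."""
        from skimage.segmentation import find_boundaries
        img, dist, center = disc_image(radius=20.0)
        refined = refine_tumour_roi(img, RoiMask(dist <= 17.0), 10, 1.0)
        b = np.argwhere(find_boundaries(refined.support, mode="inner"))
        radii = np.hypot(b[:, 0] - center[0], b[:, 1] - center[1])
        assert abs(radii.mean() - 20.0) <= 1.0

    def test_constant_image_falls_back(self, caplog):
        manual = np.zeros((32, 32), bool)
        manual[10:20, 10:20] = True
        with caplog.at_level(logging.WARNING):
            refined = refine_tumour_roi(np.full((32, 32), 5.0),
                                        RoiMask(manual), 10, 1.0)
        assert np.array_equal(refined.support, manual)
        assert any("falling back" in r.message for r in caplog.records)

    def test_refinement_idempotent(self):
        img, dist, _ = disc_image(radius=20.0)
        r1 = refine_tumour_roi(img, RoiMask(dist <= 17.0), 10, 1.0)
        r2 = refine_tumour_roi(img, r1, 10, 1.0)
        changed = np.sum(r1.support ^ r2.support)
        assert changed <= 0.01 * r1.support.sum()

    def test_subset_of_dilated_manual(self):
        from skimage.morphology import dilation, disk
        img, dist, _ = disc_image(radius=20.0)
        manual = dist <= 17.0
        refined = refine_tumour_roi(img, RoiMask(manual), 5, 1.0)
        assert not np.any(refined.support & ~dilation(manual, disk(5)))


class TestTraceGradientLines:
    def test_step_edge_profile_peaks_at_center(self):
        img, dist, _ = disc_image(radius=20.0)
        f = compute_gradient_field(img, 1.0)
        border = (47, int(round(47.5 + 20)))  # right-most edge pixel
        lines = trace_gradient_lines(f, border, half_length=10)
        assert len(lines) == 3
        main = lines[0]
        assert abs(int(np.argmax(main.samples)) - main.center_idx) <= 1

    def test_sigmoid_inflection_span(self):
        """For a logistic edge of scale k the gradient profile's
        inflection-to-inflection span is 2*ln(2+sqrt(3))*k (closed form for
        the logistic derivative)."""
        k = 2.0
        img, dist, center = disc_image(radius=20.0,
                                       rim=k * _LOGISTIC_DFWHM)
        f = compute_gradient_field(img, smoothing_sigma=0.0)
        border = (int(center[0]), int(round(center[1] + 20)))
        main = trace_gradient_lines(f, border, half_length=15)[0]
        d2 = np.diff(main.samples, 2)
        signs = np.sign(d2)
        flips = np.flatnonzero(np.diff(signs) != 0) + 1
        # inflections nearest the peak on each side
        c = main.center_idx - 1
        left = flips[flips < c].max()
        right = flips[flips >= c].min()
        expected = 2 * math.log(2 + math.sqrt(3)) * k
        assert (right - left) == pytest.approx(expected, abs=1.5)

    def test_flat_region_line_undetectable(self):
        img, dist, _ = disc_image(radius=10.0, inside=100, outside=40)
        f = compute_gradient_field(img, 1.0)
        lines = trace_gradient_lines(f, (3, 3), half_length=5)  # far corner
        assert max(ln.samples.max() for ln in lines) < 1.0
        for ln in lines:
            assert find_transition_extent(ln, noise_floor=2.0) is None

    def test_out_of_bounds_truncated_flag(self):
        img, dist, _ = disc_image((40, 40), radius=12.0)
        f = compute_gradient_field(img, 1.0)
        lines = trace_gradient_lines(f, (1, 20), half_length=15)
        assert any(ln.truncated for ln in lines)

    def test_half_length_validation(self):
        img, _, _ = disc_image((40, 40), radius=12.0)
        f = compute_gradient_field(img, 1.0)
        with pytest.raises(ValueError):
            trace_gradient_lines(f, (20, 20), half_length=1)


def _extent_oracle(samples, center, floor):
    """Independent exhaustive implementation of the transition-extent rule."""
    s = list(samples)
    n = len(s)
    if n < 5:
        return None
    i = center
    while True:
        if i + 1 < n and s[i + 1] > s[i]:
            i += 1
        elif i - 1 >= 0 and s[i - 1] > s[i]:
            i -= 1
        else:
            break
    if i in (0, n - 1) or s[i] < floor or s[i] <= 0:
        return None

    def scan(indices):
        for j in indices:
            if s[j] <= floor:
                return j
            if 0 < j < n - 1 and s[j] < s[j - 1] and s[j] < s[j + 1]:
                return j
        return None

    left = scan(range(i - 1, -1, -1))
    right = scan(range(i + 1, n))
    if left is None or right is None:
        return None
    return left, right


def _line(samples, center=None):
    samples = np.asarray(samples, dtype=float)
    center = len(samples) // 2 if center is None else center
    return GradientLine((0, 0), 0.0, samples, center, (0.0, 1.0))


class TestFindTransitionExtent:
    def test_symmetric_bell(self):
        assert find_transition_extent(_line([0, 1, 3, 1, 0]), 0.5) == (0, 4)

    def test_monotone_profile_undetectable(self):
        assert find_transition_extent(_line([1, 2, 3, 4, 5]), 0.5) is None

    def test_peak_below_floor_undetectable(self):
        assert find_transition_extent(_line([0, 1, 2, 1, 0]), 10.0) is None

    @pytest.mark.parametrize("sigma", [1.5, 2.5, 4.0])
    def test_matches_exhaustive_oracle(self, sigma, rng):
        """Gaussian-bell profiles with additive ripple: the minima match an
        independent exhaustive scan exactly."""
        t = np.arange(-15, 16, dtype=float)
        for trial in range(20):
            prof = np.exp(-t**2 / (2 * sigma**2)) \
                + 0.05 * rng.standard_normal(len(t))
            prof -= prof.min()
            floor = 0.1 * prof.max()
            line = _line(prof, center=15)
            got = find_transition_extent(line, floor)
            assert got == _extent_oracle(prof, 15, floor)

    def test_short_profile_undetectable(self):
        assert find_transition_extent(_line([0, 1, 0]), 0.0) is None


class TestReconstructZot:
    def test_low_detectability_raises(self):
        lines = [_line([0, 1, 3, 1, 0]) for _ in range(10)]
        for i, ln in enumerate(lines):
            ln.border_pixel = (i, i)
            if i < 2:  # only 20% detectable
                find_transition_extent(ln, 0.5)
        with pytest.raises(ZOTUndetectableError, match="20%"):
            reconstruct_zot(lines, np.ones((10, 10), bool), (10, 10))

    def test_annulus_brackets_true_rim(self):
        """Noiseless circular phantom, rim 6 px: the detected band covers
        the true rim annulus to within 1.5 px on both sides."""
        spec = PhantomSpec(lesion_radii=(16.0, 16.0), rim_width=6.0,
                           texture_sd_core=0, texture_sd_rim=0, noise_sd=0,
                           seed=2)
        arterial, _, mask = generate_phantom(spec)
        _, zot, _ = detect_zot(arterial, mask, ZotConfig())
        inner, outer, _ = band_stats(zot.support, spec.lesion_center)
        assert inner <= 16.0 - 3.0 + 1.5
        assert outer >= 16.0 + 3.0 - 1.5

    def test_sharp_edge_resolution_limited(self):
        """rim_width -> 0 limit: on an analytically sharp edge (no extra
        smoothing) the band is at most ~3 px thick."""
        img, dist, center = disc_image(radius=20.0)
        _, zot, _ = detect_zot(img, RoiMask(dist <= 20.0),
                               ZotConfig(smoothing_sigma=0.0))
        _, _, width = band_stats(zot.support, center)
        assert width <= 3.0

    def test_anisotropic_sectors(self):
        """One sharp and one blurred sector: the band is wider where the
        transition is gradual."""
        yy, xx = np.indices((96, 96))
        cy = cx = 47.5
        dist = np.hypot(yy - cy, xx - cx)
        th = np.arctan2(yy - cy, xx - cx)
        k = 9.0 / _LOGISTIC_DFWHM
        blurred = expit((16.0 - dist) / k)
        sharp = (dist <= 16.0).astype(float)
        img = 40.0 + 60.0 * np.where(np.cos(th) >= 0, sharp, blurred)
        _, zot, _ = detect_zot(img, RoiMask(dist <= 16.0), ZotConfig())
        ys, xs = np.nonzero(zot.support)
        r = np.hypot(ys - cy, xs - cx)
        ang = np.arctan2(ys - cy, xs - cx)
        width_sharp = np.ptp(r[np.cos(ang) > 0.3])
        width_blur = np.ptp(r[np.cos(ang) < -0.3])
        assert width_blur > width_sharp + 2.0

    def test_thickness_monotone_in_rim_width(self):
        widths = []
        for rim in (2.0, 5.0, 8.0):
            spec = PhantomSpec(lesion_radii=(16.0, 16.0), rim_width=rim,
                               texture_sd_core=0, texture_sd_rim=0,
                               noise_sd=0, seed=2)
            arterial, _, mask = generate_phantom(spec)
            _, zot, _ = detect_zot(arterial, mask, ZotConfig())
            widths.append(band_stats(zot.support, spec.lesion_center)[2])
        assert widths[0] <= widths[1] + 0.25 <= widths[2] + 0.5

    def test_band_crosses_border(self, demo_zot):
        for phase in ("arterial", "venous"):
            zot = demo_zot[phase][1]
            assert zot.inner_overlap > 0
            assert zot.outer_overlap > 0

    def test_constant_image_undetectable(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.indices((64, 64))
        mask[np.hypot(yy - 31.5, xx - 31.5) < 10] = True
        with pytest.raises(ZOTUndetectableError):
            detect_zot(np.full((64, 64), 50.0), RoiMask(mask), ZotConfig())
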