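import math

import numpy as np
import pytest
from scipy import integrate
from scipy.ndimage import rotate

from vesselwall.data_io import ImageStack, ValidationError
from vesselwall.orientation import (
    OrientationDistribution,
    average_distribution,
    depth_orientation_map,
    detect_interface,
    orientation_distribution,
    qc_qa_ratio,
)
from vesselwall.synth import (
    axial_to_circumferential_specs,
    render_fiber_image,
    render_fiber_stack,
)

from .conftest import grating_spec


def circ_distance(a, b):
    """Distance between orientations modulo 180°."""
    return abs(((a - b + 90.0) % 180.0) - 90.0)


class TestOrientationDistribution:
    @pytest.mark.parametrize("angle", [0.0, 30.0, 90.0, -60.0])
    def test_grating_mode_recovered(self, angle):
        img, _ = render_fiber_image(grating_spec(angle))
        d = orientation_distribution(img)
        assert circ_distance(d.mode_angle(), angle) <= d.bin_width

    def test_rotation_equivariance(self):
        img, _ = render_fiber_image(grating_spec(0.0, seed=2))
        d0 = orientation_distribution(img)
        for delta in (20.0, 45.0):
            rot = rotate(img, delta, reshape=False, order=1)
            d = orientation_distribution(rot)
            assert circ_distance(d.mode_angle(), d0.mode_angle() + delta) <= d.bin_width

    def test_density_normalised(self):
        img, _ = render_fiber_image(grating_spec(30.0))
        d = orientation_distribution(img)
        assert d.density.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(d.density >= 0)

    def test_constant_image_flagged_uniform(self):
        d = orientation_distribution(np.full((64, 64), 7.0))
        assert d.no_structure
        np.testing.assert_allclose(d.density, 1.0 / d.n_bins)

    def test_small_image_rejected(self):
        with pytest.raises(ValidationError):
            orientation_distribution(np.zeros((32, 32)))

    def test_intensity_scale_invariance(self):
        img, _ = render_fiber_image(grating_spec(25.0, seed=5))
        d1 = orientation_distribution(img)
        d2 = orientation_distribution(img * 11.0)
        np.testing.assert_allclose(d1.density, d2.density, atol=1e-12)

    def test_matches_brute_force_spectrum_binning(self):
        """Vectorised binning agrees with an explicit per-frequency loop."""
        rng = np.random.default_rng(3)
        img = rng.random((64, 64)) + render_fiber_image(
            grating_spec(40.0, image_size=(64, 64), n_fibers=6, fiber_length=50.0)
        )[0]
        n_bins = 90
        d = orientation_distribution(img, n_bins=n_bins, low_freq_radius=3.0)

        # independent brute-force oracle
        ny, nx = img.shape
        yy = np.arange(ny) - (ny - 1) / 2.0
        xx = np.arange(nx) - (nx - 1) / 2.0
        rr = np.hypot(yy[:, None] / (ny / 2.0), xx[None, :] / (nx / 2.0))
        win = np.where(rr <= 1.0, 0.5 * (1 + np.cos(math.pi * np.minimum(rr, 1.0))), 0.0)
        spec = np.fft.fftshift(np.abs(np.fft.fft2((img - img.mean()) * win)) ** 2)
        hist = np.zeros(n_bins)
        cy, cx = ny // 2, nx // 2
        for iy in range(ny):
            for ix in range(nx):
                fy, fx = -(iy - cy), ix - cx
                if math.hypot(fy, fx) <= 3.0:
                    continue
                theta = (math.degrees(math.atan2(fy, fx)) - 90.0 + 90.0) % 180.0 - 90.0
                b = min(int((theta + 90.0) // 2.0), n_bins - 1)
                hist[b] += spec[iy, ix]
        hist /= hist.sum()
        np.testing.assert_allclose(d.density, hist, atol=1e-9)

    def test_isotropic_noise_near_uniform(self):
        diffs = []
        for s in range(5):
            rng = np.random.default_rng(s)
            d = orientation_distribution(rng.standard_normal((256, 256)))
            diffs.append(d.density.max() - d.density.min())
        assert np.mean(diffs) < 0.02


class TestAverageDistribution:
    def _delta(self, angle, n_bins=90):
        centers = -90.0 + 2.0 * (np.arange(n_bins) + 0.5)
        dens = np.zeros(n_bins)
        dens[np.argmin(np.abs(centers - angle))] = 1.0
        return OrientationDistribution(centers, dens)

    def test_identity(self):
        d = self._delta(10.0)
        avg = average_distribution([d, d, d])
        np.testing.assert_allclose(avg.density, d.density)

    def test_bimodal_from_two_deltas(self):
        avg = average_distribution([self._delta(-45.0), self._delta(45.0)])
        peaks = np.sort(avg.density)[-2:]
        np.testing.assert_allclose(peaks, [0.5, 0.5])

    def test_mismatched_bins_rejected(self):
        d90 = self._delta(0.0, n_bins=90)
        d45 = self._delta(0.0, n_bins=45)
        with pytest.raises(ValidationError):
            average_distribution([d90, d45])

    def test_von_mises_stack_mode(self):
        specs = [
            grating_spec(20.0, seed=s, mixture_kappas=(30.0,)) for s in range(4)
        ]
        dists = [orientation_distribution(render_fiber_image(sp)[0]) for sp in specs]
        avg = average_distribution(dists)
        assert circ_distance(avg.mode_angle(), 20.0) <= 2 * avg.bin_width


class TestQcQaRatio:
    def _uniform(self, n_bins=90):
        centers = -90.0 + (180.0 / n_bins) * (np.arange(n_bins) + 0.5)
        return OrientationDistribution(centers, np.full(n_bins, 1.0 / n_bins))

    def test_uniform_is_exactly_one(self):
        q = qc_qa_ratio(self._uniform())
        assert q.ratio == pytest.approx(1.0, abs=1e-12)
        assert q.Q_C + q.Q_A == pytest.approx(1.0, abs=1e-12)

    def test_axial_delta_is_zero(self):
        centers = -90.0 + 2.0 * (np.arange(90) + 0.5)
        dens = np.zeros(90)
        dens[np.argmin(np.abs(centers))] = 1.0
        q = qc_qa_ratio(OrientationDistribution(centers, dens))
        assert q.ratio == 0.0

    def test_circumferential_delta_is_infinite(self):
        centers = -90.0 + 2.0 * (np.arange(90) + 0.5)
        dens = np.zeros(90)
        dens[0] = 1.0  # bin centred at −89°
        q = qc_qa_ratio(OrientationDistribution(centers, dens))
        assert q.infinite and math.isinf(q.ratio)

    def test_von_mises_at_90_against_quadrature(self):
        kappa = 2.0
        # axial density with period 180°, mean at ±90°; 1° bins so the ±45°
        # split falls exactly on bin edges
        pdf = lambda th: math.exp(kappa * math.cos(2 * math.radians(th - 90.0)))
        n_bins = 180
        centers = -90.0 + 1.0 * (np.arange(n_bins) + 0.5)
        masses = np.array([
            integrate.quad(pdf, c - 0.5, c + 0.5)[0] for c in centers
        ])
        dist = OrientationDistribution(centers, masses / masses.sum())
        q = qc_qa_ratio(dist)
        total, _ = integrate.quad(pdf, -90.0, 90.0)
        axial, _ = integrate.quad(pdf, -45.0, 45.0)
        expected = (total - axial) / axial
        assert q.ratio == pytest.approx(expected, abs=1e-3)

    def test_straddling_bin_contributes_proportionally(self):
        # all mass in the bin spanning [44°, 46°]: half axial, half circumferential
        centers = -90.0 + 2.0 * (np.arange(90) + 0.5)
        dens = np.zeros(90)
        dens[np.argmin(np.abs(centers - 45.0))] = 1.0
        q = qc_qa_ratio(OrientationDistribution(centers, dens))
        assert q.ratio == pytest.approx(1.0, abs=1e-12)

    def test_split_angle_bounds(self):
        with pytest.raises(ValueError):
            qc_qa_ratio(self._uniform(), split_angle=0.0)


class TestInterfaceDetection:
    def _map_from_ratios(self, ratios):
        centers = -90.0 + 2.0 * (np.arange(90) + 0.5)
        dists = []
        for r in ratios:
            # two-delta distribution at 0° and ±89° with circ mass r/(1+r)
            dens = np.zeros(90)
            circ = r / (1.0 + r)
            dens[np.argmin(np.abs(centers))] = 1.0 - circ
            dens[0] = circ
            dists.append(OrientationDistribution(centers, dens))
        return depth_map_from(dists)

    def test_axial_throughout_gives_none(self):
        m = self._map_from_ratios([0.2] * 10)
        assert detect_interface(m) is None

    def test_single_terminal_circumferential_frame_insufficient(self):
        m = self._map_from_ratios([0.2] * 9 + [5.0])
        assert detect_interface(m, persistence=3) is None

    def test_first_persistent_crossing_depth(self):
        m = self._map_from_ratios([0.2] * 5 + [3.0] * 5)
        assert detect_interface(m, persistence=3) == 5.0

    def test_transient_crossing_skipped(self):
        m = self._map_from_ratios([0.2, 3.0, 0.2, 0.2] + [3.0] * 4)
        assert detect_interface(m, persistence=3) == 4.0

    def test_programmed_flip_recovered_on_rendered_stack(self):
        specs = axial_to_circumferential_specs(
            30, 15, seed=9,
        )
        stack, _ = render_fiber_stack(specs, interface_depth=15.0)
        m = depth_orientation_map(stack)
        depth = detect_interface(m)
        assert depth is not None and 14.0 <= depth <= 17.0


def depth_map_from(dists):
    from vesselwall.orientation import DepthOrientationMap

    return DepthOrientationMap(np.arange(float(len(dists))), dists)


class TestDepthOrientationMap:
    def test_single_frame_stack(self):
        img, _ = render_fiber_image(grating_spec(0.0))
        stack = ImageStack(img[None], pixel_size=1.0)
        m = depth_orientation_map(stack)
        assert len(m.distributions) == 1

    def test_all_axial_stack_modes(self):
        frames = [render_fiber_image(grating_spec(0.0, seed=s))[0] for s in range(3)]
        stack = ImageStack(np.stack(frames), pixel_size=1.0)
        m = depth_orientation_map(stack)
        for d in m.distributions:
            assert circ_distance(d.mode_angle(), 0.0) <= d.bin_width

    def test_surface_shape(self):
        frames = [render_fiber_image(grating_spec(0.0, seed=s))[0] for s in range(4)]
        m = depth_orientation_map(ImageStack(np.stack(frames), pixel_size=1.0), n_bins=45)
        assert m.surface().shape == (4, 45)
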