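"""Synaptic-plane metrics: partition geometry, enrichment indices, kinetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import synquant as sq
from synquant.errors import DegenerateWindowError, SegmentationError, UndefinedRatioError
from synquant.synapse_plane import _mask_moments


def disk_mask(shape=(120, 120), center=(60, 60), radius=40):
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ellipse_mask(shape=(160, 160), center=(80, 80), a=55, b=22, angle=0.0):
    rr, cc = np.indices(shape)
    u = (rr - center[0]) * np.cos(angle) + (cc - center[1]) * np.sin(angle)
    v = -(rr - center[0]) * np.sin(angle) + (cc - center[1]) * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestPartition:
    def test_circular_mask_gets_concentric_one_third_disk(self):
        mask = disk_mask()
        part = sq.build_partition(mask)
        assert part.center_area_fraction == pytest.approx(1 / 3, abs=0.02)
        c_mask, _, _ = _mask_moments(mask)
        c_center, _, _ = _mask_moments(part.center_template)
        assert np.linalg.norm(c_mask - c_center) <= 1.0

    def test_elongated_mask_center_matches_orientation(self):
        angle = np.deg2rad(30)
        mask = ellipse_mask(angle=angle)
        part = sq.build_partition(mask)
        _, evals, evecs = _mask_moments(part.center_template)
        major = evecs[:, 1]
        measured = np.arctan2(major[1], major[0]) % np.pi
        # compare against the whole mask's major-axis direction, mod 180°
        _, mevals, mevecs = _mask_moments(mask)
        mask_major = np.arctan2(mevecs[1, 1], mevecs[0, 1]) % np.pi
        diff = np.abs(measured - mask_major)
        assert min(diff, np.pi - diff) <= np.deg2rad(5)
        assert part.center_area_fraction == pytest.approx(1 / 3, abs=0.02)

    def test_partition_is_an_exact_set_difference(self):
        part = sq.build_partition(disk_mask())
        assert not (part.center_template & part.periphery_template).any()
        assert np.array_equal(
            part.center_template | part.periphery_template, part.cell_template
        )
        assert (
            part.center_template.sum() + part.periphery_template.sum()
            == part.cell_template.sum()
        )

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True  # 4 px
        with pytest.raises(SegmentationError, match="too small"):
            sq.build_partition(mask)


class TestEnrichmentIndices:
    def setup_method(self):
        self.mask = disk_mask()
        self.part = sq.build_partition(self.mask)

    def test_uniform_image_has_zero_periphery_index(self):
        image = np.where(self.mask, 4.2, 0.0)
        assert sq.periphery_index(image, self.part) == pytest.approx(0.0, abs=1e-12)

    def test_all_peripheral_signal(self):
        image = np.where(self.part.periphery_template, 3.0, 0.0)
        expected = (
            self.part.cell_template.sum() / self.part.periphery_template.sum() - 1.0
        )
        idx = sq.periphery_index(image, self.part)
        assert idx == pytest.approx(expected, rel=1e-12)
        assert idx == pytest.approx(0.5, abs=0.05)  # 1/(2/3) − 1 at a one-third split

    def test_all_central_signal_reads_minus_one_periphery(self):
        image = np.where(self.part.center_template, 3.0, 0.0)
        assert sq.periphery_index(image, self.part) == pytest.approx(-1.0)
        assert sq.central_fraction(image, self.part) == pytest.approx(1.0)

    def test_central_fraction_of_uniform_image_is_area_fraction(self):
        image = np.where(self.mask, 2.0, 0.0)
        assert sq.central_fraction(image, self.part) == pytest.approx(
            self.part.center_area_fraction, rel=1e-12
        )
        assert sq.central_fraction(image, self.part) == pytest.approx(1 / 3, abs=0.02)

    def test_all_peripheral_has_zero_central_fraction(self):
        image = np.where(self.part.periphery_template, 3.0, 0.0)
        assert sq.central_fraction(image, self.part) == pytest.approx(0.0)

    def test_empty_cell_fluorescence_is_an_error(self):
        with pytest.raises(UndefinedRatioError):
            sq.periphery_index(np.zeros(self.mask.shape), self.part)

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        image = np.where(self.mask, rng.random(self.mask.shape) + 0.05, 0.0)
        assert sq.periphery_index(image * scale, self.part) == pytest.approx(
            sq.periphery_index(image, self.part), rel=1e-9
        )
        assert sq.central_fraction(image * scale, self.part) == pytest.approx(
            sq.central_fraction(image, self.part), rel=1e-9
        )


class TestSpreadingKinetics:
    def test_disk_area_recovered_within_three_percent(self):
        radius_um = 4.0
        px = 0.1
        rr, cc = np.indices((120, 120))
        footprint = ((rr - 60) ** 2 + (cc - 60) ** 2) * px**2 <= radius_um**2
        frames = np.stack([np.where(footprint, 10.0, 0.5)] * 3)
        movie = sq.ImageStack(frames, spacing=(px, px), frame_interval=15, kind="timelapse")
        tc = sq.spreading_area_series(movie)
        assert tc.areas == pytest.approx(np.pi * radius_um**2, rel=0.03)

    def test_generator_curve_recovered_pointwise(self):
        truth = sq.SpreadingTruth(seed=6)  # noiseless
        tc = sq.spreading_area_series(sq.generate_spreading(truth))
        np.testing.assert_allclose(tc.areas, truth.area(tc.times), rtol=0.05)

    def test_linear_ramp_velocity_is_exact(self):
        times = np.arange(10) * 15.0
        areas = 50.0 + (10.0 / 60.0) * times  # 10 μm²/min
        tc = sq.SpreadingTimecourse(times, areas, np.zeros(10, bool))
        assert sq.spreading_velocity(tc).velocity == pytest.approx(10.0)

    def test_constant_area_gives_zero_velocity(self):
        tc = sq.SpreadingTimecourse(np.arange(5) * 15.0, np.full(5, 80.0), np.zeros(5, bool))
        assert sq.spreading_velocity(tc).velocity == pytest.approx(0.0)

    def test_saturating_curve_matches_window_averaged_derivative(self):
        truth = sq.SpreadingTruth(seed=8)
        tc = sq.spreading_velocity(sq.spreading_area_series(sq.generate_spreading(truth)))
        t_end = tc.fit_window[1]
        secant = (truth.area(t_end) - truth.A0) / t_end * 60.0
        assert tc.velocity == pytest.approx(secant, rel=0.15)

    def test_degenerate_window_rejected(self):
        tc = sq.SpreadingTimecourse(np.arange(2) * 15.0, np.array([1.0, 2.0]), np.zeros(2, bool))
        with pytest.raises(DegenerateWindowError):
            sq.spreading_velocity(tc)

    @given(k=st.floats(0.1, 10.0), shift=st.floats(0.0, 500.0))
    def test_velocity_equivariance(self, k, shift):
        """Scaling areas scales the velocity; shifting times leaves it fixed."""
        times = np.arange(8) * 15.0
        areas = 30.0 + 2.0 * np.sqrt(times + 1.0)
        base = sq.spreading_velocity(
            sq.SpreadingTimecourse(times, areas, np.zeros(8, bool)),
            window=(0.0, times[-1]),
        ).velocity
        scaled = sq.spreading_velocity(
            sq.SpreadingTimecourse(times, k * areas, np.zeros(8, bool)),
            window=(0.0, times[-1]),
        ).velocity
        shifted = sq.spreading_velocity(
            sq.SpreadingTimecourse(times + shift, areas, np.zeros(8, bool)),
            window=(shift, shift + times[-1]),
        ).velocity
        assert scaled == pytest.approx(k * base, rel=1e-9)
        assert shifted == pytest.approx(base, rel=1e-9)


class TestKymograph:
    def test_static_movie_has_identical_columns(self):
        truth = sq.SpreadingTruth(seed=2, A0=80, A_max=80, duration=60)
        ky = sq.kymograph(sq.generate_spreading(truth))
        for col in range(1, ky.data.shape[1]):
            np.testing.assert_array_equal(ky.data[:, col], ky.data[:, 0])

    def test_sample_count_contract(self):
        truth = sq.SpreadingTruth(seed=2, duration=60)
        movie = sq.generate_spreading(truth)
        ky = sq.kymograph(movie, length=7.03)
        assert ky.data.shape[0] == int(np.ceil(7.03 / truth.pixel_size))

    def test_line_outside_image_rejected(self):
        movie = sq.generate_spreading(sq.SpreadingTruth(seed=2, duration=30))
        with pytest.raises(ValueError, match="outside"):
            sq.kymograph(movie, center=(500.0, 500.0), angle=0.0, length=1.0)

    def test_growing_disk_edge_advances_with_the_area_curve(self):
        """Edge velocity in the kymograph obeys dA/dt = 2πr · dr/dt."""
        truth = sq.SpreadingTruth(seed=5)  # noiseless saturating growth
        movie = sq.generate_spreading(truth)
        ky = sq.kymograph(movie, angle=0.0)
        bg = truth.background
        edge = []
        for col in range(ky.data.shape[1]):
            profile = ky.data[:, col]
            lit = np.where(profile > bg + 1.0)[0]
            edge.append(np.abs(ky.distances[lit]).max())
        edge = np.asarray(edge)
        # secant edge speed over the rising window vs the chain-rule average
        sel = ky.times <= 2 * truth.tau
        t = ky.times[sel]
        measured = (edge[sel][-1] - edge[0]) / (t[-1] - t[0])
        r = np.sqrt(truth.area(t) / np.pi)
        dadt = (truth.A_max - truth.A0) / truth.tau * np.exp(-t / truth.tau)
        analytic = np.mean(dadt / (2 * np.pi * r))
        assert measured == pytest.approx(analytic, rel=0.15)
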