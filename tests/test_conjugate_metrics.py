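"""Conjugate indices: analytic examples, invariances, parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import synquant as sq
from synquant.conjugate import bead_total_fluorescence, polarity_out_of_range
from synquant.errors import UndefinedAxisError, UndefinedRatioError

CMC = np.zeros(3)
BMC = np.array([5.0, 0.0, 0.0])

coords = st.floats(-10, 10, allow_nan=False, allow_infinity=False)
triples = st.tuples(coords, coords, coords).map(np.array)


class TestPolarityIndex:
    @pytest.mark.parametrize(
        "cent, expected",
        [
            (BMC, 1.0),  # centrosome at the bead mass center: fully polarized
            (-BMC, -1.0),  # reflected through the cell mass center: anti-polarized
            (CMC, 0.0),
            (0.5 * BMC + np.array([0.0, 3.0, -2.0]), 0.5),  # ⊥ component annihilated
        ],
    )
    def test_analytic_landmarks(self, cent, expected):
        assert sq.polarity_index(cent, CMC, BMC) == pytest.approx(expected, abs=1e-12)

    def test_coincident_axis_endpoints_rejected(self):
        with pytest.raises(UndefinedAxisError):
            sq.polarity_index(BMC, CMC, CMC)

    def test_values_beyond_unit_range_flagged_not_clamped(self):
        p = sq.polarity_index(1.4 * BMC, CMC, BMC)
        assert p == pytest.approx(1.4)
        assert polarity_out_of_range(p)
        assert not polarity_out_of_range(1.0)

    @given(cent=triples, cmc=triples, bmc=triples, shift=triples, key=st.integers(0, 10**6))
    def test_rigid_motion_invariance(self, cent, cmc, bmc, shift, key):
        """The index depends only on relative landmark geometry."""
        if np.linalg.norm(bmc - cmc) < 1e-3:
            return
        rot = Rotation.random(rng=np.random.default_rng(key)).as_matrix()
        p0 = sq.polarity_index(cent, cmc, bmc)
        p1 = sq.polarity_index(rot @ cent + shift, rot @ cmc + shift, rot @ bmc + shift)
        assert p1 == pytest.approx(p0, abs=1e-6)

    @given(cent=triples)
    def test_antisymmetric_under_reflection_through_cmc(self, cent):
        p = sq.polarity_index(cent, CMC, BMC)
        assert sq.polarity_index(2 * CMC - cent, CMC, BMC) == pytest.approx(-p, abs=1e-9)


class TestCentrosomeNucleusDistance:
    @pytest.mark.parametrize(
        "cent, mcn, expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
            ((0.0, 0.0, 3.0), (0.0, 0.0, 0.0), 3.0),
            # 4 z-voxels apart at 0.5 μm spacing, same xy: (i+0.5)·dz convention
            (
                tuple((np.array([6, 10, 10]) + 0.5) * [0.5, 0.1, 0.1]),
                tuple((np.array([2, 10, 10]) + 0.5) * [0.5, 0.1, 0.1]),
                2.0,
            ),
        ],
    )
    def test_physical_distances(self, cent, mcn, expected):
        assert sq.centrosome_nucleus_distance(cent, mcn) == pytest.approx(expected)


def _uniform_stack(mask3d, value=3.0, channel="actin"):
    data = np.where(mask3d, value, 0.0)[None]
    return sq.ImageStack(data, spacing=(0.5, 0.1, 0.1), channel_names=(channel,))


class TestDensityIndex:
    def test_uniform_fluorescence_is_exactly_one(self, noiseless_truth):
        z, y, x = np.ogrid[:24, :100, :140]
        d2 = (
            ((z + 0.5) * 0.5 - 6.0) ** 2
            + ((y + 0.5) * 0.1 - 5.0) ** 2
            + ((x + 0.5) * 0.1 - 5.0) ** 2
        )
        mask = d2 <= 4.0**2
        stack = _uniform_stack(mask)
        for mode in ("slice", "sphere"):
            di = sq.density_index(stack, "actin", (6.0, 5.0, 6.0), mask, mode=mode)
            assert di == pytest.approx(1.0, abs=1e-12)

    def test_all_fluorescence_at_centrosome_gives_area_ratio(self):
        mask = np.ones((4, 60, 60), bool)
        cent = (0.75, 3.0, 3.0)  # z exactly at the center of slice 1
        data = np.zeros((1, 4, 60, 60))
        # fill only the 1 μm circle at the centrosome's plane
        iz = 1
        yy, xx = np.meshgrid(
            (np.arange(60) + 0.5) * 0.1, (np.arange(60) + 0.5) * 0.1, indexing="ij"
        )
        disk = (yy - 3.0) ** 2 + (xx - 3.0) ** 2 <= 1.0
        data[0, iz][disk] = 5.0
        stack = sq.ImageStack(data, spacing=(0.5, 0.1, 0.1), channel_names=("actin",))
        di = sq.density_index(stack, "actin", cent, mask, mode="slice")
        a_cell = 60 * 60
        a_cent = disk.sum()
        assert di == pytest.approx(a_cell / a_cent, rel=1e-12)

    def test_zero_fluorescence_at_centrosome_gives_zero(self):
        mask = np.ones((4, 60, 60), bool)
        data = np.full((1, 4, 60, 60), 2.0)
        yy, xx = np.meshgrid(
            (np.arange(60) + 0.5) * 0.1, (np.arange(60) + 0.5) * 0.1, indexing="ij"
        )
        disk = (yy - 3.0) ** 2 + (xx - 3.0) ** 2 <= 1.0
        data[0, 1][disk] = 0.0
        stack = sq.ImageStack(data, spacing=(0.5, 0.1, 0.1), channel_names=("actin",))
        assert sq.density_index(stack, "actin", (0.75, 3.0, 3.0), mask) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_centrosomal_region_outside_mask_is_an_error(self):
        mask = np.zeros((4, 60, 60), bool)
        mask[:, :10, :10] = True
        stack = _uniform_stack(mask)
        with pytest.raises(UndefinedRatioError):
            sq.density_index(stack, "actin", (1.0, 5.0, 5.0), mask)

    def test_monotone_in_centrosomal_actin_weight(self):
        """More centrosomal actin in the phantom → larger measured index."""
        indices = []
        for weight in (0.2, 0.6, 1.4):
            truth = sq.SceneTruth(
                channels=sq.default_channels(
                    overrides={"actin": {"params": {"centrosomal_pool_weight": weight}}}
                )
            )
            stack = sq.generate_conjugate(truth)
            mask = sq.segment_cell(stack, "actin")
            indices.append(
                sq.density_index(stack, "actin", truth.centrosome_pos, mask)
            )
        assert indices[0] < indices[1] < indices[2]
        assert indices[2] > 1.0  # accumulation reads above 1


class TestRecruitment:
    def test_all_and_none_in_bead_region(self, noiseless_scene, noiseless_truth):
        region = sq.define_bead_region(
            noiseless_scene, noiseless_truth.bead_center, noiseless_truth.bead_radius
        )
        cell = sq.segment_cell(noiseless_scene, "actin")
        inside = np.where(region.mask, 4.0, 0.0)[None]
        stack_in = sq.ImageStack(inside, spacing=(0.5, 0.1, 0.1), channel_names=("lamp1",))
        assert sq.recruitment_pct(stack_in, "lamp1", region, cell) == pytest.approx(100.0)
        outside = np.where(region.mask | ~cell, 0.0, 4.0)[None]
        stack_out = sq.ImageStack(outside, spacing=(0.5, 0.1, 0.1), channel_names=("lamp1",))
        assert sq.recruitment_pct(stack_out, "lamp1", region, cell) == pytest.approx(0.0)

    def test_monotone_in_lysosome_polarization(self):
        values = []
        for pol in (0.2, 0.7):
            truth = sq.SceneTruth(seed=3, lysosome_polarization_true=pol)
            stack = sq.generate_conjugate(truth)
            cell = sq.segment_cell(stack, "actin")
            region = sq.define_bead_region(stack, truth.bead_center, truth.bead_radius)
            values.append(sq.recruitment_pct(stack, "lamp1", region, cell))
        assert values[1] > values[0]

    def test_zero_total_fluorescence_is_an_error(self, noiseless_scene, noiseless_truth):
        region = sq.define_bead_region(
            noiseless_scene, noiseless_truth.bead_center, noiseless_truth.bead_radius
        )
        cell = sq.segment_cell(noiseless_scene, "actin")
        empty = sq.ImageStack(
            np.zeros((1,) + noiseless_scene.spatial_shape),
            spacing=(0.5, 0.1, 0.1),
            channel_names=("lamp1",),
        )
        with pytest.raises(UndefinedRatioError):
            sq.recruitment_pct(empty, "lamp1", region, cell)


class TestExtraction:
    def test_reference_level_means_no_loss(self):
        res = sq.extraction_pct([10.0, 10.0], [10.0, 10.0, 10.0])
        assert res.mean_pct == pytest.approx(0.0)

    def test_sixty_percent_loss(self):
        res = sq.extraction_pct([4.0], [10.0, 10.0])
        assert res.per_bead_pct[0] == pytest.approx(60.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(UndefinedRatioError):
            sq.extraction_pct([1.0], [0.0, 0.0])

    def test_noiseless_phantom_recovery(self):
        """Beads rendered with half the antigen extracted read ~50%."""
        totals = {}
        for frac in (0.0, 0.5):
            truth = sq.SceneTruth(seed=9, extraction_fraction_true=frac)
            stack = sq.generate_conjugate(truth)
            region = sq.define_bead_region(stack, truth.bead_center, truth.bead_radius)
            totals[frac] = bead_total_fluorescence(stack, "ova", region)
        res = sq.extraction_pct([totals[0.5]], [totals[0.0]])
        assert res.per_bead_pct[0] == pytest.approx(50.0, abs=3.0)


def test_bead_total_equals_direct_3d_sum(noiseless_scene, noiseless_truth):
    """Sum-projection totals match the 3-D regional total exactly."""
    region = sq.define_bead_region(
        noiseless_scene, noiseless_truth.bead_center, noiseless_truth.bead_radius
    )
    direct = noiseless_scene.channel("ova")[region.mask].sum()
    assert bead_total_fluorescence(noiseless_scene, "ova", region) == direct


@given(scale=st.floats(0.1, 50.0))
def test_ratio_metrics_invariant_under_intensity_scaling(scale):
    mask = np.ones((2, 30, 30), bool)
    rng = np.random.default_rng(1)
    base = rng.random((1, 2, 30, 30)) + 0.1
    a = sq.ImageStack(base, spacing=(0.5, 0.1, 0.1), channel_names=("actin",))
    b = sq.ImageStack(base * scale, spacing=(0.5, 0.1, 0.1), channel_names=("actin",))
    cent = (0.5, 1.5, 1.5)
    assert sq.density_index(b, "actin", cent, mask) == pytest.approx(
        sq.density_index(a, "actin", cent, mask), rel=1e-9
    )
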